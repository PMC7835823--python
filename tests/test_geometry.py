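"""Motif geometry, tetrahedron series and helix-axis drift."""

import numpy as np
import pytest

from redoxtraj.core import StructureError, Trajectory
from redoxtraj.geometry import (
    axis_drift,
    helix_axis,
    klyne_prelog_class,
    min_interdomain_ss_distance,
    motif_geometry,
    motif_series,
    sh_s_hbond_fraction,
    synchronized_edge_changes,
    tetrahedron_edges,
)
from redoxtraj.synthetic import (
    chain_topology,
    make_ideal_helix,
    make_motif,
    make_synthetic_bvkor_cys,
    make_thiol_pair_trajectory,
)

from conftest import as_trajectory, build_structure, random_rotation


class TestMotifGeometry:
    @pytest.mark.parametrize(
        "d, chi",
        [(4.0, 60.0), (3.0, 0.0), (4.0, 180.0), (5.5, 90.0), (2.5, 30.0),
         (6.0, 120.0), (4.5, 45.0), (3.5, 150.0), (7.0, 75.0), (8.0, 15.0)],
    )
    def test_roundtrip_with_generator(self, d, chi):
        _, traj = make_motif(d, chi)
        g = motif_geometry(traj.coordinates[0], (0, 3), (1, 2))
        assert g.s_s_distance == pytest.approx(d, abs=1e-6)
        assert g.pseudo_torsion == pytest.approx(chi, abs=1e-6)

    def test_synclinal_classification(self):
        _, traj = make_motif(4.0, 60.0)
        g = motif_geometry(traj.coordinates[0], (0, 3), (1, 2))
        assert g.klyne_prelog == "synclinal"

    @pytest.mark.parametrize(
        "torsion, cls",
        [(0.0, "syn-periplanar"), (29.9, "syn-periplanar"), (30.0, "synclinal"),
         (89.9, "synclinal"), (90.0, "anticlinal"), (149.9, "anticlinal"),
         (150.0, "antiperiplanar"), (175.0, "antiperiplanar"), (180.0, "antiperiplanar")],
    )
    def test_klyne_prelog_bands(self, torsion, cls):
        assert klyne_prelog_class(torsion) == cls

    def test_rigid_motion_invariance(self, rng):
        _, traj = make_motif(4.5, 72.0)
        f = traj.coordinates[0]
        moved = f @ random_rotation(rng).T + rng.normal(size=3)
        g0 = motif_geometry(f, (0, 3), (1, 2))
        g1 = motif_geometry(moved, (0, 3), (1, 2))
        assert g1.s_s_distance == pytest.approx(g0.s_s_distance, abs=1e-9)
        assert g1.pseudo_torsion == pytest.approx(g0.pseudo_torsion, abs=1e-9)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            make_motif(50.0, 60.0)

    def test_coincident_atoms_rejected(self):
        frame = np.zeros((4, 3))
        with pytest.raises(StructureError):
            motif_geometry(frame, (0, 3), (1, 2))

    def test_series_class_histogram(self):
        _, t60 = make_motif(4.0, 60.0)
        _, t170 = make_motif(4.0, 170.0)
        frames = np.concatenate([t60.coordinates, t170.coordinates] * 5)
        traj = as_trajectory(t60.topology, frames)
        table = motif_series(traj, (0, 3), (1, 2))
        counts = table["class"].value_counts()
        assert counts["synclinal"] == 5
        assert counts["antiperiplanar"] == 5


class TestThiolHbondFraction:
    def test_always_inside(self):
        traj, _ = make_thiol_pair_trajectory(50, 1.0, seed=0)
        assert sh_s_hbond_fraction(traj, 0, 1, 2) == 1.0

    def test_planted_fraction_recovered(self):
        traj, flags = make_thiol_pair_trajectory(1000, 0.72, seed=1)
        frac = sh_s_hbond_fraction(traj, 0, 1, 2)
        assert frac == pytest.approx(flags.mean(), abs=1e-12)
        assert frac == pytest.approx(0.72, abs=0.01)

    def test_directionality_matters(self):
        # each sulphur has its own thiol H: one points at the partner, the
        # other points away, so the two donor directions disagree
        topo, frame = build_structure(
            [
                ("CYS", 1, "A", [("SG", "S", [0, 0, 0]), ("HG", "H", [1.34, 0, 0])]),
                ("CYS", 4, "A", [("SG", "S", [3.2, 0, 0]), ("HG", "H", [4.54, 0, 0])]),
            ]
        )
        traj = as_trajectory(topo, frame)
        forward = sh_s_hbond_fraction(traj, donor_s=0, donor_h=1, acceptor_s=2)
        backward = sh_s_hbond_fraction(traj, donor_s=2, donor_h=3, acceptor_s=0)
        assert forward == 1.0
        assert backward == 0.0

    def test_missing_hydrogen_rejected(self):
        traj, _ = make_thiol_pair_trajectory(5, 0.5, seed=2)
        with pytest.raises(StructureError, match="thiol hydrogen"):
            sh_s_hbond_fraction(traj, 0, None, 2)


class TestTetrahedron:
    def _regular_tetrahedron(self):
        pts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        ) / np.sqrt(8)
        return pts  # unit edge length

    def test_unit_regular_edges(self):
        topo = chain_topology(4)
        traj = as_trajectory(topo, self._regular_tetrahedron())
        series = tetrahedron_edges(traj, (0, 1, 2, 3))
        np.testing.assert_allclose(series.values, 1.0, atol=1e-12)

    def test_displaced_vertex_changes_three_edges(self):
        pts = self._regular_tetrahedron()
        moved = pts.copy()
        moved[0] += (pts[1] - pts[0]) * 0.1
        topo = chain_topology(4)
        traj = as_trajectory(topo, np.stack([pts, moved]))
        series = tetrahedron_edges(traj, (0, 1, 2, 3))
        changed = np.abs(series.values[1] - series.values[0]) > 1e-9
        assert changed.sum() == 3

    def test_triangle_inequality_on_faces(self, rng):
        topo = chain_topology(4)
        traj = as_trajectory(topo, rng.normal(scale=4, size=(10, 4, 3)))
        series = tetrahedron_edges(traj, (0, 1, 2, 3))
        lab = {l: i for i, l in enumerate(series.labels)}
        faces = [("0-1", "0-2", "1-2"), ("0-1", "0-3", "1-3"),
                 ("0-2", "0-3", "2-3"), ("1-2", "1-3", "2-3")]
        for f in range(10):
            e = series.values[f]
            for a, b, c in faces:
                assert e[lab[a]] + e[lab[b]] >= e[lab[c]] - 1e-9

    def test_synchronized_change_detection(self, rng):
        pts = self._regular_tetrahedron() * 5
        frames = np.repeat(pts[None], 10, axis=0)
        frames[6:, 0, :] += np.array([10.0, 0, 0])  # vertex 0 jumps at frame 6
        topo = chain_topology(4)
        series = tetrahedron_edges(as_trajectory(topo, frames), (0, 1, 2, 3))
        hits = synchronized_edge_changes(series, min_delta=4.0, min_edges=3)
        np.testing.assert_array_equal(hits, [6])


class TestHelixAxis:
    def _helix_along_z(self):
        topo, traj = make_ideal_helix(12, "alpha")
        f = traj.coordinates[0]
        ca = np.array([f[i] for i, n in enumerate(topo.atom_names) if n == "CA"])
        d = ca[1:] - ca[:-1]
        axis = d.mean(axis=0)
        axis /= np.linalg.norm(axis)
        # rotate the helix so its mean rise direction is +z
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s, c = np.linalg.norm(v), axis @ z
        if s < 1e-12:
            r = np.eye(3)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            r = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        return topo, f @ r.T

    def test_ideal_helix_axis_points_along_z(self):
        topo, f = self._helix_along_z()
        ax = helix_axis(f, topo, range(12))
        angle = np.degrees(np.arccos(abs(ax.direction @ np.array([0, 0, 1.0]))))
        assert angle < 1.0

    def test_rotation_equivariance(self, rng):
        topo, traj = make_ideal_helix(10)
        f = traj.coordinates[0]
        r = random_rotation(rng)
        ax0 = helix_axis(f, topo, range(10))
        ax1 = helix_axis(f @ r.T, topo, range(10))
        np.testing.assert_allclose(ax1.direction, r @ ax0.direction, atol=1e-9)

    def test_elongation_factor(self):
        topo, traj = make_ideal_helix(10)
        f = traj.coordinates[0]
        base = helix_axis(f, topo, range(10))
        longer = helix_axis(f, topo, range(10), elongation=1.5)
        assert longer.length == pytest.approx(1.5 * base.length, rel=1e-9)
        mid0 = (base.start + base.end) / 2
        mid1 = (longer.start + longer.end) / 2
        np.testing.assert_allclose(mid0, mid1, atol=1e-9)

    def test_short_range_rejected(self):
        topo, traj = make_ideal_helix(10)
        with pytest.raises(StructureError):
            helix_axis(traj.coordinates[0], topo, [0, 1])


class TestAxisDrift:
    def _helix_with_static_anchor(self):
        """Ideal helix plus three distant static anchor residues (one CA each)."""
        topo, traj = make_ideal_helix(8)
        f = traj.coordinates[0]
        from conftest import build_structure

        extra = [
            ("GLY", 100 + i, "Z", [("CA", "C", xyz)])
            for i, xyz in enumerate([[50, 0, 0], [0, 50, 0], [0, 0, 50]])
        ]
        residues = []
        for r in range(topo.n_residues):
            atoms = [
                (str(topo.atom_names[i]), str(topo.elements[i]), f[i])
                for i in topo.residue_atoms(r)
            ]
            residues.append((str(topo.res_names[r]), int(topo.res_numbers[r]), "A", atoms))
        topo2, frame = build_structure(residues + extra)
        return topo2, frame

    def test_static_helix_single_point(self):
        topo, frame = self._helix_with_static_anchor()
        traj = as_trajectory(topo, np.repeat(frame[None], 5, axis=0))
        df = axis_drift(traj, topo, range(8))
        for (_, _), grp in df.groupby(["plane", "endpoint"]):
            assert grp["u"].std() < 1e-9
            assert grp["v"].std() < 1e-9

    def test_precessing_helix_traces_circle(self):
        topo, frame = self._helix_with_static_anchor()
        helix_atoms = np.flatnonzero(np.array([c == "A" for c in topo.atom_chain_ids()]))
        anchor_atoms = np.flatnonzero(np.array([c == "Z" for c in topo.atom_chain_ids()]))
        tilt = np.deg2rad(10.0)
        frames = []
        center = frame[helix_atoms].mean(axis=0)
        for t in range(24):
            spin = 2 * np.pi * t / 24
            rt = _rot_z(spin) @ _rot_x(tilt) @ _rot_z(-spin)
            f = frame.copy()
            f[helix_atoms] = (frame[helix_atoms] - center) @ rt.T + center
            frames.append(f)
        traj = as_trajectory(topo, frames)
        df = axis_drift(traj, topo, range(8), fit_mask=anchor_atoms)
        # endpoints wander on a closed track with nonzero spread in both planes
        for (_, _), grp in df.groupby(["plane", "endpoint"]):
            assert grp["u"].std() > 1e-3 or grp["v"].std() > 1e-3


def _rot_z(a):
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])


def _rot_x(a):
    return np.array([[1.0, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


class TestInterdomainMeasurement:
    def test_synthetic_standin_roundtrip(self, tmp_path):
        from redoxtraj.core import read_structure, write_structure

        topo, traj, info = make_synthetic_bvkor_cys(interdomain_ss=16.0)
        path = tmp_path / "standin.pdb"
        write_structure(topo, traj, path)
        topo2, traj2 = read_structure(path)
        d = min_interdomain_ss_distance(
            topo2, traj2.coordinates[0], info["vkor_domain"], info["trx_domain"]
        )
        assert d == pytest.approx(16.0, abs=1e-3)

    def test_missing_domain_rejected(self):
        topo, traj, info = make_synthetic_bvkor_cys()
        with pytest.raises(StructureError):
            min_interdomain_ss_distance(topo, traj.coordinates[0], [1], info["trx_domain"])
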