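"""Contact detection: H-bonds, salt bridges, hydrophobic contacts, interfaces."""

import numpy as np
import pytest

from redoxtraj.contacts import (
    contact_map,
    count_unique_contacts,
    exposed_residues,
    find_hbonds,
    find_hydrophobic,
    find_salt_bridges,
    interface_contacts,
    interface_summary,
)
from redoxtraj.core import ResidueClass, StructureError
from redoxtraj.synthetic import (
    PlantedContact,
    PlantedInterfaceSpec,
    make_planted_interface,
)

from conftest import as_trajectory, build_structure, random_rotation


def ser_pair(d, with_h=True, h_along=True):
    """Two serines with OG...OG = d; optional HG on the first serine."""
    atoms1 = [("CA", "C", [-2.5, 3.0, 0]), ("OG", "O", [0, 0, 0])]
    if with_h:
        hx = 0.96 if h_along else -0.96
        atoms1.append(("HG", "H", [hx, 0, 0]))
    return build_structure(
        [
            ("SER", 1, "A", atoms1),
            ("SER", 10, "A", [("CA", "C", [d + 2.5, 3.0, 0]), ("OG", "O", [d, 0, 0])]),
        ]
    )


class TestHbonds:
    def test_inside_criteria(self):
        topo, frame = ser_pair(3.5)
        recs = find_hbonds(frame, topo)
        assert len(recs) == 1
        assert recs[0].kind == "hbond"
        assert recs[0].angle >= 120.0

    def test_distance_boundary(self):
        topo, frame = ser_pair(3.7)
        assert find_hbonds(frame, topo) == []

    def test_angle_criterion(self):
        topo, frame = ser_pair(3.5, h_along=False)  # H points away: angle ~0
        assert find_hbonds(frame, topo) == []

    def test_sulphur_uses_same_defaults(self):
        topo, frame = build_structure(
            [
                ("CYS", 1, "A", [("SG", "S", [0, 0, 0]), ("HG", "H", [1.34, 0, 0])]),
                ("CYS", 5, "A", [("SG", "S", [3.9, 0, 0])]),
            ]
        )
        assert find_hbonds(frame, topo) == []
        longer = find_hbonds(frame, topo, d_cut=4.2)
        assert len(longer) == 1 and longer[0].kind == "hbond"

    def test_donor_without_h_is_silent(self):
        topo, frame = ser_pair(3.2, with_h=False)
        assert find_hbonds(frame, topo, idealize_backbone_h=False) == []


class TestHydrophobic:
    def leu_pair(self, d):
        return build_structure(
            [
                ("LEU", 1, "A", [("CA", "C", [-2.5, 3, 0]), ("CD1", "C", [0, 0, 0])]),
                ("LEU", 10, "A", [("CA", "C", [d + 2.5, 3, 0]), ("CD1", "C", [d, 0, 0])]),
            ]
        )

    def test_close_side_chains(self):
        topo, frame = self.leu_pair(3.8)
        recs = find_hydrophobic(frame, topo)
        assert len(recs) == 1 and recs[0].distance == pytest.approx(3.8)

    def test_beyond_cutoff(self):
        topo, frame = self.leu_pair(4.2)
        assert find_hydrophobic(frame, topo) == []

    def test_glycine_calpha_proxy(self):
        topo, frame = build_structure(
            [
                ("GLY", 1, "A", [("CA", "C", [0, 0, 0])]),
                ("ALA", 10, "A", [("CA", "C", [3.5 + 1.5, 0, 0]), ("CB", "C", [3.5, 0, 0])]),
            ]
        )
        recs = find_hydrophobic(frame, topo)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.5)


class TestSaltBridges:
    def arg_asp(self, d):
        return build_structure(
            [
                ("ARG", 1, "A", [("CA", "C", [-3, 3, 0]), ("NH1", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [d + 3, 3, 0]), ("OD1", "O", [d, 0, 0])]),
            ]
        )

    def test_arg_asp_bridge(self):
        topo, frame = self.arg_asp(2.8)
        recs = find_salt_bridges(frame, topo)
        assert len(recs) == 1 and recs[0].distance == pytest.approx(2.8)

    def test_beyond_cutoff(self):
        topo, frame = self.arg_asp(4.5)
        assert find_salt_bridges(frame, topo) == []

    def test_lys_glu_dual_listed_as_hbond_with_explicit_h(self):
        topo, frame = build_structure(
            [
                ("LYS", 1, "A", [("CA", "C", [-3, 3, 0]), ("NZ", "N", [0, 0, 0]),
                                 ("HZ1", "H", [1.0, 0, 0])]),
                ("GLU", 10, "A", [("CA", "C", [6.2, 3, 0]), ("OE2", "O", [3.2, 0, 0])]),
            ]
        )
        salts = find_salt_bridges(frame, topo)
        hbonds = find_hbonds(frame, topo)
        assert len(salts) == 1
        assert len(hbonds) == 1
        both = salts + hbonds
        assert count_unique_contacts(both) == 1  # one residue pair, two listings

    def test_histidine_not_a_donor(self):
        topo, frame = build_structure(
            [
                ("HIS", 1, "A", [("CA", "C", [-3, 3, 0]), ("NE2", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [5.8, 3, 0]), ("OD1", "O", [2.8, 0, 0])]),
            ]
        )
        assert find_salt_bridges(frame, topo) == []


class TestBruteForceOracle:
    def _mixed_structure(self, rng):
        """Residues of every detector-relevant type scattered in a box."""
        residues = []
        kinds = [
            ("LEU", [("CA", "C"), ("CD1", "C")]),
            ("ARG", [("CA", "C"), ("NH1", "N")]),
            ("ASP", [("CA", "C"), ("OD1", "O")]),
            ("SER", [("CA", "C"), ("OG", "O"), ("HG", "H")]),
            ("GLY", [("CA", "C")]),
            ("LYS", [("CA", "C"), ("NZ", "N")]),
            ("GLU", [("CA", "C"), ("OE1", "O")]),
            ("ALA", [("CA", "C"), ("CB", "C")]),
        ]
        num = 1
        for rep in range(2):
            for rn, atom_spec in kinds:
                origin = rng.uniform(0, 12, size=3)
                atoms = []
                for i, (nm, el) in enumerate(atom_spec):
                    offset = rng.uniform(-1.0, 1.0, size=3)
                    if el == "H":  # keep H covalently close to the previous heavy atom
                        offset = atoms[-1][2] - origin + rng.normal(scale=0.3, size=3)
                        offset *= 0.96 / max(np.linalg.norm(offset), 1e-6)
                        offset = atoms[-1][2] - origin + offset
                    atoms.append((nm, el, origin + offset))
                residues.append((rn, num, "A", atoms))
                num += 3
        return build_structure(residues)

    def test_detectors_equal_brute_force_scan(self, rng):
        topo, frame = self._mixed_structure(rng)
        got = {
            (r.kind, r.residue_pair())
            for r in (
                find_hbonds(frame, topo, idealize_backbone_h=False)
                + find_salt_bridges(frame, topo)
                + find_hydrophobic(frame, topo)
            )
        }
        expected = set()
        # independent scan with its own criteria bookkeeping
        n_res = topo.n_residues
        names = topo.atom_names
        elements = topo.elements
        res_of = topo.atom_residue
        hydro = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY"}
        backbone = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
        for d in range(topo.n_atoms):
            if elements[d] not in ("N", "O", "S"):
                continue
            hs = [
                h
                for h in range(topo.n_atoms)
                if elements[h] == "H"
                and res_of[h] == res_of[d]
                and np.linalg.norm(frame[h] - frame[d]) < 1.3
            ]
            for a in range(topo.n_atoms):
                if a == d or res_of[a] == res_of[d] or elements[a] not in ("N", "O", "S"):
                    continue
                if np.linalg.norm(frame[d] - frame[a]) >= 3.6:
                    continue
                for h in hs:
                    v1, v2 = frame[d] - frame[h], frame[a] - frame[h]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 120:
                        expected.add(("hbond", tuple(sorted((res_of[d], res_of[a])))))
        basic = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
        acidic = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
        for i in range(topo.n_atoms):
            rn_i = topo.res_names[res_of[i]]
            if names[i] not in basic.get(str(rn_i), ()):
                continue
            for j in range(topo.n_atoms):
                rn_j = topo.res_names[res_of[j]]
                if names[j] not in acidic.get(str(rn_j), ()):
                    continue
                if np.linalg.norm(frame[i] - frame[j]) < 4.0:
                    expected.add(("salt_bridge", tuple(sorted((res_of[i], res_of[j])))))
        for r1 in range(n_res):
            for r2 in range(r1 + 1, n_res):
                if str(topo.res_names[r1]) not in hydro or str(topo.res_names[r2]) not in hydro:
                    continue
                if abs(int(topo.res_numbers[r1]) - int(topo.res_numbers[r2])) < 2:
                    continue
                for i in range(topo.n_atoms):
                    if res_of[i] != r1 or elements[i] == "H":
                        continue
                    if names[i] in backbone and not (
                        str(topo.res_names[r1]) == "GLY" and names[i] == "CA"
                    ):
                        continue
                    for j in range(topo.n_atoms):
                        if res_of[j] != r2 or elements[j] == "H":
                            continue
                        if names[j] in backbone and not (
                            str(topo.res_names[r2]) == "GLY" and names[j] == "CA"
                        ):
                            continue
                        if np.linalg.norm(frame[i] - frame[j]) < 4.0:
                            expected.add(("hydrophobic", (r1, r2)))
        assert got == expected

    def test_rigid_motion_invariance(self, rng):
        topo, frame = self._mixed_structure(rng)
        moved = frame @ random_rotation(rng).T + rng.normal(size=3) * 20

        def signature(f):
            return sorted(
                (r.kind, r.residue_pair(), round(r.distance, 6))
                for r in (
                    find_hbonds(f, topo, idealize_backbone_h=False)
                    + find_salt_bridges(f, topo)
                    + find_hydrophobic(f, topo)
                )
            )

        assert signature(frame) == signature(moved)


class TestInterface:
    def test_planted_five_contacts(self):
        spec = PlantedInterfaceSpec(
            contacts=[
                PlantedContact("salt", 3.0),
                PlantedContact("salt", 3.2),
                PlantedContact("hydrophobic", 3.6),
                PlantedContact("hydrophobic", 3.7),
                PlantedContact("hydrophobic", 3.5),
            ]
        )
        topo, traj, _ = make_planted_interface(spec)
        recs = interface_contacts(traj.coordinates[0], topo, "A", "B")
        assert count_unique_contacts(recs) == 5
        summary = interface_summary(recs)
        assert summary["by_type"] == {"salt_bridge": 2, "hydrophobic": 3}
        # no intra-chain leakage
        all_recs = recs
        for r in all_recs:
            ca = topo.chain_ids[r.donor_residue]
            cb = topo.chain_ids[r.acceptor_residue]
            assert {ca, cb} == {"A", "B"}

    def test_planted_nine_contacts(self):
        spec = PlantedInterfaceSpec(
            contacts=[PlantedContact("salt", 3.0)] * 3
            + [PlantedContact("hbond", 3.2, 170.0)] * 3
            + [PlantedContact("hydrophobic", 3.6)] * 3
        )
        topo, traj, _ = make_planted_interface(spec)
        recs = interface_contacts(traj.coordinates[0], topo, "A", "B")
        assert count_unique_contacts(recs) == 9

    def test_distant_chains_are_empty(self):
        topo, traj, _ = make_planted_interface(PlantedInterfaceSpec(contacts=[]))
        assert interface_contacts(traj.coordinates[0], topo, "A", "B") == []

    def test_hbond_detected_as_hbond_not_salt(self):
        spec = PlantedInterfaceSpec(contacts=[PlantedContact("hbond", 3.5, 150.0)])
        topo, traj, _ = make_planted_interface(spec)
        recs = interface_contacts(traj.coordinates[0], topo, "A", "B")
        kinds = {r.kind for r in recs}
        assert kinds == {"hbond"}

    def test_symmetric_in_chain_order(self):
        spec = PlantedInterfaceSpec(
            contacts=[PlantedContact("salt", 3.0), PlantedContact("hydrophobic", 3.5)]
        )
        topo, traj, _ = make_planted_interface(spec)
        ab = interface_contacts(traj.coordinates[0], topo, "A", "B")
        ba = interface_contacts(traj.coordinates[0], topo, "B", "A")
        key = lambda rs: sorted((r.kind, r.residue_pair()) for r in rs)
        assert key(ab) == key(ba)

    def test_unknown_chain_rejected(self):
        topo, traj, _ = make_planted_interface(
            PlantedInterfaceSpec(contacts=[PlantedContact("salt", 3.0)])
        )
        with pytest.raises(StructureError):
            interface_contacts(traj.coordinates[0], topo, "A", "Q")


class TestContactMap:
    def test_single_frame_binary_and_symmetric(self):
        topo, frame = build_structure(
            [
                ("ARG", 1, "A", [("CA", "C", [-3, 3, 0]), ("NH1", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [5.8, 3, 0]), ("OD1", "O", [2.8, 0, 0])]),
            ]
        )
        cmap = contact_map(as_trajectory(topo, frame))
        assert set(np.unique(cmap.occupancy)) <= {0.0, 1.0}
        np.testing.assert_allclose(cmap.occupancy, cmap.occupancy.T, atol=1e-12)
        assert cmap.occupancy[0, 1] == 1.0

    def test_half_occupancy(self):
        topo, close = build_structure(
            [
                ("ARG", 1, "A", [("CA", "C", [-3, 3, 0]), ("NH1", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [5.8, 3, 0]), ("OD1", "O", [2.8, 0, 0])]),
            ]
        )
        far = close.copy()
        far[2:] += np.array([20.0, 0, 0])
        cmap = contact_map(as_trajectory(topo, np.stack([close, far])))
        assert cmap.occupancy[0, 1] == pytest.approx(0.5)


class TestExposedResidues:
    def test_buried_pair_not_listed(self):
        topo, frame = build_structure(
            [
                ("ARG", 1, "A", [("CA", "C", [-3, 3, 0]), ("NH1", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [5.8, 3, 0]), ("OD1", "O", [2.8, 0, 0])]),
            ]
        )
        assert exposed_residues(frame, topo) == []

    def test_protruding_arginine_listed_with_class(self):
        topo, frame = build_structure(
            [
                ("ARG", 1, "A", [("CA", "C", [-3, 3, 0]), ("NH1", "N", [0, 0, 0])]),
                ("ASP", 10, "A", [("CA", "C", [25, 3, 0]), ("OD1", "O", [22, 0, 0])]),
            ]
        )
        out = dict(exposed_residues(frame, topo))
        assert out[0] is ResidueClass.POSITIVE
        assert out[1] is ResidueClass.NEGATIVE
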