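"""CX1X2C motif metrics, tetrahedron edge series and helix-axis drift.

The redox motif of thioredoxin-fold proteins (two cysteines separated by
two residues) is summarized per frame by the S...S' distance between the
two sulphur atoms and the absolute pseudo-torsion S-Ca-Ca'-S', classified
with Klyne-Prelog nomenclature.  Four-anchor tetrahedra track loop
deformation through their six edge distances, and helix axes (centroid of
the main-chain atoms of the first and last residues) are projected on the
x-z and y-z planes to visualise helix drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StructureError, Topology, Trajectory
from .fluctuations import apply_superposition, superpose

__all__ = [
    "MotifGeometry",
    "TetrahedronSeries",
    "HelixAxis",
    "dihedral",
    "klyne_prelog_class",
    "motif_geometry",
    "motif_series",
    "sh_s_hbond_fraction",
    "tetrahedron_edges",
    "synchronized_edge_changes",
    "helix_axis",
    "axis_drift",
    "min_interdomain_ss_distance",
    "KLYNE_PRELOG_BANDS",
]

# Klyne-Prelog bands on the absolute torsion (degrees, upper bound exclusive
# except the last): syn-periplanar, synclinal, anticlinal, antiperiplanar.
KLYNE_PRELOG_BANDS = (
    (0.0, 30.0, "syn-periplanar"),
    (30.0, 90.0, "synclinal"),
    (90.0, 150.0, "anticlinal"),
    (150.0, 180.0, "antiperiplanar"),
)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees) of four points about the p1-p2 axis."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-10:
        raise StructureError("degenerate dihedral: coincident axis atoms")
    b1 = b1 / nb1
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise StructureError("degenerate dihedral: collinear atoms")
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def klyne_prelog_class(abs_torsion_deg: float) -> str:
    t = float(abs_torsion_deg)
    if not 0.0 <= t <= 180.0:
        raise ValueError("absolute torsion must lie in [0, 180] degrees")
    for lo, hi, name in KLYNE_PRELOG_BANDS:
        if lo <= t < hi or (name == "antiperiplanar" and t == 180.0):
            return name
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class MotifGeometry:
    s_s_distance: float  # Angstrom
    pseudo_torsion: float  # degrees, absolute value in [0, 180]
    klyne_prelog: str


def motif_geometry(frame: np.ndarray, sulphurs: tuple[int, int], alphas: tuple[int, int]) -> MotifGeometry:
    """S...S' distance and |S-Ca-Ca'-S'| pseudo-torsion of one frame.

    ``sulphurs`` and ``alphas`` are atom indices (S, S') and (Ca, Ca'),
    paired so the torsion runs S-Ca-Ca'-S'.
    """
    s1, s2 = sulphurs
    a1, a2 = alphas
    if len({s1, s2, a1, a2}) != 4:
        raise StructureError("motif atoms must be four distinct atoms")
    frame = np.asarray(frame)
    d = float(np.linalg.norm(frame[s1] - frame[s2]))
    if d < 1e-8:
        raise StructureError("degenerate motif: coincident sulphur atoms")
    chi = abs(dihedral(frame[s1], frame[a1], frame[a2], frame[s2]))
    return MotifGeometry(s_s_distance=d, pseudo_torsion=chi, klyne_prelog=klyne_prelog_class(chi))


def motif_series(
    trajectory: Trajectory, sulphurs: tuple[int, int], alphas: tuple[int, int]
) -> pd.DataFrame:
    """Per-frame motif geometry table (distance, torsion, class)."""
    rows = []
    for f in range(trajectory.n_frames):
        g = motif_geometry(trajectory.coordinates[f], sulphurs, alphas)
        rows.append(
            {
                "frame": f,
                "time_ps": trajectory.time_ps[f],
                "d_SS_A": g.s_s_distance,
                "torsion_deg": g.pseudo_torsion,
                "class": g.klyne_prelog,
            }
        )
    return pd.DataFrame(rows)


def sh_s_hbond_fraction(
    trajectory: Trajectory,
    donor_s: int,
    donor_h: int | None,
    acceptor_s: int,
    d_cut: float = 3.6,
    angle_cut: float = 120.0,
) -> float:
    """Fraction of frames in which the thiol forms an S-H...S hydrogen bond.

    The direction matters: the donor sulphur's hydrogen must point at the
    acceptor sulphur.  Criteria: S(donor)...S(acceptor) distance below
    ``d_cut`` and angle S-H...S at the hydrogen at least ``angle_cut``.
    Requires an explicit thiol hydrogen — thiol H positions are never
    idealized because the statistic depends on them; pass a structure with
    hydrogens (call both directions separately to compare donors).
    """
    if donor_h is None:
        raise StructureError(
            "thiol hydrogen missing: provide a structure with explicit thiol H "
            "(idealized placement is not available for S-H)"
        )
    coords = trajectory.coordinates
    n_ok = 0
    for f in range(trajectory.n_frames):
        s_d, h, s_a = coords[f, donor_s], coords[f, donor_h], coords[f, acceptor_s]
        d = np.linalg.norm(s_d - s_a)
        if d >= d_cut:
            continue
        v1 = s_d - h
        v2 = s_a - h
        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= angle_cut:
            n_ok += 1
    return n_ok / trajectory.n_frames


# ---------------------------------------------------------------------------
# Tetrahedra
# ---------------------------------------------------------------------------

_EDGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class TetrahedronSeries:
    anchors: tuple[int, int, int, int]  # atom indices (Calpha)
    labels: tuple[str, ...]  # six edge labels "i-j"
    values: np.ndarray  # (F, 6) edge distances, Angstrom
    time_ps: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.labels))
        df.insert(0, "time_ps", self.time_ps)
        df.insert(0, "frame", np.arange(len(df)))
        return df


def tetrahedron_edges(trajectory: Trajectory, anchors) -> TetrahedronSeries:
    """Six per-frame edge distances between four Calpha anchor atoms."""
    anchors = tuple(int(a) for a in anchors)
    if len(anchors) != 4 or len(set(anchors)) != 4:
        raise StructureError("need four distinct anchor atoms")
    coords = trajectory.coordinates[:, list(anchors), :]
    values = np.stack(
        [np.linalg.norm(coords[:, i] - coords[:, j], axis=1) for i, j in _EDGE_PAIRS],
        axis=1,
    )
    labels = tuple(f"{anchors[i]}-{anchors[j]}" for i, j in _EDGE_PAIRS)
    return TetrahedronSeries(
        anchors=anchors, labels=labels, values=values, time_ps=trajectory.time_ps.copy()
    )


def synchronized_edge_changes(
    series: TetrahedronSeries, min_delta: float = 6.0, min_edges: int = 3
) -> np.ndarray:
    """Frames at which at least ``min_edges`` edges jump by ``min_delta`` A.

    Detects the synchronous rearrangements in which several edges to one
    vertex shift together between consecutive frames.
    """
    if series.values.shape[0] < 2:
        return np.array([], dtype=int)
    jumps = np.abs(np.diff(series.values, axis=0))
    hits = np.sum(jumps >= min_delta, axis=1) >= min_edges
    return np.flatnonzero(hits) + 1


# ---------------------------------------------------------------------------
# Helix axes
# ---------------------------------------------------------------------------

_MAIN_CHAIN = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HelixAxis:
    start: np.ndarray  # centroid of the first residue's main-chain atoms
    end: np.ndarray  # centroid of the last residue's main-chain atoms
    direction: np.ndarray  # unit vector start -> end
    length: float


def _mainchain_centroid(frame: np.ndarray, topology: Topology, residue_index: int) -> np.ndarray:
    pts = []
    for name in _MAIN_CHAIN:
        i = topology.find_atom(residue_index, name)
        if i is None:
            raise StructureError(
                f"residue index {residue_index} lacks main-chain atom {name}"
            )
        pts.append(frame[i])
    return np.mean(pts, axis=0)


def helix_axis(
    frame: np.ndarray,
    topology: Topology,
    residue_indices,
    elongation: float = 1.0,
) -> HelixAxis:
    """Helix axis through the main-chain centroids of the terminal residues.

    ``elongation`` stretches the segment symmetrically about its midpoint
    (e.g. 1.5 lengthens it by 50% for display).
    """
    residue_indices = list(residue_indices)
    if len(residue_indices) < 3:
        raise StructureError("a helix needs at least 3 residues")
    start = _mainchain_centroid(frame, topology, residue_indices[0])
    end = _mainchain_centroid(frame, topology, residue_indices[-1])
    if elongation != 1.0:
        mid = (start + end) / 2
        start = mid + (start - mid) * elongation
        end = mid + (end - mid) * elongation
    vec = end - start
    length = float(np.linalg.norm(vec))
    if length < 1e-8:
        raise StructureError("degenerate helix axis (coincident centroids)")
    return HelixAxis(start=start, end=end, direction=vec / length, length=length)


_PLANES = {"xz": (0, 2), "yz": (1, 2)}


def axis_drift(
    trajectory: Trajectory,
    topology: Topology,
    residue_indices,
    planes=("xz", "yz"),
    fit_mask=None,
) -> pd.DataFrame:
    """Projected helix-endpoint tracks over a trajectory.

    Frames are first superposed on frame 0 (over ``fit_mask`` or all atoms)
    so the drift is measured in a common frame; each endpoint is then
    projected on the requested Cartesian planes.
    """
    for p in planes:
        if p not in _PLANES:
            raise ValueError(f"unknown plane {p!r}; choose from {sorted(_PLANES)}")
    idx = np.arange(trajectory.n_atoms) if fit_mask is None else np.asarray(fit_mask, int)
    ref = trajectory.coordinates[0]
    rows = []
    for f in range(trajectory.n_frames):
        res = superpose(trajectory.coordinates[f], ref, idx)
        moved = apply_superposition(trajectory.coordinates[f], res)
        ax = helix_axis(moved, topology, residue_indices)
        for plane in planes:
            i, j = _PLANES[plane]
            for endpoint, pt in (("start", ax.start), ("end", ax.end)):
                rows.append(
                    {
                        "frame": f,
                        "time_ps": trajectory.time_ps[f],
                        "plane": plane,
                        "endpoint": endpoint,
                        "u": pt[i],
                        "v": pt[j],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Worked-example measurement
# ---------------------------------------------------------------------------


def min_interdomain_ss_distance(
    topology: Topology,
    frame: np.ndarray,
    domain_a_residues,
    domain_b_residues,
) -> float:
    """Minimal S...S distance between cysteine sulphurs of two domains.

    Domains are given as iterables of residue numbers; every cysteine SG
    atom whose residue number falls in a domain contributes.  Used for the
    worked example comparing the separation of the thioredoxin-like and
    VKOR-like active sites in a fused VKOR homologue.
    """
    dom_a = set(int(r) for r in domain_a_residues)
    dom_b = set(int(r) for r in domain_b_residues)
    res_nums = topology.atom_res_numbers()
    res_names = topology.atom_res_names()
    is_sg = (topology.atom_names == "SG") & (res_names == "CYS")
    a_idx = np.flatnonzero(is_sg & np.isin(res_nums, list(dom_a)))
    b_idx = np.flatnonzero(is_sg & np.isin(res_nums, list(dom_b)))
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise StructureError("no cysteine SG atoms found in one of the domains")
    frame = np.asarray(frame)
    d = np.linalg.norm(frame[a_idx][:, None, :] - frame[b_idx][None, :, :], axis=2)
    return float(d.min())
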