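"""Secondary-structure assignment from backbone -NH and -CO geometry.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model: with partial charges q1 = 0.42 e, q2 = 0.20 e and the dimensional
factor f = 332 kcal*A/(mol*e^2),

    E = q1 * q2 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * f   [kcal/mol]

and a bond is called when E < -0.5 kcal/mol.  Labels: H (alpha-helix, two
consecutive i -> i+4 bonds), G (3_10-helix, i -> i+3), E (beta bridges /
ladders), T (isolated turn), S (bend, Calpha direction change > 70 deg),
C (coil).  Priority on conflicts: H > G > E > T > S > C.  The pi-helix
pattern is folded into T.  Amide hydrogens are idealized when absent
(1.0 A from N, anti-parallel to the preceding C=O) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StructureError, Topology, Trajectory
from .contacts import idealized_amide_h

__all__ = [
    "SSAssignment",
    "backbone_hbond_energy",
    "assign_ss",
    "ss_timeline",
    "ss_fraction",
    "HBOND_ENERGY_CUTOFF",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_FACTOR = 0.42 * 0.20 * 332.0  # q1*q2*f, kcal*A/mol


@dataclass(frozen=True)
class SSAssignment:
    """Per-frame, per-residue labels; ``labels[f, r]`` in {H,G,E,T,S,C}."""

    labels: np.ndarray  # (n_sampled_frames, n_residues) of single characters
    frame_ids: np.ndarray
    time_ps: np.ndarray


def _backbone_positions(topology: Topology, frame: np.ndarray):
    """Per-residue N, CA, C, O, H positions (H idealized when missing)."""
    n_res = topology.n_residues
    out = {nm: np.full((n_res, 3), np.nan) for nm in ("N", "CA", "C", "O", "H")}
    for r in range(n_res):
        for nm in ("N", "CA", "C", "O", "H"):
            i = topology.find_atom(r, nm)
            if i is not None:
                out[nm][r] = frame[i]
        if np.isnan(out["H"][r]).any():
            n_atom = topology.find_atom(r, "N")
            if n_atom is not None:
                pos = idealized_amide_h(topology, frame, n_atom)
                if pos is not None:
                    out["H"][r] = pos
    return out


def backbone_hbond_energy(
    donor_residue: int, acceptor_residue: int, frame: np.ndarray, topology: Topology
) -> float:
    """Kabsch-Sander energy (kcal/mol) of NH(donor) -> CO(acceptor)."""
    bb = _backbone_positions(topology, frame)
    return _ks_energy(bb, donor_residue, acceptor_residue)


def _ks_energy(bb, donor: int, acceptor: int) -> float:
    n, h = bb["N"][donor], bb["H"][donor]
    c, o = bb["C"][acceptor], bb["O"][acceptor]
    if np.isnan(n).any() or np.isnan(c).any() or np.isnan(o).any():
        raise StructureError("missing backbone atoms for hydrogen-bond energy")
    if np.isnan(h).any():
        return 0.0  # N-terminal residue or proline-like: no amide H, no bond
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom clash; treated as bonded, as in the original method
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(bb, n_res: int) -> np.ndarray:
    """hb[a, d] True when CO(a) accepts a bond from NH(d); |a - d| >= 2."""
    hb = np.zeros((n_res, n_res), dtype=bool)
    for a in range(n_res):
        for d in range(n_res):
            if abs(a - d) < 2:
                continue
            if np.isnan(bb["H"][d]).any() or np.isnan(bb["O"][a]).any():
                continue
            try:
                e = _ks_energy(bb, d, a)
            except StructureError:
                continue
            hb[a, d] = e < HBOND_ENERGY_CUTOFF
    return hb


def assign_ss(frame: np.ndarray, topology: Topology) -> np.ndarray:
    """Per-residue secondary-structure labels for one frame."""
    n_res = topology.n_residues
    labels = np.full(n_res, "C", dtype="U1")
    if n_res < 3:
        return labels
    bb = _backbone_positions(topology, frame)
    hb = _hbond_matrix(bb, n_res)

    def turn(i: int, n: int) -> bool:
        return i + n < n_res and hb[i, i + n]

    helix4 = np.zeros(n_res, dtype=bool)
    for i in range(n_res - 5):
        if turn(i, 4) and turn(i + 1, 4):
            helix4[i + 1 : i + 5] = True
    helix3 = np.zeros(n_res, dtype=bool)
    for i in range(n_res - 4):
        if turn(i, 3) and turn(i + 1, 3):
            helix3[i + 1 : i + 4] = True

    strand = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                strand[i] = strand[j] = True

    turn_any = np.zeros(n_res, dtype=bool)
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if turn(i, n):
                turn_any[i + 1 : i + n] = True

    bend = np.zeros(n_res, dtype=bool)
    ca = bb["CA"]
    for i in range(2, n_res - 2):
        v1 = ca[i] - ca[i - 2]
        v2 = ca[i + 2] - ca[i]
        if np.isnan(v1).any() or np.isnan(v2).any():
            continue
        nv1, nv2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if nv1 < 1e-8 or nv2 < 1e-8:
            continue
        ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (nv1 * nv2), -1, 1)))
        bend[i] = ang > 70.0

    labels[bend] = "S"
    labels[turn_any & ~bend] = "T"
    labels[turn_any & bend] = "T"
    labels[strand] = "E"
    labels[helix3] = "G"
    labels[helix4] = "H"
    return labels


def ss_timeline(trajectory: Trajectory, stride: int = 1) -> SSAssignment:
    """Secondary-structure assignment of every stride-th frame."""
    frames = np.arange(0, trajectory.n_frames, stride)
    labels = np.stack(
        [assign_ss(trajectory.coordinates[f], trajectory.topology) for f in frames]
    )
    return SSAssignment(labels=labels, frame_ids=frames, time_ps=trajectory.time_ps[frames])


def ss_fraction(assignment: SSAssignment | np.ndarray, classes=("H", "G", "E")) -> float:
    """Mean over frames of the per-frame fraction of residues in ``classes``."""
    classes = tuple(classes)
    if len(classes) == 0:
        raise ValueError("empty class set")
    labels = assignment.labels if isinstance(assignment, SSAssignment) else np.atleast_2d(assignment)
    hits = np.isin(labels, classes)
    return float(hits.mean())


def ss_occupancy(assignment: SSAssignment) -> pd.DataFrame:
    """Per-residue occupancy of each label over the sampled frames."""
    n_res = assignment.labels.shape[1]
    rows = []
    for r in range(n_res):
        col = assignment.labels[:, r]
        row = {"residue": r}
        for lab in "HGETSC":
            row[lab] = float(np.mean(col == lab))
        rows.append(row)
    return pd.DataFrame(rows)
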