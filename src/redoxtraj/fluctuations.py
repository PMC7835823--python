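"""Least-squares superposition, RMSD series and RMSF profiles.

Rigid-body motion is removed by a Kabsch fit (proper rotations only —
reflections are never allowed, preserving chirality).  RMSD series support
split fit/measure masks so that the rigid-body displacement of one domain
relative to another can be tracked: fit on domain A, measure on domain B.
The RMSF profile supports the high-fluctuation exclusion rule (atoms with
RMSF above a threshold, 4 Angstrom by default, are dropped from a mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SelectionMask, StructureError, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "superpose",
    "apply_superposition",
    "fit_frames",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "high_fluctuation_mask",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom, over the fitted atoms


@dataclass(frozen=True)
class RmsdSeries:
    values: np.ndarray  # per-frame RMSD, Angstrom
    fit_mask: np.ndarray
    measure_mask: np.ndarray
    reference_frame: int
    time_ps: np.ndarray


@dataclass(frozen=True)
class RmsfProfile:
    values: np.ndarray  # per-selected-atom fluctuation, Angstrom
    atom_indices: np.ndarray
    reference: str  # "initial" or "mean"


def _as_indices(mask, n_atoms: int) -> np.ndarray:
    if mask is None:
        return np.arange(n_atoms)
    return np.asarray(mask, dtype=int)


def _check_fit_points(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise StructureError("superposition needs at least 3 atoms")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise StructureError("superposition atoms are collinear (degenerate fit)")


def superpose(mobile: np.ndarray, reference: np.ndarray, mask=None) -> SuperpositionResult:
    """Optimal proper-rotation + translation of ``mobile`` onto ``reference``.

    The returned RMSD is the global least-squares minimum over rigid motions
    (Kabsch); reflections are excluded by construction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _as_indices(mask, mobile.shape[0])
    x = mobile[idx]
    y = reference[idx]
    _check_fit_points(x)
    _check_fit_points(y)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    rot = _kabsch_rotation(x - xc, y - yc)
    translation = yc - xc @ rot.T
    fitted = x @ rot.T + translation
    value = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=value)


def _kabsch_rotation(xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |R xc_i - yc_i|^2 for centered point sets."""
    h = yc.T @ xc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    diag = np.array([1.0, 1.0, d])
    return u @ np.diag(diag) @ vt


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


def batch_rmsd(coordinates: np.ndarray, reference: np.ndarray, mask=None) -> np.ndarray:
    """Fitted RMSD of every frame to a reference, via batched 3x3 SVDs.

    Equivalent to calling :func:`superpose` frame by frame, but vectorized;
    used by the clustering stages where many thousands of pairwise RMSDs
    are needed.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    idx = _as_indices(mask, coordinates.shape[1])
    x = coordinates[:, idx, :]
    y = np.asarray(reference, dtype=float)[idx]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=0)
    h = np.einsum("fni,nj->fij", xc, yc)  # per-frame correlation (3x3)
    _, s, _ = np.linalg.svd(h)
    det = np.linalg.det(h)
    s_sum = s.sum(axis=1) - 2 * s[:, 2] * (det < 0)
    n = len(idx)
    sq = (np.sum(xc * xc, axis=(1, 2)) + np.sum(yc * yc) - 2 * s_sum) / n
    return np.sqrt(np.clip(sq, 0.0, None))


def fit_frames(
    coordinates: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using ``fit_indices``; all atoms move."""
    out = np.empty_like(coordinates)
    for f in range(coordinates.shape[0]):
        res = superpose(coordinates[f], reference, fit_indices)
        out[f] = apply_superposition(coordinates[f], res)
    return out


def rmsd(a: np.ndarray, b: np.ndarray, mask=None, fit: bool = True) -> float:
    """RMSD between two conformations, fitted (default) or raw."""
    idx = _as_indices(mask, np.asarray(a).shape[0])
    if fit:
        return superpose(a, b, idx).rmsd
    d = np.asarray(a)[idx] - np.asarray(b)[idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: int = 0,
    fit_mask=None,
    measure_mask=None,
) -> RmsdSeries:
    """Per-frame RMSD to a reference frame.

    When ``fit_mask == measure_mask`` (or both None) this is the standard
    fitted RMSD.  When they differ, each frame is superposed on the
    reference using ``fit_mask`` only, and the deviation is then measured
    over ``measure_mask`` without refitting — capturing rigid-body
    displacement of the measured domain relative to the fitted one.
    """
    coords = trajectory.coordinates
    n = trajectory.n_atoms
    fit_idx = _as_indices(fit_mask, n)
    meas_idx = _as_indices(measure_mask if measure_mask is not None else fit_mask, n)
    ref = coords[reference_frame]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        res = superpose(coords[f], ref, fit_idx)
        moved = apply_superposition(coords[f], res)
        d = moved[meas_idx] - ref[meas_idx]
        values[f] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return RmsdSeries(
        values=values,
        fit_mask=fit_idx,
        measure_mask=meas_idx,
        reference_frame=reference_frame,
        time_ps=trajectory.time_ps.copy(),
    )


def rmsf(trajectory: Trajectory, mask=None, reference: str = "mean") -> RmsfProfile:
    """Per-atom root-mean-square fluctuation after removing rigid-body motion.

    ``reference="mean"`` (default) fits frames to the initial conformation,
    forms the time-mean structure, refits to it and measures fluctuation
    about the mean — the variance-minimizing choice.  ``reference="initial"``
    measures fluctuation about frame 0 instead.
    """
    if trajectory.n_frames < 2:
        raise StructureError("RMSF needs at least 2 frames")
    if reference not in ("mean", "initial"):
        raise ValueError("reference must be 'mean' or 'initial'")
    idx = _as_indices(mask, trajectory.n_atoms)
    fitted = fit_frames(trajectory.coordinates, trajectory.coordinates[0], idx)
    if reference == "mean":
        mean = fitted.mean(axis=0)
        fitted = fit_frames(fitted, mean, idx)
        ref = fitted.mean(axis=0)
    else:
        ref = trajectory.coordinates[0]
    dev = fitted[:, idx, :] - ref[idx]
    values = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    return RmsfProfile(values=values, atom_indices=idx, reference=reference)


def high_fluctuation_mask(profile: RmsfProfile, threshold: float = 4.0) -> SelectionMask:
    """Atoms of the profile with RMSF strictly below ``threshold`` (Angstrom).

    The complementary, highly fluctuating atoms are excluded; their count is
    available as ``len(profile.values) - len(result)``.
    """
    keep = profile.atom_indices[profile.values < threshold]
    n_total = int(profile.atom_indices.max()) + 1 if len(profile.atom_indices) else 1
    return SelectionMask(np.sort(keep), max(n_total, len(profile.atom_indices)))
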