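"""Essential dynamics: covariance, PCA, projections and cross-correlation.

The covariance matrix is accumulated over frames after superposing every
frame on a reference conformation (time-mean by default), using the
population (1/F) estimator — the time-average form of the covariance.
Diagonalisation orders eigenvalues descending so the leading eigenvectors
(principal components) carry the largest share of the fluctuation variance.
The dynamic cross-correlation (DCC) coefficient of two atoms i, j is

    CC_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

with dr the displacement from the mean position; values lie in [-1, 1],
+1 fully correlated, -1 fully anticorrelated.  Zero-variance atoms get
CC = 0 by convention (the ratio is undefined there) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import StructureError, Trajectory
from .fluctuations import fit_frames

__all__ = [
    "CovarianceModel",
    "CrossCorrelationMatrix",
    "PCProjection",
    "covariance",
    "pca",
    "cumulative_variance",
    "project",
    "cross_correlation",
    "mode_arrows",
]


@dataclass
class CovarianceModel:
    """Covariance of fitted coordinates with optional eigendecomposition.

    ``matrix`` is 3N x 3N in Angstrom^2 over the masked atoms;
    ``eigenvalues`` (descending) and ``eigenvectors`` (orthonormal columns)
    are populated by :func:`pca`.
    """

    matrix: np.ndarray
    mean: np.ndarray  # (3N,) mean fitted coordinates
    atom_indices: np.ndarray
    reference: str
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass(frozen=True)
class CrossCorrelationMatrix:
    values: np.ndarray  # (n, n) in [-1, 1]
    atom_indices: np.ndarray


@dataclass(frozen=True)
class PCProjection:
    scores: np.ndarray  # (F, m)
    m: int


def _mask_indices(trajectory: Trajectory, mask) -> np.ndarray:
    if mask is None:
        return np.arange(trajectory.n_atoms)
    return np.asarray(mask, dtype=int)


def _fitted_deviations(trajectory: Trajectory, idx: np.ndarray, reference: str, fit: bool = True):
    """Frames superposed on the reference over idx; returns (devs (F,3n), mean (3n,))."""
    coords = trajectory.coordinates
    if not fit:
        x = coords[:, idx, :].reshape(trajectory.n_frames, -1)
        ref_flat = x.mean(axis=0)
        return x - ref_flat, ref_flat
    fitted = fit_frames(coords, coords[0], idx)
    if reference == "mean":
        target = fitted.mean(axis=0)
        fitted = fit_frames(fitted, target, idx)
        ref_flat = fitted[:, idx, :].reshape(len(fitted), -1).mean(axis=0)
    elif reference == "initial":
        ref_flat = fitted[:, idx, :].reshape(len(fitted), -1).mean(axis=0)
    else:
        raise ValueError("reference must be 'mean' or 'initial'")
    x = fitted[:, idx, :].reshape(trajectory.n_frames, -1)
    return x - ref_flat, ref_flat


def covariance(
    trajectory: Trajectory, mask=None, reference: str = "mean", fit: bool = True
) -> CovarianceModel:
    """Population covariance of the fitted trajectory matrix.

    Fitting removes rigid-body motion before accumulation; deviations are
    always taken about the time mean (the estimator of the stationary
    fluctuation), while ``reference`` selects the superposition target.
    ``fit=False`` skips the superposition (for inputs already aligned).
    """
    if trajectory.n_frames < 2:
        raise StructureError("covariance needs at least 2 frames")
    idx = _mask_indices(trajectory, mask)
    dev, mean = _fitted_deviations(trajectory, idx, reference, fit)
    c = dev.T @ dev / dev.shape[0]
    return CovarianceModel(matrix=c, mean=mean, atom_indices=idx, reference=reference)


def pca(model: CovarianceModel) -> CovarianceModel:
    """Diagonalise the covariance; eigenvalues descending, eigenvectors orthonormal."""
    c = model.matrix
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("covariance matrix is not symmetric")
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    model.eigenvalues = np.clip(evals[order], 0.0, None)
    model.eigenvectors = evecs[:, order]
    return model


def cumulative_variance(model: CovarianceModel, m: int) -> float:
    """Fraction of total fluctuation variance carried by the first m modes."""
    if m <= 0:
        raise ValueError("m must be positive")
    if model.eigenvalues is None:
        pca(model)
    lam = model.eigenvalues
    m = min(m, len(lam))
    total = lam.sum()
    if total == 0:
        return 0.0
    return float(lam[:m].sum() / total)


def project(trajectory: Trajectory, model: CovarianceModel, m: int = 2) -> PCProjection:
    """Scores of each frame on the first m principal components."""
    if model.eigenvectors is None:
        pca(model)
    idx = model.atom_indices
    if idx.max() >= trajectory.n_atoms:
        raise ValueError("model mask does not match trajectory")
    dev, _ = _fitted_deviations(trajectory, idx, model.reference)
    if dev.shape[1] != model.matrix.shape[0]:
        raise ValueError("model mask does not match trajectory")
    scores = dev @ model.eigenvectors[:, :m]
    return PCProjection(scores=scores, m=m)


def cross_correlation(
    trajectory: Trajectory, mask=None, reference: str = "mean", fit: bool = True
) -> CrossCorrelationMatrix:
    """Dynamic cross-correlation of per-atom displacement vectors."""
    if trajectory.n_frames < 2:
        raise StructureError("cross-correlation needs at least 2 frames")
    idx = _mask_indices(trajectory, mask)
    dev, _ = _fitted_deviations(trajectory, idx, reference, fit)
    f, n3 = dev.shape
    n = n3 // 3
    dr = dev.reshape(f, n, 3)
    dot = np.einsum("fik,fjk->ij", dr, dr) / f  # <dr_i . dr_j>
    var = np.diag(dot).copy()
    zero = var <= 1e-30
    if zero.any():
        warnings.warn(f"{zero.sum()} zero-variance atoms; their CC set to 0")
        var[zero] = 1.0
    cc = dot / np.sqrt(np.outer(var, var))
    cc[zero, :] = 0.0
    cc[:, zero] = 0.0
    np.fill_diagonal(cc, np.where(zero, 0.0, 1.0))
    return CrossCorrelationMatrix(values=np.clip(cc, -1.0, 1.0), atom_indices=idx)


def mode_arrows(
    model: CovarianceModel, mode: int = 0, amplitude_threshold: float = 2.0
) -> dict[int, np.ndarray]:
    """Per-atom displacement arrows of one PCA mode, scaled by sqrt(eigenvalue).

    Atoms whose arrow amplitude is below ``amplitude_threshold`` (Angstrom,
    default 2) are omitted, matching the usual rendering rule for porcupine
    plots.  Keys are atom indices into the original topology.
    """
    if model.eigenvectors is None:
        pca(model)
    if not 0 <= mode < len(model.eigenvalues):
        raise IndexError(f"mode {mode} out of range")
    vec = model.eigenvectors[:, mode].reshape(-1, 3) * np.sqrt(model.eigenvalues[mode])
    amps = np.linalg.norm(vec, axis=1)
    return {
        int(model.atom_indices[i]): vec[i]
        for i in np.flatnonzero(amps >= amplitude_threshold)
    }
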