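"""Kendall shape-space statistics of landmark configurations.

A configuration of k landmarks in R^3 is reduced to its *preshape* by
centering (translation removed) and scaling to unit centroid size; the
shape is the preshape modulo proper rotations, a point on a manifold of
dimension 3k - 7.  Reflections are NOT quotiented out: the handedness of
molecular landmark sets (e.g. S-Ca-Ca'-S') is physically meaningful.

The geodesic distance between two shapes is

    d(a, b) = arccos( max_{R in SO(3)} <a, b R^T>_F )   in radians,

computed in closed form by singular value decomposition with the
determinant correction that excludes reflections.  On this convention the
distance between the equilateral and a collinear triangle is pi/4; the
classical triangle shape sphere of radius 1/2 is recovered by doubling the
angle (colatitude theta = 2 d from the equilateral pole), which is what the
disk map (phi, theta) -> (r = sin theta, phi) uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import StructureError, Trajectory

__all__ = [
    "PreShape",
    "Embedding",
    "FrechetMeanResult",
    "TriangleDiskPoint",
    "preshape",
    "kendall_distance",
    "distance_matrix",
    "mds_embed",
    "frechet_mean",
    "triangle_disk",
    "shape_trajectory",
    "equilateral_triangle",
    "collinear_triangle",
]


@dataclass(frozen=True)
class PreShape:
    """k x 3 landmark configuration, centered and scaled to unit size."""

    landmarks: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.landmarks, dtype=float)
        object.__setattr__(self, "landmarks", x)
        if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
            raise ValueError("preshape needs a (k>=3) x 3 array")
        if np.linalg.norm(x.mean(axis=0)) > 1e-8:
            raise ValueError("preshape is not centered")
        if abs(np.linalg.norm(x) - 1.0) > 1e-8:
            raise ValueError("preshape is not unit-size")

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]


def preshape(landmarks: np.ndarray) -> PreShape:
    """Center a k x 3 configuration and scale it to unit centroid size."""
    x = np.asarray(landmarks, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("landmarks must be k x 3")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    x = x - x.mean(axis=0)
    size = np.linalg.norm(x)
    if size < 1e-12:
        raise StructureError("degenerate shape: all landmarks coincide")
    return PreShape(x / size)


def _optimal_alignment(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate b onto a over SO(3); returns (b_rotated, cosine similarity)."""
    h = a.T @ b  # 3x3
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s_corr = s.copy()
    s_corr[-1] *= d
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return b @ rot.T, float(s_corr.sum())


def kendall_distance(a: PreShape, b: PreShape) -> float:
    """Geodesic shape distance in radians (proper rotations only).

    Computed through the chord length, d = 2 arcsin(|a - b*|_F / 2) with b*
    the optimally rotated partner — algebraically equal to arccos of the
    alignment score but numerically stable near zero.
    """
    if a.k != b.k:
        raise ValueError("shapes must share the same landmark count k")
    b_al, lam = _optimal_alignment(a.landmarks, b.landmarks)
    if lam >= 0:
        chord = np.linalg.norm(a.landmarks - b_al)
        return float(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))
    return float(np.arccos(np.clip(lam, -1.0, 1.0)))


def distance_matrix(shapes: list[PreShape]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise geodesic distances."""
    ks = {s.k for s in shapes}
    if len(ks) > 1:
        raise ValueError("mixed landmark counts in shape set")
    n = len(shapes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kendall_distance(shapes[i], shapes[j])
    return d


# ---------------------------------------------------------------------------
# Metric MDS (Torgerson initialisation + SMACOF majorization)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Embedding:
    points: np.ndarray  # (n, dim)
    stress: float  # sum over ordered pairs of (d_ij - |x_i - x_j|)^2
    seed: int | None


def _raw_stress(d: np.ndarray, x: np.ndarray) -> float:
    diff = x[:, None, :] - x[None, :, :]
    emb = np.sqrt(np.sum(diff * diff, axis=2))
    return float(np.sum((d - emb) ** 2))  # ordered pairs; diagonal contributes 0


def _torgerson(d: np.ndarray, dim: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def mds_embed(
    matrix: np.ndarray,
    dim: int = 2,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-12,
) -> Embedding:
    """Metric MDS minimizing the squared-discrepancy stress.

    Classical (Torgerson) scaling provides the initial configuration, which
    SMACOF majorization then refines; the iteration never increases the
    stress, so Euclidean-realizable inputs embed exactly.
    """
    d = np.asarray(matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    x0 = _torgerson(d, dim)
    stress0 = _raw_stress(d, x0)
    if stress0 > 0 and d.shape[0] > dim + 1:
        from sklearn.manifold import smacof

        x1, _ = smacof(
            d,
            n_components=dim,
            init=x0,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            metric=True,
            random_state=seed,
        )
        stress1 = _raw_stress(d, x1)
        if stress1 <= stress0:
            return Embedding(points=x1, stress=stress1, seed=seed)
    return Embedding(points=x0, stress=stress0, seed=seed)


# ---------------------------------------------------------------------------
# Riemannian log/exp and the Frechet mean
# ---------------------------------------------------------------------------


def _log_map(mu: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Tangent vector at mu pointing to x (after optimal rotation of x)."""
    x_al, lam = _optimal_alignment(mu, x)
    lam = np.clip(lam, -1.0, 1.0)
    d = np.arccos(lam)
    if d < 1e-14:
        return np.zeros_like(mu)
    v = x_al - lam * mu
    nv = np.linalg.norm(v)
    if nv < 1e-14:
        return np.zeros_like(mu)
    return v * (d / nv)


def _exp_map(mu: np.ndarray, v: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v)
    if nv < 1e-14:
        return mu.copy()
    y = np.cos(nv) * mu + np.sin(nv) * v / nv
    y = y - y.mean(axis=0)
    return y / np.linalg.norm(y)


@dataclass(frozen=True)
class FrechetMeanResult:
    mean: PreShape
    iterations: int
    residual: float  # gradient (mean tangent) norm at convergence


def frechet_mean(
    shapes: list[PreShape], tol: float = 1e-8, max_iter: int = 1000
) -> FrechetMeanResult:
    """Riemannian (Karcher) mean by tangent-space log/exp iteration.

    The mean minimizes the sum of squared geodesic distances.  In the flat
    limit (tiny dispersion) it coincides with the classical arithmetic mean;
    for two shapes it is the geodesic midpoint.
    """
    if not shapes:
        raise ValueError("cannot average an empty shape set")
    ks = {s.k for s in shapes}
    if len(ks) > 1:
        raise ValueError("mixed landmark counts")
    arrays = [s.landmarks for s in shapes]
    mu = arrays[0].copy()
    acc = mu.copy()
    for x in arrays[1:]:
        x_al, _ = _optimal_alignment(mu, x)
        acc += x_al
    acc -= acc.mean(axis=0)
    n = np.linalg.norm(acc)
    if n > 1e-12:
        mu = acc / n
    residual = np.inf
    for it in range(1, max_iter + 1):
        grad = np.zeros_like(mu)
        for x in arrays:
            grad += _log_map(mu, x)
        grad /= len(arrays)
        residual = float(np.linalg.norm(grad))
        if residual < tol:
            return FrechetMeanResult(mean=PreShape(_renorm(mu)), iterations=it, residual=residual)
        mu = _exp_map(mu, grad)
    raise RuntimeError(
        f"Frechet mean did not converge in {max_iter} iterations "
        f"(last gradient norm {residual:.3e})"
    )


def _renorm(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    return x / np.linalg.norm(x)


# ---------------------------------------------------------------------------
# Triangle disk representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleDiskPoint:
    r: float  # sin of the colatitude on the radius-1/2 triangle hemisphere
    phi: float  # longitude (radians), vertex-1 meridian convention


def equilateral_triangle() -> PreShape:
    """The equilateral reference triangle (disk centre), vertex 1 on +y."""
    ang = np.deg2rad([90.0, 210.0, 330.0])
    pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(3)], axis=1)
    return preshape(pts)


def collinear_triangle() -> PreShape:
    """A maximally degenerate (collinear) triangle — the disk rim."""
    return preshape(np.array([[-1.0, 0, 0], [0.0, 0, 0], [1.0, 0, 0]]))


def _horizontal_basis(mu: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the horizontal tangent space at mu (flattened)."""
    k = mu.shape[0]
    flat = mu.reshape(-1)
    # vertical directions: infinitesimal rotations of mu
    gens = []
    for axis in range(3):
        a = np.zeros((3, 3))
        i, j = [(1, 2), (2, 0), (0, 1)][axis]
        a[i, j], a[j, i] = -1.0, 1.0
        gens.append((mu @ a.T).reshape(-1))
    # constraint directions: mu itself (scale) — centering is preserved by
    # construction since mu is centered and rotations keep it so.
    span = np.column_stack([flat] + gens)
    q, _ = np.linalg.qr(span)
    # complement within the centered subspace
    basis = []
    for seed_vec in np.eye(3 * k):
        v = seed_vec.reshape(k, 3)
        v = (v - v.mean(axis=0)).reshape(-1)
        v = v - q @ (q.T @ v)
        for b in basis:
            v = v - b * (b @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            basis.append(v / nv)
    return np.column_stack(basis)


_DISK_CACHE: dict = {}


def _disk_frame() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pole, e1, e2): equilateral pole and the tangent 2-frame fixing phi=0."""
    if "frame" not in _DISK_CACHE:
        pole = equilateral_triangle().landmarks
        basis = _horizontal_basis(pole)  # (9, 2) for k=3
        ref = preshape(np.array([[0.0, 1.6, 0.0], [-0.8, -0.8, 0.0], [0.8, -0.8, 0.0]]))
        t_ref = _log_map(pole, ref.landmarks).reshape(-1)
        c = basis.T @ t_ref
        e1 = (basis @ c) / np.linalg.norm(c)
        e2 = basis @ np.array([-c[1], c[0]]) / np.linalg.norm(c)
        _DISK_CACHE["frame"] = (pole, e1, e2)
    return _DISK_CACHE["frame"]


def triangle_disk(triangle: PreShape) -> TriangleDiskPoint:
    """Map a 3-landmark shape to the unit disk.

    The shape space of triangles is a hemisphere of radius 1/2 with the
    equilateral triangle at the pole and collinear triangles on the equator.
    The colatitude is theta = 2 d(T, equilateral) (our geodesic convention
    is the unit-preshape-sphere angle) and the disk point is
    (r, phi) = (sin theta, longitude).  phi = 0 is the meridian of the
    isosceles triangle elongated along vertex 1.
    """
    if triangle.k != 3:
        raise ValueError("triangle_disk requires exactly 3 landmarks")
    pole, e1, e2 = _disk_frame()
    d = kendall_distance(PreShape(pole), triangle)
    theta = 2.0 * d
    r = float(np.clip(np.sin(theta), 0.0, 1.0))
    t = _log_map(pole, triangle.landmarks).reshape(-1)
    if np.linalg.norm(t) < 1e-12:
        return TriangleDiskPoint(r=r, phi=0.0)
    phi = float(np.arctan2(t @ e2, t @ e1))
    return TriangleDiskPoint(r=r, phi=phi)


# ---------------------------------------------------------------------------
# Shape trajectories
# ---------------------------------------------------------------------------


def shape_trajectory(
    trajectory: Trajectory, mask, metadata_pair: tuple[int, int] | None = None
):
    """One PreShape per frame from the selected landmark atoms.

    Returns ``(shapes, table)`` where the table carries frame ids, times,
    the geodesic distance to the first valid frame and, when
    ``metadata_pair`` names two atoms (e.g. the two sulphurs), their
    per-frame distance in Angstrom.  Degenerate frames are skipped with a
    warning and excluded from the table.
    """
    import pandas as pd

    idx = np.asarray(mask, dtype=int)
    shapes: list[PreShape] = []
    rows = []
    first: PreShape | None = None
    for f in range(trajectory.n_frames):
        pts = trajectory.coordinates[f, idx]
        try:
            s = preshape(pts)
        except StructureError:
            warnings.warn(f"frame {f}: degenerate landmark configuration skipped")
            continue
        if first is None:
            first = s
        row = {
            "frame": f,
            "time_ps": trajectory.time_ps[f],
            "dist_to_first_rad": kendall_distance(first, s),
        }
        if metadata_pair is not None:
            a, b = metadata_pair
            row["pair_distance_A"] = float(
                np.linalg.norm(trajectory.coordinates[f, a] - trajectory.coordinates[f, b])
            )
        shapes.append(s)
        rows.append(row)
    return shapes, pd.DataFrame(rows)
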