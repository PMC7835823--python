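"""Ensemble-based conformational clustering.

Two-step randomized algorithm over Calpha (or any masked) RMSD:

(i)  harvest — pick a random frame as a reference, remove every frame whose
     fitted RMSD to it is within the cut-off r, repeat on the remainder
     until the ensemble is empty.  The surviving references are pairwise
     more than r apart.
(ii) assign — group every frame with the reference of minimal fitted RMSD
     (even when that minimum exceeds r); ties break to the lowest
     reference index.

Cut-off scans, merged-replica composition tables, medoid representatives
and time-localisation of clusters complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StructureError, Trajectory
from .fluctuations import batch_rmsd, superpose

__all__ = [
    "ClusterModel",
    "harvest_references",
    "assign_clusters",
    "cluster_scan",
    "merge_and_compose",
    "representative",
    "cluster_timeline",
    "DENSITY_FLOOR_PERCENT",
    "DEFAULT_CUTOFF_GRID",
]

# Dense-cluster population floor (percent) and the canonical cut-off scan
# grid: 1.6 to 3.0 Angstrom in steps of 0.2.
DENSITY_FLOOR_PERCENT = 4.0
DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(1.6, 3.01, 0.2), 1))


@dataclass
class ClusterModel:
    cutoff: float
    reference_frames: np.ndarray  # frame ids of the harvested references
    assignments: np.ndarray  # per-frame cluster index
    populations: np.ndarray  # per-cluster % of frames (sums to 100)
    seed: int | None = None
    source_ids: np.ndarray | None = None  # per-frame source trajectory (merged runs)

    @property
    def n_clusters(self) -> int:
        return len(self.reference_frames)

    def composition(self) -> pd.DataFrame | None:
        """Cluster x source percentage table (merged runs only)."""
        if self.source_ids is None:
            return None
        sources = np.unique(self.source_ids)
        rows = []
        for c in range(self.n_clusters):
            members = self.source_ids[self.assignments == c]
            total = max(len(members), 1)
            rows.append([100.0 * np.sum(members == s) / total for s in sources])
        return pd.DataFrame(rows, columns=[f"source_{s}" for s in sources])


def _pairwise_rmsd_to(coords: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return batch_rmsd(coords, ref, idx)


def _mask_idx(trajectory: Trajectory, mask) -> np.ndarray:
    if mask is None:
        return np.arange(trajectory.n_atoms)
    return np.asarray(mask, dtype=int)


def harvest_references(
    trajectory: Trajectory, mask=None, cutoff: float = 2.0, seed: int | None = None
) -> np.ndarray:
    """Step (i): random reference harvesting at cut-off r.

    Returns frame ids whose pairwise fitted RMSD exceeds ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if trajectory.n_frames < 1:
        raise StructureError("empty trajectory")
    idx = _mask_idx(trajectory, mask)
    rng = np.random.default_rng(seed)
    remaining = np.arange(trajectory.n_frames)
    references: list[int] = []
    coords = trajectory.coordinates
    while len(remaining):
        pick = int(remaining[rng.integers(len(remaining))])
        references.append(pick)
        d = _pairwise_rmsd_to(coords[remaining], coords[pick], idx)
        remaining = remaining[d > cutoff]
    return np.array(sorted(references))


def assign_clusters(
    trajectory: Trajectory,
    mask=None,
    references: np.ndarray | None = None,
    cutoff: float = 2.0,
    seed: int | None = None,
    source_ids: np.ndarray | None = None,
) -> ClusterModel:
    """Step (ii): group every frame with its nearest reference by fitted RMSD."""
    if references is None:
        references = harvest_references(trajectory, mask, cutoff, seed)
    references = np.asarray(references, dtype=int)
    if len(references) == 0:
        raise ValueError("no reference structures")
    idx = _mask_idx(trajectory, mask)
    coords = trajectory.coordinates
    dists = np.stack(
        [_pairwise_rmsd_to(coords, coords[r], idx) for r in references], axis=1
    )
    assignments = np.argmin(dists, axis=1)  # argmin takes the lowest index on ties
    populations = np.array(
        [100.0 * np.sum(assignments == c) / trajectory.n_frames for c in range(len(references))]
    )
    return ClusterModel(
        cutoff=cutoff,
        reference_frames=references,
        assignments=assignments,
        populations=populations,
        seed=seed,
        source_ids=None if source_ids is None else np.asarray(source_ids),
    )


def cluster_scan(
    trajectory: Trajectory,
    mask=None,
    cutoffs=DEFAULT_CUTOFF_GRID,
    seed: int | None = None,
    density_floor: float = DENSITY_FLOOR_PERCENT,
) -> pd.DataFrame:
    """Cluster at each cut-off; report cluster counts and the cumulative
    population of clusters denser than ``density_floor`` percent."""
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must be nonempty")
    rows = []
    for i, r in enumerate(cutoffs):
        sub_seed = None if seed is None else seed + i
        model = assign_clusters(trajectory, mask, cutoff=float(r), seed=sub_seed)
        dense = model.populations[model.populations > density_floor]
        rows.append(
            {
                "cutoff_A": float(r),
                "n_clusters": model.n_clusters,
                "n_dense_clusters": len(dense),
                "dense_cumulative_percent": float(dense.sum()),
            }
        )
    return pd.DataFrame(rows)


def merge_and_compose(
    trajectories: list[Trajectory],
    mask=None,
    cutoff: float = 2.0,
    seed: int | None = None,
) -> ClusterModel:
    """Cluster the merged trajectory of several replicas and tabulate, per
    cluster, the percentage contributed by each source replica."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    topo = trajectories[0].topology
    for t in trajectories[1:]:
        if t.topology.n_atoms != topo.n_atoms or not np.array_equal(
            t.topology.atom_names, topo.atom_names
        ):
            raise StructureError("trajectories must share an identical topology")
    coords = np.concatenate([t.coordinates for t in trajectories], axis=0)
    n_frames = coords.shape[0]
    merged = Trajectory(coords, np.arange(n_frames, dtype=float), topo)
    source_ids = np.concatenate(
        [np.full(t.n_frames, i, dtype=int) for i, t in enumerate(trajectories)]
    )
    model = assign_clusters(merged, mask, cutoff=cutoff, seed=seed)
    model.source_ids = source_ids
    return model


def representative(trajectory: Trajectory, model: ClusterModel, cluster: int, mask=None) -> int:
    """Medoid frame of a cluster: minimal mean fitted RMSD to all members.

    Ties break to the lowest frame id.
    """
    members = np.flatnonzero(model.assignments == cluster)
    if len(members) == 0:
        raise ValueError(f"cluster {cluster} is empty")
    if len(members) == 1:
        return int(members[0])
    idx = _mask_idx(trajectory, mask)
    coords = trajectory.coordinates
    mean_d = np.empty(len(members))
    for a, fa in enumerate(members):
        d = _pairwise_rmsd_to(coords[members], coords[fa], idx)
        mean_d[a] = d.mean()
    return int(members[np.argmin(mean_d)])


def cluster_timeline(model: ClusterModel, time_ps: np.ndarray) -> pd.DataFrame:
    """Per-frame (time, cluster) table ordered by time."""
    df = pd.DataFrame(
        {
            "frame": np.arange(len(model.assignments)),
            "time_ps": np.asarray(time_ps, dtype=float),
            "cluster": model.assignments,
        }
    )
    if model.source_ids is not None:
        df["source"] = model.source_ids
    return df.sort_values("time_ps", kind="stable").reset_index(drop=True)
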