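"""Configuration-driven orchestration of the analysis stages.

A single YAML (or dict) configuration selects inputs, named atom
selections, the analyses to run and their parameters.  Stages execute in
dependency order (fit -> fluctuations -> covariance/PCA/CC -> clustering ->
geometry -> shapes -> contacts -> secondary structure), each writing
plot-ready CSV tables and JSON summaries into the output directory; a
manifest records inputs, a configuration hash, seeds and every produced
file, so a re-run with identical config and seeds reproduces deterministic
outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import assign_clusters, cluster_scan, cluster_timeline, representative
from .collective import covariance, cross_correlation, cumulative_variance, pca, project
from .contacts import contact_map, contacts_table, interface_contacts, interface_summary
from .core import Trajectory, read_structure, select
from .fluctuations import high_fluctuation_mask, rmsd_series, rmsf
from .geometry import axis_drift, motif_series
from .secondary import ss_fraction, ss_occupancy, ss_timeline

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline", "annotate_schedule", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (see ``from_dict`` for the schema)."""

    inputs: list  # list of {path, format}
    selections: dict  # name -> selection expression
    analyses: dict  # analysis name -> parameter dict
    seed: int | None = None
    trim_ps: float = 0.0
    schedule: list = field(default_factory=list)  # [{label, start_ps, end_ps}]
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "AnalysisConfig":
        if "input" in cfg:
            inputs = [cfg["input"]]
        elif "inputs" in cfg:
            inputs = list(cfg["inputs"])
        else:
            raise ConfigError("config needs 'input' or 'inputs'")
        for item in inputs:
            if "path" not in item:
                raise ConfigError("every input needs a 'path'")
        analyses = cfg.get("analyses", {})
        if not isinstance(analyses, dict) or not analyses:
            raise ConfigError("config needs a nonempty 'analyses' mapping")
        schedule = cfg.get("schedule", [])
        _validate_schedule(schedule)
        return cls(
            inputs=inputs,
            selections=dict(cfg.get("selections", {})),
            analyses=dict(analyses),
            seed=cfg.get("seed"),
            trim_ps=float(cfg.get("trim_ps", 0.0)),
            schedule=schedule,
            raw=cfg,
        )

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
        return cls.from_dict(cfg)

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _validate_schedule(schedule) -> None:
    prev_end = None
    for seg in schedule:
        for key in ("label", "start_ps", "end_ps"):
            if key not in seg:
                raise ConfigError(f"schedule segment missing {key!r}")
        if seg["end_ps"] <= seg["start_ps"]:
            raise ConfigError("schedule segment must have end_ps > start_ps")
        if prev_end is not None and seg["start_ps"] != prev_end:
            raise ConfigError("schedule segments must be contiguous (no gaps or overlaps)")
        prev_end = seg["end_ps"]


def annotate_schedule(trajectory: Trajectory, schedule) -> np.ndarray:
    """Label each frame by the schedule segment covering its timestamp.

    Segments are half-open [start_ps, end_ps); frames outside every segment
    (or all frames when the schedule is empty) get the empty label.
    """
    _validate_schedule(schedule)
    labels = np.full(trajectory.n_frames, "", dtype="U16")
    for seg in schedule:
        sel = (trajectory.time_ps >= seg["start_ps"]) & (trajectory.time_ps < seg["end_ps"])
        labels[sel] = seg["label"]
    return labels


@dataclass
class ReportBundle:
    directory: Path
    manifest: dict

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.manifest["stages"].values())


def _resolve_mask(topology, selections: dict, name, cache: dict):
    if name is None:
        return None
    if name in cache:
        return cache[name]
    if name not in selections:
        raise ConfigError(f"selection {name!r} is not defined")
    mask = select(topology, selections[name])
    cache[name] = mask
    return mask


def _trim(traj: Trajectory, trim_ps: float) -> Trajectory:
    if trim_ps <= 0:
        return traj
    keep = traj.time_ps >= trim_ps
    if not keep.any():
        raise ConfigError("equilibration trim removes every frame")
    return Trajectory(traj.coordinates[keep], traj.time_ps[keep], traj.topology)


# stage implementations -----------------------------------------------------


def _stage_rmsd(traj, topo, cfg, masks, outdir, seed):
    series = rmsd_series(
        traj,
        reference_frame=int(cfg.get("reference_frame", 0)),
        fit_mask=masks.get("fit"),
        measure_mask=masks.get("measure", masks.get("fit")),
    )
    df = pd.DataFrame({"frame": np.arange(len(series.values)),
                       "time_ps": series.time_ps, "rmsd_A": series.values})
    path = outdir / "rmsd.csv"
    df.to_csv(path, index=False)
    return [path], {"mean_rmsd_A": float(series.values.mean())}


def _stage_rmsf(traj, topo, cfg, masks, outdir, seed):
    profile = rmsf(traj, masks.get("mask"), reference=cfg.get("reference", "mean"))
    df = pd.DataFrame({"atom_index": profile.atom_indices, "rmsf_A": profile.values})
    path = outdir / "rmsf.csv"
    df.to_csv(path, index=False)
    threshold = float(cfg.get("exclusion_threshold_A", 4.0))
    kept = high_fluctuation_mask(profile, threshold)
    return [path], {
        "excluded_atoms": int(len(profile.values) - len(kept)),
        "threshold_A": threshold,
    }


def _stage_pca(traj, topo, cfg, masks, outdir, seed):
    model = pca(covariance(traj, masks.get("mask"), reference=cfg.get("reference", "mean")))
    n_modes = int(cfg.get("n_modes", 10))
    lam = model.eigenvalues[:n_modes]
    df = pd.DataFrame(
        {
            "mode": np.arange(1, len(lam) + 1),
            "eigenvalue_A2": lam,
            "cumulative_fraction": [cumulative_variance(model, m) for m in range(1, len(lam) + 1)],
        }
    )
    path = outdir / "pca_spectrum.csv"
    df.to_csv(path, index=False)
    proj = project(traj, model, m=min(3, n_modes))
    pdf = pd.DataFrame(proj.scores, columns=[f"pc{i+1}" for i in range(proj.scores.shape[1])])
    pdf.insert(0, "frame", np.arange(len(pdf)))
    ppath = outdir / "pca_projection.csv"
    pdf.to_csv(ppath, index=False)
    return [path, ppath], {"cumulative_variance_10": cumulative_variance(model, 10)}


def _stage_cross_correlation(traj, topo, cfg, masks, outdir, seed):
    cc = cross_correlation(traj, masks.get("mask"), reference=cfg.get("reference", "mean"))
    path = outdir / "cross_correlation.csv"
    pd.DataFrame(cc.values).to_csv(path, index=False)
    return [path], {"n_atoms": len(cc.atom_indices)}


def _stage_clustering(traj, topo, cfg, masks, outdir, seed):
    stage_seed = int(cfg.get("seed", seed if seed is not None else 0))
    cutoff = float(cfg.get("cutoff", 2.0))
    model = assign_clusters(traj, masks.get("mask"), cutoff=cutoff, seed=stage_seed)
    timeline = cluster_timeline(model, traj.time_ps)
    tpath = outdir / "cluster_timeline.csv"
    timeline.to_csv(tpath, index=False)
    reps = {c: representative(traj, model, c, masks.get("mask")) for c in range(model.n_clusters)}
    files = [tpath]
    summary = {
        "cutoff_A": cutoff,
        "seed": stage_seed,
        "n_clusters": model.n_clusters,
        "populations_percent": [round(float(p), 3) for p in model.populations],
        "representatives": {str(k): int(v) for k, v in reps.items()},
    }
    if cfg.get("scan"):
        scan = cluster_scan(traj, masks.get("mask"), cutoffs=list(cfg["scan"]), seed=stage_seed)
        spath = outdir / "cluster_scan.csv"
        scan.to_csv(spath, index=False)
        files.append(spath)
    return files, summary


def _stage_motif(traj, topo, cfg, masks, outdir, seed):
    sulphurs = tuple(cfg["sulphur_atoms"])
    alphas = tuple(cfg["alpha_atoms"])
    df = motif_series(traj, sulphurs, alphas)
    path = outdir / "motif_geometry.csv"
    df.to_csv(path, index=False)
    return [path], {
        "mean_d_SS_A": float(df["d_SS_A"].mean()),
        "class_counts": df["class"].value_counts().to_dict(),
    }


def _stage_helix_drift(traj, topo, cfg, masks, outdir, seed):
    residues = cfg["residue_indices"]
    df = axis_drift(traj, topo, residues, fit_mask=masks.get("fit"))
    path = outdir / "helix_drift.csv"
    df.to_csv(path, index=False)
    return [path], {"n_frames": traj.n_frames}


def _stage_contacts(traj, topo, cfg, masks, outdir, seed):
    stride = int(cfg.get("stride", 1))
    cmap = contact_map(traj, stride=stride)
    path = outdir / "contact_map.csv"
    pd.DataFrame(cmap.occupancy).to_csv(path, index=False)
    summary = {"n_frames_sampled": cmap.n_frames_sampled}
    files = [path]
    if "interface" in cfg:
        a, b = cfg["interface"]["chain_a"], cfg["interface"]["chain_b"]
        recs = interface_contacts(traj.coordinates[0], topo, a, b, frame_id=0)
        tab = contacts_table(recs)
        ipath = outdir / "interface_contacts.csv"
        tab.to_csv(ipath, index=False)
        files.append(ipath)
        summary["interface"] = interface_summary(recs)
    return files, summary


def _stage_secondary_structure(traj, topo, cfg, masks, outdir, seed):
    stride = int(cfg.get("stride", 1))
    assignment = ss_timeline(traj, stride=stride)
    occ = ss_occupancy(assignment)
    path = outdir / "ss_occupancy.csv"
    occ.to_csv(path, index=False)
    rows = []
    for fi, f in enumerate(assignment.frame_ids):
        for r in range(assignment.labels.shape[1]):
            rows.append((int(f), float(assignment.time_ps[fi]), r, assignment.labels[fi, r]))
    tl = pd.DataFrame(rows, columns=["frame", "time_ps", "residue", "label"])
    tpath = outdir / "ss_timeline.csv"
    tl.to_csv(tpath, index=False)
    return [path, tpath], {
        "folded_fraction_HGE": ss_fraction(assignment, ("H", "G", "E")),
    }


_STAGES = {
    "rmsd": (_stage_rmsd, ("fit", "measure")),
    "rmsf": (_stage_rmsf, ("mask",)),
    "pca": (_stage_pca, ("mask",)),
    "cross_correlation": (_stage_cross_correlation, ("mask",)),
    "clustering": (_stage_clustering, ("mask",)),
    "motif": (_stage_motif, ()),
    "helix_drift": (_stage_helix_drift, ("fit",)),
    "contacts": (_stage_contacts, ()),
    "secondary_structure": (_stage_secondary_structure, ()),
}

# execution order respects stage dependencies
_STAGE_ORDER = [
    "rmsd",
    "rmsf",
    "pca",
    "cross_correlation",
    "clustering",
    "motif",
    "helix_drift",
    "contacts",
    "secondary_structure",
]


def run_pipeline(config: AnalysisConfig | dict | str | Path, outdir) -> ReportBundle:
    """Execute the configured analyses and write a report bundle.

    A failed stage is recorded in the manifest with its error; the bundle
    is then marked partial (``bundle.ok`` is False) and remaining stages
    still run.
    """
    if isinstance(config, (str, Path)):
        config = AnalysisConfig.from_file(config)
    elif isinstance(config, dict):
        config = AnalysisConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    unknown = set(config.analyses) - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown analyses: {sorted(unknown)}")

    topo, traj = read_structure(config.inputs[0]["path"], config.inputs[0].get("format"))
    extra = []
    for item in config.inputs[1:]:
        _, t = read_structure(item["path"], item.get("format"))
        extra.append(t)
    traj = _trim(traj, config.trim_ps)

    mask_cache: dict = {}
    manifest = {
        "package": "redoxtraj",
        "version": __version__,
        "config_hash": config.config_hash(),
        "inputs": [str(i["path"]) for i in config.inputs],
        "seed": config.seed,
        "stages": {},
        "files": [],
    }
    if config.schedule:
        labels = annotate_schedule(traj, config.schedule)
        sched = pd.DataFrame(
            {"frame": np.arange(traj.n_frames), "time_ps": traj.time_ps, "segment": labels}
        )
        spath = outdir / "schedule_segments.csv"
        sched.to_csv(spath, index=False)
        manifest["files"].append(spath.name)

    for name in _STAGE_ORDER:
        if name not in config.analyses:
            continue
        stage_cfg = config.analyses[name] or {}
        fn, mask_keys = _STAGES[name]
        t0 = time.perf_counter()
        try:
            masks = {
                key: _resolve_mask(topo, config.selections, stage_cfg.get(key), mask_cache)
                for key in mask_keys
            }
            files, summary = fn(traj, topo, stage_cfg, masks, outdir, config.seed)
            manifest["stages"][name] = {
                "status": "ok",
                "summary": summary,
                "files": [f.name for f in files],
                "wall_s": round(time.perf_counter() - t0, 4),
            }
            manifest["files"].extend(f.name for f in files)
        except Exception as exc:  # recorded, pipeline continues
            manifest["stages"][name] = {
                "status": "error",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=3),
                "wall_s": round(time.perf_counter() - t0, 4),
            }

    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"].append(mpath.name)
    return ReportBundle(directory=outdir, manifest=manifest)
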