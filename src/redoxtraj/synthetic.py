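"""Synthetic trajectories and structures with known ground truth.

Every downstream analysis stage is testable against these generators: they
plant the quantity the analysis must recover (a covariance spectrum, state
occupancies, a contact list, a motif geometry) and emit it alongside the
data.  All generators are deterministic under a fixed seed.  The fixtures
are geometric, not physical: no force field, solvent or membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import StructureError, Topology, Trajectory
from .fluctuations import superpose
from .shapes import PreShape, preshape

__all__ = [
    "GaussianEnsembleSpec",
    "MultiStateSpec",
    "PlantedContact",
    "PlantedInterfaceSpec",
    "make_gaussian_ensemble",
    "make_multistate_trajectory",
    "displaced_states",
    "make_ideal_helix",
    "make_motif",
    "make_planted_interface",
    "make_thiol_pair_trajectory",
    "make_synthetic_bvkor_cys",
    "sample_shapes",
    "chain_topology",
    "rigid_body_complement",
]


def chain_topology(n_atoms: int, atom_name: str = "CA", element: str = "C",
                   res_name: str = "ALA", chain: str = "A") -> Topology:
    """One-atom-per-residue polymer topology (default: a Calpha trace)."""
    return Topology(
        atom_names=np.full(n_atoms, atom_name),
        elements=np.full(n_atoms, element),
        atom_residue=np.arange(n_atoms),
        res_names=np.full(n_atoms, res_name),
        res_numbers=np.arange(1, n_atoms + 1),
        chain_ids=np.full(n_atoms, chain),
    )


def rigid_body_complement(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N x 3N-6) orthogonal to rigid-body modes.

    Rigid translations and infinitesimal rotations of the reference span a
    6-dimensional subspace; displacement fields planted in the complement
    survive the superposition step of downstream analyses essentially
    unchanged, so planted covariance spectra are recoverable.
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    modes = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        modes.append(t.reshape(-1))
    for ax in range(3):
        a = np.zeros((3, 3))
        i, j = [(1, 2), (2, 0), (0, 1)][ax]
        a[i, j], a[j, i] = -1.0, 1.0
        modes.append((centered @ a.T).reshape(-1))
    m = np.column_stack(modes)
    q, _ = np.linalg.qr(m)
    full = np.eye(3 * n)
    proj = full - q @ q.T
    u, s, _ = np.linalg.svd(proj)
    return u[:, s > 1e-8]


# ---------------------------------------------------------------------------
# Gaussian fluctuation ensembles
# ---------------------------------------------------------------------------


@dataclass
class GaussianEnsembleSpec:
    """Stationary Gaussian ensemble about a reference conformation.

    Provide either a full 3N x 3N covariance or a planted spectrum:
    ``eigenvalues`` (A^2, descending) with optional orthonormal
    ``directions`` (3N x m).  When directions are omitted they are drawn
    (seeded) from the rigid-body complement of the reference so the
    spectrum survives superposition.
    """

    reference: np.ndarray  # (N, 3) Angstrom
    n_frames: int
    seed: int
    eigenvalues: np.ndarray | None = None
    directions: np.ndarray | None = None
    covariance: np.ndarray | None = None

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float)
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.covariance is None and self.eigenvalues is None:
            raise ValueError("provide a covariance or a planted spectrum")
        if self.covariance is not None:
            c = np.asarray(self.covariance, dtype=float)
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("covariance must be positive semi-definite")
            self.covariance = c
        if self.eigenvalues is not None:
            ev = np.asarray(self.eigenvalues, dtype=float)
            if (ev < 0).any():
                raise ValueError("eigenvalues must be nonnegative")
            self.eigenvalues = ev


def make_gaussian_ensemble(spec: GaussianEnsembleSpec) -> Trajectory:
    """Sample frames ref + sum_k sqrt(lambda_k) z_k q_k, z ~ N(0,1)."""
    rng = np.random.default_rng(spec.seed)
    ref_flat = spec.reference.reshape(-1)
    n3 = ref_flat.shape[0]
    if spec.covariance is not None:
        evals, evecs = np.linalg.eigh(spec.covariance)
        evals = np.clip(evals, 0.0, None)
        q = evecs
        lam = evals
    else:
        lam = spec.eigenvalues
        if spec.directions is not None:
            q = np.asarray(spec.directions, dtype=float)
            if q.shape != (n3, len(lam)):
                raise ValueError("directions must be 3N x m, matching the spectrum")
            if not np.allclose(q.T @ q, np.eye(len(lam)), atol=1e-8):
                raise ValueError("directions must be orthonormal")
        else:
            basis = rigid_body_complement(spec.reference)
            if len(lam) > basis.shape[1]:
                raise ValueError("spectrum longer than the rigid-body complement")
            gauss = rng.standard_normal((basis.shape[1], len(lam)))
            q_sub, _ = np.linalg.qr(gauss)
            q = basis @ q_sub
    z = rng.standard_normal((spec.n_frames, len(lam)))
    frames = ref_flat + (z * np.sqrt(lam)) @ q.T
    coords = frames.reshape(spec.n_frames, -1, 3)
    topo = chain_topology(spec.reference.shape[0])
    return Trajectory(coords, np.arange(spec.n_frames, dtype=float), topo)


# ---------------------------------------------------------------------------
# Multi-state (conformational switching) trajectories
# ---------------------------------------------------------------------------


@dataclass
class MultiStateSpec:
    """m-state switching ensemble with isotropic per-atom jitter.

    States are visited i.i.d. with ``occupancies`` unless a row-stochastic
    ``transition_matrix`` is given, in which case a Markov chain is
    simulated from ``start_state``.  Pairwise fitted inter-state RMSDs are
    recorded in ``inter_state_rmsd`` at construction as ground truth.
    """

    states: np.ndarray  # (m, N, 3)
    n_frames: int
    seed: int
    occupancies: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    jitter_sd: float = 0.3  # Angstrom, per atom per coordinate
    start_state: int = 0
    inter_state_rmsd: np.ndarray = field(init=False)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        m = self.states.shape[0]
        if self.occupancies is None and self.transition_matrix is None:
            self.occupancies = np.full(m, 1.0 / m)
        if self.occupancies is not None:
            occ = np.asarray(self.occupancies, dtype=float)
            if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
                raise ValueError("occupancies must be nonnegative and sum to 1")
            self.occupancies = occ
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            if t.shape != (m, m) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition matrix must be m x m row-stochastic")
            self.transition_matrix = t
        d = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d[i, j] = d[j, i] = superpose(self.states[i], self.states[j]).rmsd
        self.inter_state_rmsd = d


def make_multistate_trajectory(spec: MultiStateSpec) -> tuple[Trajectory, np.ndarray]:
    """Sample the switching trajectory; returns (trajectory, state labels)."""
    rng = np.random.default_rng(spec.seed)
    m = spec.states.shape[0]
    if spec.transition_matrix is not None:
        labels = np.empty(spec.n_frames, dtype=int)
        labels[0] = spec.start_state
        for f in range(1, spec.n_frames):
            labels[f] = rng.choice(m, p=spec.transition_matrix[labels[f - 1]])
    else:
        labels = rng.choice(m, size=spec.n_frames, p=spec.occupancies)
    coords = spec.states[labels] + rng.normal(0.0, spec.jitter_sd, (spec.n_frames,) + spec.states.shape[1:])
    topo = chain_topology(spec.states.shape[1])
    return Trajectory(coords, np.arange(spec.n_frames, dtype=float), topo), labels


def displaced_states(
    reference: np.ndarray, m: int, target_rmsd: float, seed: int
) -> np.ndarray:
    """m state structures whose pairwise *fitted* RMSD equals target_rmsd.

    Displacement fields live in the rigid-body complement of the reference
    and are rescaled (1-D root find) until the Kabsch-fitted RMSD between
    every state pair matches the target within 1e-3 A.
    """
    ref = np.asarray(reference, dtype=float)
    n = ref.shape[0]
    rng = np.random.default_rng(seed)
    basis = rigid_body_complement(ref)
    raw = basis @ rng.standard_normal((basis.shape[1], m))
    raw, _ = np.linalg.qr(raw)  # orthogonal displacement directions
    fields = raw.T.reshape(m, n, 3)

    def worst_misfit(scale: float) -> float:
        states = ref + scale * fields
        d = [
            superpose(states[i], states[j]).rmsd
            for i in range(m)
            for j in range(i + 1, m)
        ]
        return min(d) - target_rmsd

    hi = target_rmsd * math.sqrt(n) * 4
    scale = brentq(worst_misfit, 1e-6, hi, xtol=1e-6)
    return ref + scale * fields


# ---------------------------------------------------------------------------
# Ideal helices and extended chains (internal-coordinate construction)
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.01}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8}
# phi/psi pairs reproducing the canonical helix parameters
# (alpha: 1.5 A rise / 100 deg twist; 3_10: ~2 A rise / 120 deg twist).
_TORSIONS = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "extended": (180.0, 180.0),
}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of a new atom bonded to c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_ideal_helix(n_residues: int, kind: str = "alpha") -> tuple[Topology, Trajectory]:
    """Ideal polyalanine backbone: N, H, CA, C, O per residue.

    ``kind`` is one of ``alpha``, ``three_ten``, ``extended``.  The first
    residue carries no amide hydrogen.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if kind not in _TORSIONS:
        raise ValueError(f"unknown helix kind {kind!r}")
    phi, psi = _TORSIONS[kind]
    omega = 180.0

    backbone: list[np.ndarray] = [
        np.array([0.0, 0.0, 0.0]),  # N0
        np.array([_BOND["N-CA"], 0.0, 0.0]),  # CA0
    ]
    # C0 via the N-CA-C angle in the xy-plane
    ang = math.radians(180.0 - _ANGLE["N-CA-C"])
    backbone.append(
        backbone[1] + _BOND["CA-C"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    )
    for _ in range(1, n_residues):
        n_new = _place(backbone[-3], backbone[-2], backbone[-1], _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_new = _place(backbone[-2], backbone[-1], n_new, _BOND["N-CA"], _ANGLE["C-N-CA"], omega)
        c_new = _place(backbone[-1], n_new, ca_new, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        backbone.extend([n_new, ca_new, c_new])

    ns = [backbone[3 * i] for i in range(n_residues)]
    cas = [backbone[3 * i + 1] for i in range(n_residues)]
    cs = [backbone[3 * i + 2] for i in range(n_residues)]
    os_: list[np.ndarray] = []
    for i in range(n_residues):
        if i + 1 < n_residues:
            # O anti to the next amide nitrogen across the peptide plane
            os_.append(_place(ns[i + 1], cas[i], cs[i], _BOND["C-O"], _ANGLE["CA-C-O"], 180.0))
        else:
            os_.append(_place(ns[i], cas[i], cs[i], _BOND["C-O"], 121.0, psi + 180.0))
    hs: list[np.ndarray | None] = [None]
    for i in range(1, n_residues):
        v = cs[i - 1] - os_[i - 1]
        hs.append(ns[i] + _BOND["N-H"] * v / np.linalg.norm(v))

    names, elements, res_idx, coords = [], [], [], []
    for i in range(n_residues):
        entries = [("N", "N", ns[i])]
        if hs[i] is not None:
            entries.append(("H", "H", hs[i]))
        entries += [("CA", "C", cas[i]), ("C", "C", cs[i]), ("O", "O", os_[i])]
        for nm, el, xyz in entries:
            names.append(nm)
            elements.append(el)
            res_idx.append(i)
            coords.append(xyz)
    topo = Topology(
        atom_names=np.array(names),
        elements=np.array(elements),
        atom_residue=np.array(res_idx),
        res_names=np.full(n_residues, "ALA"),
        res_numbers=np.arange(1, n_residues + 1),
        chain_ids=np.full(n_residues, "A"),
    )
    traj = Trajectory(np.array(coords)[None, :, :], np.array([0.0]), topo)
    return topo, traj


# ---------------------------------------------------------------------------
# CX1X2C motif landmarks
# ---------------------------------------------------------------------------

_MOTIF_CA_CA = 5.0  # Angstrom, Ca...Ca' span of the i,i+3 cysteines
_MOTIF_ARM = 2.8  # Angstrom, effective S-Ca arm length


def make_motif(s_s_distance: float, pseudo_torsion: float) -> tuple[Topology, Trajectory]:
    """Four-landmark S-Ca-Ca'-S' motif with prescribed geometry.

    Solves the symmetric-arm construction so that measuring the built
    landmarks returns exactly the requested S...S' distance (Angstrom) and
    absolute pseudo-torsion (degrees in [0, 180]).
    """
    if s_s_distance <= 0:
        raise ValueError("distance must be positive")
    if not 0.0 <= pseudo_torsion <= 180.0:
        raise ValueError("pseudo-torsion must lie in [0, 180] degrees")
    L, r = _MOTIF_CA_CA, _MOTIF_ARM
    chi = math.radians(pseudo_torsion)

    def span(alpha: float) -> float:
        dx = L + 2 * r * math.cos(alpha)
        perp = (r * math.sin(alpha)) ** 2 * (2.0 - 2.0 * math.cos(chi))
        return math.hypot(dx, math.sqrt(perp)) if perp > 0 else abs(dx)

    def f(alpha: float) -> float:
        return span(alpha) - s_s_distance

    lo, hi = 1e-9, math.pi - 1e-9
    # span is continuous on (0, pi); find a bracketing interval on a grid
    grid = np.linspace(lo, hi, 721)
    vals = [f(a) for a in grid]
    alpha = None
    for a0, a1, v0, v1 in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if v0 == 0:
            alpha = a0
            break
        if v0 * v1 < 0:
            alpha = brentq(f, a0, a1, xtol=1e-12)
            break
    if alpha is None:
        raise ValueError(
            f"impossible motif geometry: S...S' = {s_s_distance} A is outside the "
            f"reachable span [{min(map(span, grid)):.2f}, {max(map(span, grid)):.2f}] A"
        )
    ca1 = np.array([0.0, 0.0, 0.0])
    ca2 = np.array([L, 0.0, 0.0])
    s1 = ca1 + r * np.array([-math.cos(alpha), math.sin(alpha), 0.0])
    s2 = ca2 + r * np.array(
        [math.cos(alpha), math.sin(alpha) * math.cos(chi), math.sin(alpha) * math.sin(chi)]
    )
    coords = np.stack([s1, ca1, ca2, s2])
    topo = Topology(
        atom_names=np.array(["SG", "CA", "CA", "SG"]),
        elements=np.array(["S", "C", "C", "S"]),
        atom_residue=np.array([0, 0, 1, 1]),
        res_names=np.array(["CYS", "CYS"]),
        res_numbers=np.array([1, 4]),
        chain_ids=np.array(["A", "A"]),
    )
    return topo, Trajectory(coords[None], np.array([0.0]), topo)


def make_thiol_pair_trajectory(
    n_frames: int, inside_fraction: float, seed: int
) -> tuple[Trajectory, np.ndarray]:
    """S-H...S fixture: a planted fraction of frames satisfies the H-bond criteria.

    Atoms: SG (donor), HG, SG' (acceptor).  Inside frames place the triplet
    at 3.2 A with a collinear hydrogen (angle 180); outside frames at 5.5 A.
    Returns the trajectory and the ground-truth per-frame flags.
    """
    rng = np.random.default_rng(seed)
    n_inside = round(n_frames * inside_fraction)
    flags = np.zeros(n_frames, dtype=bool)
    flags[:n_inside] = True
    rng.shuffle(flags)
    coords = np.empty((n_frames, 3, 3))
    for f in range(n_frames):
        d = 3.2 if flags[f] else 5.5
        coords[f] = [[0.0, 0.0, 0.0], [1.34, 0.0, 0.0], [d, 0.0, 0.0]]
    topo = Topology(
        atom_names=np.array(["SG", "HG", "SG"]),
        elements=np.array(["S", "H", "S"]),
        atom_residue=np.array([0, 0, 1]),
        res_names=np.array(["CYS", "CYS"]),
        res_numbers=np.array([1, 4]),
        chain_ids=np.array(["A", "A"]),
    )
    return Trajectory(coords, np.arange(n_frames, dtype=float), topo), flags


# ---------------------------------------------------------------------------
# Planted two-chain interfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedContact:
    kind: str  # "hbond" | "salt" | "hydrophobic"
    distance: float  # Angstrom, between the defining atom pair
    angle: float | None = None  # degrees at H (hbond only)


@dataclass
class PlantedInterfaceSpec:
    """Two-chain complex whose cross-chain contacts are exactly as listed."""

    contacts: list
    chain_a: str = "A"
    chain_b: str = "B"
    spacing: float = 30.0  # Angstrom between successive contact sites

    def __post_init__(self):
        for c in self.contacts:
            if c.kind == "hbond":
                if c.distance > 3.5 or (c.angle is not None and c.angle < 125.0):
                    raise ValueError("hbond must satisfy criteria with margin (<=3.5 A, >=125 deg)")
            elif c.kind == "salt":
                if c.distance > 3.9:
                    raise ValueError("salt bridge must be <= 3.9 A (0.1 A margin)")
            elif c.kind == "hydrophobic":
                if c.distance > 3.9:
                    raise ValueError("hydrophobic contact must be <= 3.9 A (0.1 A margin)")
            else:
                raise ValueError(f"unknown contact type {c.kind!r}")
            if c.distance < 2.4:
                raise ValueError("planted distance below physical contact range")


def _hbond_h_position(d: np.ndarray, a: np.ndarray, angle_deg: float) -> np.ndarray:
    """Hydrogen 0.96 A from donor d so that the D-H...A angle equals angle_deg."""
    if angle_deg >= 179.9:
        u = (a - d) / np.linalg.norm(a - d)
        return d + 0.96 * u
    target = math.radians(angle_deg)
    dist = np.linalg.norm(a - d)
    u = (a - d) / dist
    # perpendicular direction in a fixed plane
    w = np.array([0.0, 0.0, 1.0])
    if abs(u @ w) > 0.9:
        w = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, w)
    v /= np.linalg.norm(v)

    def ang(beta: float) -> float:
        h = d + 0.96 * (math.cos(beta) * u + math.sin(beta) * v)
        x1 = d - h
        x2 = a - h
        return math.acos(
            np.clip(x1 @ x2 / (np.linalg.norm(x1) * np.linalg.norm(x2)), -1, 1)
        ) - target

    beta = brentq(ang, 1e-6, math.pi - 1e-6, xtol=1e-12)
    return d + 0.96 * (math.cos(beta) * u + math.sin(beta) * v)


def make_planted_interface(spec: PlantedInterfaceSpec):
    """Build the two-chain complex; returns (topology, trajectory, planted list).

    Contact sites are strung along x at ``spacing`` intervals, far enough
    apart that no unintended cross-site contact can arise; chain A holds the
    donor-side residues and chain B the acceptor side.
    """
    names, elements, res_idx, res_names, res_numbers, chain_ids, coords = (
        [],
        [],
        [],
        [],
        [],
        [],
        [],
    )

    def add_residue(res_name: str, number: int, chain: str, atoms):
        r = len(res_names)
        res_names.append(res_name)
        res_numbers.append(number)
        chain_ids.append(chain)
        for nm, el, xyz in atoms:
            names.append(nm)
            elements.append(el)
            res_idx.append(r)
            coords.append(np.asarray(xyz, dtype=float))

    for i, c in enumerate(spec.contacts):
        o = np.array([spec.spacing * i, 0.0, 0.0])
        num_a, num_b = i + 1, i + 101
        if c.kind == "salt":
            nz = o
            oe = o + np.array([c.distance, 0.0, 0.0])
            add_residue("LYS", num_a, spec.chain_a, [("CA", "C", nz + [-2.5, 3.0, 0]), ("NZ", "N", nz)])
            add_residue("GLU", num_b, spec.chain_b, [("CA", "C", oe + [2.5, 3.0, 0]), ("OE1", "O", oe)])
        elif c.kind == "hbond":
            og_a = o
            og_b = o + np.array([c.distance, 0.0, 0.0])
            h = _hbond_h_position(og_a, og_b, c.angle if c.angle is not None else 180.0)
            add_residue(
                "SER", num_a, spec.chain_a,
                [("CA", "C", og_a + [-2.5, 3.0, 0]), ("OG", "O", og_a), ("HG", "H", h)],
            )
            add_residue("SER", num_b, spec.chain_b, [("CA", "C", og_b + [2.5, 3.0, 0]), ("OG", "O", og_b)])
        else:  # hydrophobic
            cb_a = o
            cb_b = o + np.array([c.distance, 0.0, 0.0])
            add_residue("LEU", num_a, spec.chain_a, [("CA", "C", cb_a + [-2.5, 3.0, 0]), ("CB", "C", cb_a)])
            add_residue("LEU", num_b, spec.chain_b, [("CA", "C", cb_b + [2.5, 3.0, 0]), ("CB", "C", cb_b)])

    if not coords:
        # two far-apart lone residues so the topology is non-empty
        add_residue("ALA", 1, spec.chain_a, [("CA", "C", [0.0, 0.0, 0.0]), ("CB", "C", [1.5, 0.0, 0.0])])
        add_residue("ALA", 101, spec.chain_b, [("CA", "C", [30.0, 0.0, 0.0]), ("CB", "C", [31.5, 0.0, 0.0])])

    topo = Topology(
        atom_names=np.array(names),
        elements=np.array(elements),
        atom_residue=np.array(res_idx),
        res_names=np.array(res_names),
        res_numbers=np.array(res_numbers),
        chain_ids=np.array(chain_ids),
    )
    traj = Trajectory(np.stack(coords)[None], np.array([0.0]), topo)
    return topo, traj, list(spec.contacts)


# ---------------------------------------------------------------------------
# Shape clusters
# ---------------------------------------------------------------------------


def sample_shapes(
    cluster_centers: list, noise_sd, counts, seed: int
) -> tuple[list[PreShape], np.ndarray]:
    """Noisy landmark shapes around centers; returns (shapes, labels)."""
    centers = [np.asarray(c, dtype=float) for c in cluster_centers]
    ks = {c.shape[0] for c in centers}
    if len(ks) > 1:
        raise ValueError("all cluster centers must share the landmark count k")
    if np.isscalar(noise_sd):
        noise_sd = [float(noise_sd)] * len(centers)
    rng = np.random.default_rng(seed)
    shapes: list[PreShape] = []
    labels: list[int] = []
    for label, (center, sd, count) in enumerate(zip(centers, noise_sd, counts)):
        for _ in range(count):
            pts = center + rng.normal(0.0, sd, center.shape)
            shapes.append(preshape(pts))
            labels.append(label)
    return shapes, np.array(labels)


# ---------------------------------------------------------------------------
# Synthetic stand-in for the fused bacterial VKOR cysteine geometry
# ---------------------------------------------------------------------------


def make_synthetic_bvkor_cys(
    interdomain_ss: float = 16.0,
) -> tuple[Topology, Trajectory, dict]:
    """SYNTHETIC stand-in for the cysteine skeleton of a fused VKOR homologue.

    Bacterial VKOR fuses a VKOR-like domain (active-site CXXC plus loop
    cysteines) with a thioredoxin-like domain in one chain.  This generator
    places only the cysteine SG landmarks: two intra-domain disulphide
    pairs at bonding distance (2.05 A) in each domain, with the closest
    inter-domain pair separated by ``interdomain_ss`` Angstrom.  It is a
    geometric stand-in constructed in code — NOT coordinates from any
    deposited structure — and exists so the inter-domain S...S measurement
    has a self-contained worked example.

    Returns (topology, trajectory, info) where info gives the residue
    numbers of each domain.
    """
    d = float(interdomain_ss)
    # VKOR-like domain: loop pair C50/C56 and active-site pair C130/C133
    vkor = {
        50: np.array([0.0, 6.0, 0.0]),
        56: np.array([2.05, 6.0, 0.0]),
        130: np.array([0.0, 0.0, 0.0]),
        133: np.array([2.05, 0.0, 0.0]),
    }
    # Trx-like domain CXXC, its nearest sulphur d away from C133
    trx = {
        209: np.array([2.05 + d, 0.0, 0.0]),
        212: np.array([2.05 + d + 2.05, 0.0, 0.0]),
    }
    residues = {**vkor, **trx}
    numbers = sorted(residues)
    topo = Topology(
        atom_names=np.full(len(numbers), "SG"),
        elements=np.full(len(numbers), "S"),
        atom_residue=np.arange(len(numbers)),
        res_names=np.full(len(numbers), "CYS"),
        res_numbers=np.array(numbers),
        chain_ids=np.full(len(numbers), "A"),
    )
    coords = np.stack([residues[n] for n in numbers])
    traj = Trajectory(coords[None], np.array([0.0]), topo)
    info = {"vkor_domain": sorted(vkor), "trx_domain": sorted(trx)}
    return topo, traj, info
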