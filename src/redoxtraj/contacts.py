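"""Noncovalent contact detection: H-bonds, salt bridges, hydrophobic contacts.

Criteria
--------
* H-bond: heavy donor/acceptor atoms among N, O, S; donor...acceptor
  distance < 3.6 A and angle at the hydrogen (D-H...A) >= 120 deg.  Donors
  need an attached hydrogen; backbone amide hydrogens can be idealized when
  absent (N-H anti-parallel to the preceding C=O), side-chain and thiol
  hydrogens must be explicit.
* Salt bridge: any side-chain N of Arg (NE/NH1/NH2) or Lys (NZ) within
  4.0 A of a side-chain O of Asp (OD1/OD2) or Glu (OE1/OE2).  Histidine is
  excluded by default (neutral, epsilon-protonated convention).
* Hydrophobic: two hydrophobic residues whose side-chain heavy atoms come
  within 4.0 A; glycine's Calpha stands in for its absent side chain.

A residue pair may legitimately appear as both hbond and salt_bridge; use
:func:`count_unique_contacts` to count unique interacting residue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ResidueClass, StructureError, Topology, Trajectory, classify_residue

__all__ = [
    "ContactRecord",
    "ContactMap",
    "find_hbonds",
    "find_salt_bridges",
    "find_hydrophobic",
    "interface_contacts",
    "contact_map",
    "exposed_residues",
    "count_unique_contacts",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "SALT_BRIDGE_CUTOFF",
    "HYDROPHOBIC_CUTOFF",
]

HBOND_DISTANCE_CUTOFF = 3.6  # Angstrom, donor...acceptor heavy-atom distance
HBOND_ANGLE_CUTOFF = 120.0  # degrees at the hydrogen
SALT_BRIDGE_CUTOFF = 4.0  # Angstrom, side-chain N...O
HYDROPHOBIC_CUTOFF = 4.0  # Angstrom, closest side-chain heavy atoms

_HBOND_ELEMENTS = ("N", "O", "S")
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
_BASIC_GROUPS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_ACIDIC_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # "hbond" | "salt_bridge" | "hydrophobic"
    donor_atom: int
    acceptor_atom: int
    donor_residue: int  # residue index into the topology
    acceptor_residue: int
    distance: float  # Angstrom
    angle: float | None = None  # degrees at H (hbond only)
    frame: int | None = None

    def residue_pair(self) -> tuple[int, int]:
        return tuple(sorted((self.donor_residue, self.acceptor_residue)))


@dataclass(frozen=True)
class ContactMap:
    occupancy: np.ndarray  # (n_res, n_res) fraction of sampled frames in contact
    n_frames_sampled: int


def count_unique_contacts(records) -> int:
    """Number of unique interacting residue pairs (hbond+salt dual listings collapse)."""
    return len({r.residue_pair() for r in records})


# covalent H search radius; S-H bonds run to ~1.35 A
_H_BOND_RADIUS = 1.45


def _attached_hydrogens(topology: Topology, frame: np.ndarray, heavy: int) -> list[int]:
    """Explicit hydrogens bonded to a heavy atom (bond list, else proximity in-residue)."""
    if topology.bonds is not None and len(topology.bonds):
        hs = []
        for i, j in topology.bonds:
            if i == heavy and topology.elements[j] == "H":
                hs.append(int(j))
            elif j == heavy and topology.elements[i] == "H":
                hs.append(int(i))
        return hs
    res_atoms = topology.residue_atoms(topology.atom_residue[heavy])
    hs = []
    for a in res_atoms:
        if (
            topology.elements[a] == "H"
            and np.linalg.norm(frame[a] - frame[heavy]) < _H_BOND_RADIUS
        ):
            hs.append(int(a))
    return hs


def idealized_amide_h(topology: Topology, frame: np.ndarray, n_atom: int) -> np.ndarray | None:
    """Idealized backbone amide H: 1.0 A from N, anti-parallel to the previous C=O."""
    res = topology.atom_residue[n_atom]
    if res == 0:
        return None
    prev = res - 1
    if topology.chain_ids[prev] != topology.chain_ids[res]:
        return None
    c = topology.find_atom(prev, "C")
    o = topology.find_atom(prev, "O")
    if c is None or o is None:
        return None
    v = frame[c] - frame[o]
    nv = np.linalg.norm(v)
    if nv < 1e-8:
        return None
    return frame[n_atom] + v / nv


def find_hbonds(
    frame: np.ndarray,
    topology: Topology,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
    idealize_backbone_h: bool = True,
    frame_id: int | None = None,
) -> list[ContactRecord]:
    """Hydrogen bonds in one frame between N/O/S heavy atoms.

    With ``idealize_backbone_h`` (default), backbone nitrogens without an
    explicit hydrogen get one reconstructed; other H-less donors are
    silently non-donors.  Same-residue pairs are excluded.
    """
    frame = np.asarray(frame)
    eligible = np.flatnonzero(np.isin(np.char.upper(topology.elements), _HBOND_ELEMENTS))
    records: list[ContactRecord] = []
    donor_hs: dict[int, list[np.ndarray]] = {}
    for d in eligible:
        hs = [frame[h] for h in _attached_hydrogens(topology, frame, d)]
        if not hs and idealize_backbone_h and topology.atom_names[d] == "N":
            pos = idealized_amide_h(topology, frame, d)
            if pos is not None:
                hs = [pos]
        if hs:
            donor_hs[int(d)] = hs
    for d, hs in donor_hs.items():
        for a in eligible:
            if a == d or topology.atom_residue[a] == topology.atom_residue[d]:
                continue
            dist = float(np.linalg.norm(frame[d] - frame[a]))
            if dist >= d_cut:
                continue
            best_angle = -1.0
            for h_pos in hs:
                v1 = frame[d] - h_pos
                v2 = frame[a] - h_pos
                nv1, nv2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if nv1 < 1e-8 or nv2 < 1e-8:
                    continue
                ang = float(np.degrees(np.arccos(np.clip(v1 @ v2 / (nv1 * nv2), -1, 1))))
                best_angle = max(best_angle, ang)
            if best_angle >= angle_cut:
                records.append(
                    ContactRecord(
                        kind="hbond",
                        donor_atom=int(d),
                        acceptor_atom=int(a),
                        donor_residue=int(topology.atom_residue[d]),
                        acceptor_residue=int(topology.atom_residue[a]),
                        distance=dist,
                        angle=best_angle,
                        frame=frame_id,
                    )
                )
    return records


def _sidechain_heavy_atoms(topology: Topology, residue_index: int) -> np.ndarray:
    atoms = topology.residue_atoms(residue_index)
    names = topology.atom_names[atoms]
    elements = np.char.upper(topology.elements[atoms])
    side = atoms[(~np.isin(names, list(_BACKBONE_NAMES))) & (elements != "H")]
    if len(side) == 0 and topology.res_names[residue_index] == "GLY":
        ca = topology.find_atom(residue_index, "CA")
        if ca is not None:
            return np.array([ca])
    return side


def find_hydrophobic(
    frame: np.ndarray,
    topology: Topology,
    d_cut: float = HYDROPHOBIC_CUTOFF,
    min_seq_separation: int = 2,
    frame_id: int | None = None,
) -> list[ContactRecord]:
    """Hydrophobic contacts: side chains of two hydrophobic residues < d_cut apart.

    Within a chain, residues closer in sequence than ``min_seq_separation``
    are skipped (their side chains are covalent neighbours); cross-chain
    pairs are always considered.  Glycine's Calpha is its side-chain proxy.
    """
    frame = np.asarray(frame)
    hydrophobic = [
        r
        for r in range(topology.n_residues)
        if topology.res_names[r] in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY")
    ]
    records: list[ContactRecord] = []
    side = {r: _sidechain_heavy_atoms(topology, r) for r in hydrophobic}
    for ii, r1 in enumerate(hydrophobic):
        for r2 in hydrophobic[ii + 1 :]:
            if topology.chain_ids[r1] == topology.chain_ids[r2]:
                if abs(int(topology.res_numbers[r1]) - int(topology.res_numbers[r2])) < min_seq_separation:
                    continue
            a1, a2 = side[r1], side[r2]
            if len(a1) == 0 or len(a2) == 0:
                continue
            d = np.linalg.norm(frame[a1][:, None, :] - frame[a2][None, :, :], axis=2)
            k = np.unravel_index(np.argmin(d), d.shape)
            if d[k] < d_cut:
                records.append(
                    ContactRecord(
                        kind="hydrophobic",
                        donor_atom=int(a1[k[0]]),
                        acceptor_atom=int(a2[k[1]]),
                        donor_residue=r1,
                        acceptor_residue=r2,
                        distance=float(d[k]),
                        frame=frame_id,
                    )
                )
    return records


def find_salt_bridges(
    frame: np.ndarray,
    topology: Topology,
    d_cut: float = SALT_BRIDGE_CUTOFF,
    frame_id: int | None = None,
) -> list[ContactRecord]:
    """Salt bridges: side-chain N of Arg/Lys within d_cut of side-chain O of Asp/Glu."""
    frame = np.asarray(frame)
    records: list[ContactRecord] = []
    basics = [
        (r, topology.find_atom(r, nm))
        for r in range(topology.n_residues)
        for nm in _BASIC_GROUPS.get(str(topology.res_names[r]), ())
    ]
    acidics = [
        (r, topology.find_atom(r, nm))
        for r in range(topology.n_residues)
        for nm in _ACIDIC_GROUPS.get(str(topology.res_names[r]), ())
    ]
    seen: set[tuple] = set()
    for rb, nb in basics:
        if nb is None:
            continue
        for ra, oa in acidics:
            if oa is None:
                continue
            dist = float(np.linalg.norm(frame[nb] - frame[oa]))
            if dist < d_cut:
                key = (rb, ra)
                # keep the closest N-O pair per residue pair
                existing = next(
                    (x for x in records if x.kind == "salt_bridge" and (x.donor_residue, x.acceptor_residue) == key),
                    None,
                )
                if existing is None:
                    records.append(
                        ContactRecord(
                            kind="salt_bridge",
                            donor_atom=int(nb),
                            acceptor_atom=int(oa),
                            donor_residue=rb,
                            acceptor_residue=ra,
                            distance=dist,
                            frame=frame_id,
                        )
                    )
                elif dist < existing.distance:
                    records[records.index(existing)] = ContactRecord(
                        kind="salt_bridge",
                        donor_atom=int(nb),
                        acceptor_atom=int(oa),
                        donor_residue=rb,
                        acceptor_residue=ra,
                        distance=dist,
                        frame=frame_id,
                    )
                seen.add(key)
    return records


def _all_contacts(frame, topology, frame_id=None, **kw):
    return (
        find_hbonds(frame, topology, frame_id=frame_id, **kw.get("hbond", {}))
        + find_salt_bridges(frame, topology, frame_id=frame_id, **kw.get("salt", {}))
        + find_hydrophobic(frame, topology, frame_id=frame_id, **kw.get("hydrophobic", {}))
    )


def interface_contacts(
    frame: np.ndarray,
    topology: Topology,
    chain_a: str,
    chain_b: str,
    frame_id: int | None = None,
    **detector_kwargs,
) -> list[ContactRecord]:
    """Contacts of all three types restricted to cross-chain (A x B) pairs."""
    chains = set(topology.chain_ids)
    for c in (chain_a, chain_b):
        if c not in chains:
            raise StructureError(f"unknown chain {c!r}; present: {sorted(chains)}")
    records = _all_contacts(frame, topology, frame_id=frame_id, **detector_kwargs)
    out = []
    for r in records:
        ca = topology.chain_ids[r.donor_residue]
        cb = topology.chain_ids[r.acceptor_residue]
        if {ca, cb} == {chain_a, chain_b}:
            out.append(r)
    return out


def interface_summary(records) -> dict:
    """Counts by contact type plus the unique-residue-pair total."""
    by_type: dict[str, int] = {}
    for r in records:
        by_type[r.kind] = by_type.get(r.kind, 0) + 1
    return {
        "by_type": by_type,
        "unique_residue_pairs": count_unique_contacts(records),
        "records": len(records),
    }


def contact_map(
    trajectory: Trajectory,
    detectors=("hbond", "salt_bridge", "hydrophobic"),
    stride: int = 1,
    **detector_kwargs,
) -> ContactMap:
    """Residue x residue occupancy: the fraction of sampled frames in contact."""
    topo = trajectory.topology
    n = topo.n_residues
    counts = np.zeros((n, n))
    frames = range(0, trajectory.n_frames, stride)
    n_sampled = 0
    for f in frames:
        n_sampled += 1
        recs: list[ContactRecord] = []
        if "hbond" in detectors:
            recs += find_hbonds(trajectory.coordinates[f], topo, frame_id=f, **detector_kwargs.get("hbond", {}))
        if "salt_bridge" in detectors:
            recs += find_salt_bridges(trajectory.coordinates[f], topo, frame_id=f, **detector_kwargs.get("salt", {}))
        if "hydrophobic" in detectors:
            recs += find_hydrophobic(trajectory.coordinates[f], topo, frame_id=f, **detector_kwargs.get("hydrophobic", {}))
        pairs = {r.residue_pair() for r in recs}
        for i, j in pairs:
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1
    return ContactMap(occupancy=counts / max(n_sampled, 1), n_frames_sampled=n_sampled)


def exposed_residues(frame: np.ndarray, topology: Topology) -> list[tuple[int, ResidueClass]]:
    """Residues whose side chains join no intra-molecular contact.

    A contact-based proxy for protruding/solvent-facing side chains (this is
    not a solvent-accessible-surface computation).  Returns (residue index,
    residue class) pairs; residues outside the 20 standard amino acids are
    skipped.
    """
    records = _all_contacts(frame, topology)
    engaged: set[int] = set()
    for r in records:
        for atom, res in ((r.donor_atom, r.donor_residue), (r.acceptor_atom, r.acceptor_residue)):
            if atom in _sidechain_heavy_atoms(topology, res) or (
                topology.elements[atom] == "H"
            ):
                engaged.add(res)
    out = []
    for res in range(topology.n_residues):
        if res in engaged:
            continue
        try:
            cls = classify_residue(str(topology.res_names[res]))
        except KeyError:
            continue
        out.append((res, cls))
    return out


def contacts_table(records) -> pd.DataFrame:
    """Flat table of contact records (one row per record)."""
    return pd.DataFrame(
        [
            {
                "frame": r.frame,
                "type": r.kind,
                "donor_atom": r.donor_atom,
                "acceptor_atom": r.acceptor_atom,
                "donor_residue": r.donor_residue,
                "acceptor_residue": r.acceptor_residue,
                "distance_A": r.distance,
                "angle_deg": r.angle,
            }
            for r in records
        ]
    )
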