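"""Domain types, residue chemistry, structure I/O and atom selection.

Coordinates are always in Angstrom and times in picoseconds throughout the
package; no unit autodetection is performed.  Structures are read and written
as multi-model PDB (one MODEL per trajectory frame) or as a minimal
XYZ-per-frame dialect.  The PDB route is backed by :mod:`biotite`; the
package accepts structures with or without hydrogens — operations that need
explicit hydrogens (thiol H-bond statistics) say so in their docstrings.
"""

from __future__ import annotations

import enum
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "SelectionMask",
    "ResidueClass",
    "StructureError",
    "ParseError",
    "SelectionSyntaxError",
    "EmptySelectionWarning",
    "read_structure",
    "write_structure",
    "select",
    "classify_residue",
    "STANDARD_RESIDUES",
]


class StructureError(ValueError):
    """Invalid structure or trajectory content."""


class ParseError(StructureError):
    """A file did not parse in the declared dialect.

    Carries ``line`` (1-based) when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SelectionSyntaxError(ValueError):
    """Unknown token or malformed selection expression."""


class EmptySelectionWarning(UserWarning):
    """A syntactically valid selection matched no atoms."""


class ResidueClass(enum.Enum):
    """Physico-chemical class of a standard amino-acid residue."""

    POSITIVE = "positively-charged"
    NEGATIVE = "negatively-charged"
    POLAR = "polar"
    HYDROPHOBIC = "hydrophobic"
    AMPHIPATHIC = "amphipathic"


# Fixed classification: +{R,K}; -{D,E}; polar{S,T,N,Q,C,H};
# hydrophobic{A,V,L,I,P,F,M,G}; amphipathic{W,Y}.  Histidine is treated as
# neutral/polar (epsilon-protonated convention); glycine counts as
# hydrophobic so that backbone-proxy hydrophobic contacts are detectable.
_RESIDUE_CLASS: dict[str, ResidueClass] = {
    "ARG": ResidueClass.POSITIVE,
    "LYS": ResidueClass.POSITIVE,
    "ASP": ResidueClass.NEGATIVE,
    "GLU": ResidueClass.NEGATIVE,
    "SER": ResidueClass.POLAR,
    "THR": ResidueClass.POLAR,
    "ASN": ResidueClass.POLAR,
    "GLN": ResidueClass.POLAR,
    "CYS": ResidueClass.POLAR,
    "HIS": ResidueClass.POLAR,
    "ALA": ResidueClass.HYDROPHOBIC,
    "VAL": ResidueClass.HYDROPHOBIC,
    "LEU": ResidueClass.HYDROPHOBIC,
    "ILE": ResidueClass.HYDROPHOBIC,
    "PRO": ResidueClass.HYDROPHOBIC,
    "PHE": ResidueClass.HYDROPHOBIC,
    "MET": ResidueClass.HYDROPHOBIC,
    "GLY": ResidueClass.HYDROPHOBIC,
    "TRP": ResidueClass.AMPHIPATHIC,
    "TYR": ResidueClass.AMPHIPATHIC,
}

STANDARD_RESIDUES: tuple[str, ...] = tuple(sorted(_RESIDUE_CLASS))


def classify_residue(res_name: str) -> ResidueClass:
    """Classify a standard residue (3-letter code) by side-chain character.

    Raises
    ------
    KeyError
        For a residue outside the 20 standard amino acids.
    """
    try:
        return _RESIDUE_CLASS[res_name.upper()]
    except KeyError:
        raise KeyError(f"no residue class defined for {res_name!r}") from None


@dataclass(frozen=True)
class Topology:
    """Static chemical identity of a structure.

    ``atom_names``, ``elements`` and ``atom_residue`` are parallel per-atom
    arrays; ``atom_residue[i]`` indexes into the per-residue arrays
    ``res_names`` / ``res_numbers`` / ``chain_ids``.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    atom_residue: np.ndarray
    res_names: np.ndarray
    res_numbers: np.ndarray
    chain_ids: np.ndarray
    bonds: np.ndarray | None = None  # optional (i, j) pair list

    def __post_init__(self):
        object.__setattr__(self, "atom_names", np.asarray(self.atom_names, dtype="U6"))
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype="U2"))
        object.__setattr__(self, "atom_residue", np.asarray(self.atom_residue, dtype=int))
        object.__setattr__(self, "res_names", np.asarray(self.res_names, dtype="U3"))
        object.__setattr__(self, "res_numbers", np.asarray(self.res_numbers, dtype=int))
        object.__setattr__(self, "chain_ids", np.asarray(self.chain_ids, dtype="U4"))
        if self.n_atoms == 0:
            raise StructureError("topology has zero atoms")
        if self.atom_residue.min() < 0 or self.atom_residue.max() >= self.n_residues:
            raise StructureError("atom references a nonexistent residue")
        for chain in np.unique(self.chain_ids):
            nums = self.res_numbers[self.chain_ids == chain]
            if len(np.unique(nums)) != len(nums):
                raise StructureError(f"duplicate residue numbers in chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def atom_chain_ids(self) -> np.ndarray:
        return self.chain_ids[self.atom_residue]

    def atom_res_numbers(self) -> np.ndarray:
        return self.res_numbers[self.atom_residue]

    def atom_res_names(self) -> np.ndarray:
        return self.res_names[self.atom_residue]

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """Atom indices belonging to one residue, in file order."""
        return np.flatnonzero(self.atom_residue == residue_index)

    def find_atom(self, residue_index: int, atom_name: str) -> int | None:
        idx = self.residue_atoms(residue_index)
        hits = idx[self.atom_names[idx] == atom_name]
        return int(hits[0]) if len(hits) else None


@dataclass
class Trajectory:
    """F frames of Cartesian coordinates (Angstrom) with timestamps (ps)."""

    coordinates: np.ndarray  # (F, N, 3)
    time_ps: np.ndarray  # (F,)
    topology: Topology

    def __post_init__(self):
        self.coordinates = np.atleast_3d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureError("coordinates must have shape (F, N, 3)")
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        if self.n_frames < 1:
            raise StructureError("trajectory must contain at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.time_ps.shape != (self.n_frames,):
            raise StructureError("one timestamp per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.time_ps) > 0):
            raise StructureError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]


@dataclass(frozen=True)
class SelectionMask:
    """Ordered, unique, sorted atom indices into a Topology."""

    indices: np.ndarray
    n_atoms_total: int

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if len(idx) and (idx.min() < 0 or idx.max() >= self.n_atoms_total):
            raise StructureError("selection index out of range")
        if len(idx) and (np.any(np.diff(idx) <= 0)):
            raise StructureError("selection indices must be sorted and unique")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.indices, dtype=dtype)


# ---------------------------------------------------------------------------
# Selection expressions
# ---------------------------------------------------------------------------

_SELECTION_KEYWORDS = ("name", "resname", "resid", "chain")


def select(topology: Topology, expression: str) -> SelectionMask:
    """Evaluate a selection expression against a topology.

    Grammar: clauses of the form ``<keyword> <value> [<value> ...]`` joined
    by ``and``; keywords are ``name`` (atom name), ``resname`` (3-letter
    residue code), ``resid`` (residue number or ``lo-hi`` range) and
    ``chain``.  Multiple values within a clause are OR-ed; clauses are
    AND-ed, so adding a clause never adds atoms.

    Examples
    --------
    ``"name CA"``, ``"resid 37-40 and name SG"``, ``"chain A and resname CYS"``.
    """
    tokens = expression.split()
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    clauses: list[tuple[str, list[str]]] = []
    i = 0
    while i < len(tokens):
        kw = tokens[i].lower()
        if kw == "and":
            i += 1
            continue
        if kw not in _SELECTION_KEYWORDS:
            raise SelectionSyntaxError(f"unknown token {tokens[i]!r}")
        values: list[str] = []
        i += 1
        while i < len(tokens) and tokens[i].lower() not in (*_SELECTION_KEYWORDS, "and"):
            values.append(tokens[i])
            i += 1
        if not values:
            raise SelectionSyntaxError(f"keyword {kw!r} expects at least one value")
        clauses.append((kw, values))

    keep = np.ones(topology.n_atoms, dtype=bool)
    for kw, values in clauses:
        if kw == "name":
            clause = np.isin(topology.atom_names, values)
        elif kw == "resname":
            clause = np.isin(topology.atom_res_names(), [v.upper() for v in values])
        elif kw == "chain":
            clause = np.isin(topology.atom_chain_ids(), values)
        else:  # resid
            nums = topology.atom_res_numbers()
            clause = np.zeros(topology.n_atoms, dtype=bool)
            for v in values:
                if "-" in v[1:]:  # allow negative single ids
                    lo_s, hi_s = v[1:].split("-", 1)
                    lo_s = v[0] + lo_s
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid range {v!r}") from None
                    clause |= (nums >= lo) & (nums <= hi)
                else:
                    try:
                        clause |= nums == int(v)
                    except ValueError:
                        raise SelectionSyntaxError(f"bad resid {v!r}") from None
        keep &= clause

    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        warnings.warn(
            f"selection {expression!r} matched no atoms", EmptySelectionWarning, stacklevel=2
        )
    return SelectionMask(idx, topology.n_atoms)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _prevalidate_pdb(lines: Sequence[str]) -> None:
    """Best-effort dialect check so malformed records name their line."""
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise ParseError("truncated ATOM/HETATM record", line=ln)
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"unparsable coordinate field {line[lo:hi]!r}", line=ln
                    ) from None


def _topology_from_atom_array(array) -> tuple[Topology, np.ndarray]:
    """Build a Topology from a biotite AtomArray; returns (topology, atom_residue)."""
    n = array.array_length()
    res_keys: list[tuple[str, int, str]] = []
    res_index_of: dict[tuple[str, int, str], int] = {}
    atom_residue = np.empty(n, dtype=int)
    for i in range(n):
        key = (str(array.chain_id[i]), int(array.res_id[i]), str(array.res_name[i]))
        if key not in res_index_of:
            res_index_of[key] = len(res_keys)
            res_keys.append(key)
        atom_residue[i] = res_index_of[key]
    chain_ids = np.array([k[0] if k[0] else "A" for k in res_keys])
    res_numbers = np.array([k[1] for k in res_keys])
    res_names = np.array([k[2] for k in res_keys])
    elements = np.array(
        [e if e else _guess_element(nm) for e, nm in zip(array.element, array.atom_name)]
    )
    topo = Topology(
        atom_names=np.asarray(array.atom_name),
        elements=elements,
        atom_residue=atom_residue,
        res_names=res_names,
        res_numbers=res_numbers,
        chain_ids=chain_ids,
    )
    return topo, atom_residue


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def _read_pdb(path: Path) -> tuple[Topology, Trajectory]:
    from biotite.structure.io.pdb import PDBFile

    text = path.read_text()
    _prevalidate_pdb(text.splitlines())
    try:
        pdb = PDBFile.read(io.StringIO(text))
        model_count = pdb.get_model_count()
        if model_count == 1:
            stack = pdb.get_structure(model=1, altloc="first")
            coords = stack.coord[None, :, :]
            template = stack
        else:
            stack = pdb.get_structure(model=None, altloc="first")
            coords = stack.coord
            template = stack[0]
    except ParseError:
        raise
    except Exception as exc:  # biotite raises several error types
        raise ParseError(f"PDB parse failed: {exc}") from exc
    if template.array_length() == 0:
        raise StructureError(f"{path}: structure contains zero atoms")
    topology, _ = _topology_from_atom_array(template)
    time_ps = np.arange(coords.shape[0], dtype=float)
    return topology, Trajectory(np.asarray(coords, dtype=float), time_ps, topology)


def _write_pdb(topology: Topology, trajectory: Trajectory, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3))
    array.atom_name = topology.atom_names
    array.element = np.char.upper(topology.elements)
    array.res_name = topology.atom_res_names()
    array.res_id = topology.atom_res_numbers()
    array.chain_id = topology.atom_chain_ids()
    array.hetero = np.zeros(n, dtype=bool)

    if trajectory.n_frames == 1:
        array.coord = np.asarray(trajectory.coordinates[0])
        obj = array
    else:
        obj = struc.from_template(array, np.asarray(trajectory.coordinates))
    pdb = PDBFile()
    pdb.set_structure(obj)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# XYZ I/O (minimal multi-frame dialect: count line, comment, "El x y z")
# ---------------------------------------------------------------------------


def _read_xyz(path: Path) -> tuple[Topology, Trajectory]:
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}", line=i + 1) from None
        if i + 1 + n >= len(lines) + 1:
            raise ParseError("truncated XYZ frame", line=i + 1)
        block = lines[i + 2 : i + 2 + n]
        coords = np.empty((n, 3))
        frame_elements = []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"bad XYZ atom line {row!r}", line=i + 3 + j)
            frame_elements.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"bad XYZ coordinates {row!r}", line=i + 3 + j) from None
        if elements is None:
            elements = frame_elements
        elif elements != frame_elements:
            raise ParseError("inconsistent atom list between XYZ frames", line=i + 1)
        frames.append(coords)
        i += 2 + n
    if not frames or elements is None or len(elements) == 0:
        raise StructureError(f"{path}: structure contains zero atoms")
    n_atoms = len(elements)
    topo = Topology(
        atom_names=np.array(elements),
        elements=np.array(elements),
        atom_residue=np.zeros(n_atoms, dtype=int),
        res_names=np.array(["UNK"]),
        res_numbers=np.array([1]),
        chain_ids=np.array(["A"]),
    )
    coords = np.stack(frames)
    return topo, Trajectory(coords, np.arange(len(frames), dtype=float), topo)


def _write_xyz(topology: Topology, trajectory: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {f} time_ps {trajectory.time_ps[f]:g}\n")
            for el, xyz in zip(topology.elements, trajectory.coordinates[f]):
                fh.write(f"{el:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")


def read_structure(path, format: str | None = None) -> tuple[Topology, Trajectory]:
    """Read a structure/trajectory from multi-model PDB or XYZ.

    A multi-model PDB yields one frame per MODEL record; missing timestamps
    default to the frame index in ps.

    Parameters
    ----------
    path : path-like
    format : {"pdb", "xyz"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported format {fmt!r}")


def write_structure(topology: Topology, trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ; re-readable by read_structure."""
    if trajectory is None or trajectory.n_frames < 1:
        raise StructureError("refusing to write an empty trajectory")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        _write_pdb(topology, trajectory, path)
    elif fmt == "xyz":
        _write_xyz(topology, trajectory, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
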