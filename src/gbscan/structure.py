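"""Protein structures, conformational ensembles and dimer partitions.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of chains, each an ordered list of residues with explicit atoms; an
:class:`Ensemble` couples one topology with any number of coordinate frames
(the unit over which effective energies are averaged).  Multi-MODEL PDB is the
only interchange format -- one frame per MODEL record -- read and written
through biotite.

Coordinates are in Angstrom throughout.  Waters and common counterions are
always stripped on reading, because the energy model treats solvent
implicitly; for alternate locations the highest-occupancy conformer is kept
(ties broken by file order).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "DimerPartition",
    "StructureError",
    "read_structure",
    "write_structure",
    "partition_dimer",
    "renumber",
]

#: residue names treated as solvent / counterions and always removed
SOLVENT_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL", "TIP3"})
ION_NAMES = frozenset({"NA", "CL", "K", "MG", "ZN", "MN", "FE", "BR", "IOD", "CS", "LI", "CA2", "SO4", "PO4"})

#: minimal backbone every standard amino-acid residue must provide
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for malformed structures, frames or partitions."""


@dataclass
class Atom:
    """A single atom: name, element, position (A) and occupancy."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hydrogen: bool = False
    built: bool = False  # True for hydrogens added from ideal templates

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise StructureError(f"empty element for atom {self.name}")
        self.is_hydrogen = self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue identified by (name, number, insertion code) with ordered atoms."""

    name: str
    number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.number}{self.insertion_code}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Structure:
    """Ordered chains of residues; atom order (chain, residue, atom) is canonical."""

    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids: {ids}")
        for cid, residues in self.chains:
            seen = set()
            for res in residues:
                if res.id in seen:
                    raise StructureError(
                        f"chain {cid}: duplicate residue id {res.number}{res.insertion_code}"
                    )
                seen.add(res.id)

    # -- iteration -------------------------------------------------------

    def iter_residues(self):
        for cid, residues in self.chains:
            for res in residues:
                yield cid, res

    def iter_atoms(self):
        for cid, residues in self.chains:
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"unknown chain {chain_id!r}")

    @property
    def atom_count(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates in canonical order, shape (n_atoms, 3)."""
        n = self.atom_count
        out = np.empty((n, 3))
        for i, (_, _, atom) in enumerate(self.iter_atoms()):
            out[i] = atom.coords
        return out

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.atom_count, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} does not match atom count {self.atom_count}"
            )
        for i, (_, _, atom) in enumerate(self.iter_atoms()):
            atom.coords = coords[i].copy()

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


@dataclass
class Ensemble:
    """A topology plus >=1 coordinate frames in topology atom order."""

    topology: Structure
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise StructureError("ensemble must contain at least one frame")
        n = self.topology.atom_count
        checked = []
        for k, frame in enumerate(self.frames):
            frame = np.asarray(frame, dtype=float)
            if frame.shape != (n, 3):
                raise StructureError(
                    f"frame {k} has shape {frame.shape}, expected ({n}, 3)"
                )
            checked.append(frame)
        self.frames = checked

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.atom_count

    def structure_for_frame(self, frame_index: int) -> Structure:
        """A deep copy of the topology carrying the coordinates of one frame."""
        s = self.topology.copy()
        s.set_coords(self.frames[frame_index])
        return s

    @classmethod
    def from_structure(cls, structure: Structure) -> "Ensemble":
        return cls(topology=structure, frames=[structure.coords()])


@dataclass
class DimerPartition:
    """Chain-id sets naming the two binding partners."""

    partner_a: frozenset[str]
    partner_b: frozenset[str]

    def __post_init__(self) -> None:
        self.partner_a = frozenset(self.partner_a)
        self.partner_b = frozenset(self.partner_b)
        if not self.partner_a or not self.partner_b:
            raise StructureError("both partners must contain at least one chain")
        if self.partner_a & self.partner_b:
            raise StructureError(f"partners overlap: {sorted(self.partner_a & self.partner_b)}")

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.partner_a:
            return "A"
        if chain_id in self.partner_b:
            return "B"
        raise KeyError(f"chain {chain_id!r} not in partition")

    def atom_indices(self, structure: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Canonical-order atom index arrays for partner A and partner B."""
        idx_a, idx_b = [], []
        for i, (cid, _, _) in enumerate(structure.iter_atoms()):
            if cid in self.partner_a:
                idx_a.append(i)
            elif cid in self.partner_b:
                idx_b.append(i)
        return np.asarray(idx_a, dtype=int), np.asarray(idx_b, dtype=int)


# ---------------------------------------------------------------------------
# biotite conversion
# ---------------------------------------------------------------------------

def _from_atom_array(array: struc.AtomArray) -> Structure:
    chains: list[tuple[str, list[Residue]]] = []
    cur_chain: str | None = None
    cur_res_key = None
    residues: list[Residue] = []
    res: Residue | None = None
    has_occ = "occupancy" in array.get_annotation_categories()
    has_serial = "atom_id" in array.get_annotation_categories()
    for i in range(array.array_length()):
        cid = str(array.chain_id[i])
        if cid != cur_chain:
            if cur_chain is not None:
                chains.append((cur_chain, residues))
            cur_chain, residues, cur_res_key = cid, [], None
        key = (int(array.res_id[i]), str(array.ins_code[i]).strip())
        if key != cur_res_key:
            res = Residue(name=str(array.res_name[i]), number=key[0], insertion_code=key[1])
            residues.append(res)
            cur_res_key = key
        res.atoms.append(
            Atom(
                serial=int(array.atom_id[i]) if has_serial else i + 1,
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                coords=np.array(array.coord[i], dtype=float),
                occupancy=float(array.occupancy[i]) if has_occ else 1.0,
            )
        )
    if cur_chain is not None:
        chains.append((cur_chain, residues))
    return Structure(chains=chains)


def _to_atom_array(structure: Structure, coords: np.ndarray | None = None) -> struc.AtomArray:
    n = structure.atom_count
    array = struc.AtomArray(n)
    array.add_annotation("occupancy", dtype=float)
    array.add_annotation("atom_id", dtype=int)
    for i, (cid, res, atom) in enumerate(structure.iter_atoms()):
        array.chain_id[i] = cid
        array.res_id[i] = res.number
        array.ins_code[i] = res.insertion_code
        array.res_name[i] = res.name
        array.atom_name[i] = atom.name
        array.element[i] = atom.element
        array.hetero[i] = False
        array.occupancy[i] = atom.occupancy
        # PDB serial field is 5 columns; wrap deterministically on overflow
        array.atom_id[i] = (i % 99999) + 1
    array.coord = np.asarray(coords if coords is not None else structure.coords(), dtype=np.float32)
    return array


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, keep_het: bool = False) -> Ensemble:
    """Read a (possibly multi-MODEL) PDB file into an :class:`Ensemble`.

    One frame is produced per MODEL record (a single frame if there are
    none).  Waters and counterions are always removed, HETATM records are
    removed unless ``keep_het``, and for alternate locations only the
    highest-occupancy conformer is retained.
    """
    path = Path(path)
    try:
        pdb_file = _pdb.PDBFile.read(str(path))
    except OSError as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    try:
        stack = pdb_file.get_structure(
            model=None, altloc="occupancy", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:  # biotite raises on inconsistent MODEL blocks
        raise StructureError(f"{path}: inconsistent or unparsable MODEL records ({exc})") from exc

    mask = ~np.isin(stack.res_name, list(SOLVENT_NAMES | ION_NAMES))
    if not keep_het:
        mask &= ~stack.hetero
    stack = stack[..., mask]
    if stack.array_length() == 0:
        raise StructureError(f"{path}: zero atoms after filtering")

    topology = _from_atom_array(stack[0])
    frames = [np.asarray(stack.coord[k], dtype=float) for k in range(stack.stack_depth())]
    topology.set_coords(frames[0])
    return Ensemble(topology=topology, frames=frames)


def write_structure(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as PDB text, one MODEL block per frame.

    Single-frame ensembles are written without MODEL records.  Coordinates
    survive a round trip to 0.001 A (PDB fixed-width precision); atom serials
    beyond 99999 wrap around to keep the fixed-width format intact.
    """
    pdb_file = _pdb.PDBFile()
    if ensemble.n_frames == 1:
        pdb_file.set_structure(_to_atom_array(ensemble.topology, ensemble.frames[0]))
    else:
        template = _to_atom_array(ensemble.topology, ensemble.frames[0])
        stack = struc.stack([template] * ensemble.n_frames)
        stack.coord = np.asarray(np.stack(ensemble.frames), dtype=np.float32)
        pdb_file.set_structure(stack)
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


def partition_dimer(
    ensemble: Ensemble, chains_a: list[str], chains_b: list[str]
) -> DimerPartition:
    """Partition the ensemble's chains into the two binding partners."""
    known = set(ensemble.topology.chain_ids)
    for cid in list(chains_a) + list(chains_b):
        if cid not in known:
            raise StructureError(f"unknown chain {cid!r}; structure has {sorted(known)}")
    part = DimerPartition(frozenset(chains_a), frozenset(chains_b))
    return part


def renumber(structure: Structure, chain_id: str, offset: int) -> Structure:
    """Return a copy with every residue number of one chain shifted by ``offset``.

    Used to move author (construct) numbering onto a full-length reference
    convention, e.g. placing a CTD model at its UniProt positions.
    """
    out = structure.copy()
    residues = out.chain(chain_id)
    seen = set()
    for res in residues:
        res.number += offset
        if res.id in seen:
            raise StructureError(
                f"renumbering chain {chain_id} by {offset} duplicates residue {res.number}{res.insertion_code}"
            )
        seen.add(res.id)
    return out
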