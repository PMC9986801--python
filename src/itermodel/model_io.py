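"""Atomic model hierarchy and PDB/mmCIF input/output.

The in-memory representation is a small chain/residue/atom hierarchy that the
rest of the toolkit operates on.  File parsing and serialization are delegated
to :mod:`biotite.structure.io`; this module only converts between biotite's
flat ``AtomArray`` and the hierarchy, applying the toolkit's normalization
rules (first model only, altloc blank-or-A, protein residues only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure
from biotite.structure.io.pdbx import set_structure as cif_set_structure

logger = logging.getLogger(__name__)

Provenance = Literal["predicted", "rebuilt", "deposited"]

#: Atom names considered main chain; everything else counts as "beyond CA"
#: for side-chain B-factor adjustment.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Electron counts for the elements that occur in protein models.
ELECTRON_COUNT = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "SE": 34,
}


class ModelError(Exception):
    """Raised for malformed or empty models."""


class EmptyModelError(ModelError):
    """Raised when an operation produces or encounters a model with no atoms."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # Cartesian angstroms, shape (3,)
    b_iso: float = 0.0  # ADP in A^2, or pLDDT for predicted models
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ModelError(f"atom position must be a 3-vector, got {self.position.shape}")
        if self.b_iso < 0:
            raise ModelError(f"negative b_iso {self.b_iso} for atom {self.name}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.b_iso, self.occupancy)


@dataclass
class Residue:
    number: int
    name: str = "ALA"
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name == "CA":
                return atom
        return None

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, self.insertion_code,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AtomicModel:
    """Hierarchical atomic model: ordered chains of ordered residues of atoms."""

    chains: list[Chain] = field(default_factory=list)
    provenance: Provenance = "deposited"

    # -- construction / copies ------------------------------------------------

    def copy(self) -> "AtomicModel":
        return AtomicModel([c.copy() for c in self.chains], self.provenance)

    # -- bookkeeping ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def iter_chain_residues(self) -> Iterator[tuple[str, Residue]]:
        for chain in self.chains:
            for residue in chain.residues:
                yield chain.id, residue

    def residue_keys(self) -> list[tuple[str, int]]:
        return [(cid, res.number) for cid, res in self.iter_chain_residues()]

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in model")

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array, model order."""
        coords = [a.position for r in self.iter_residues() for a in r.atoms]
        if not coords:
            return np.empty((0, 3))
        return np.array(coords)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ModelError(f"coordinate array shape {coords.shape} does not match "
                             f"{self.n_atoms} atoms")
        i = 0
        for residue in self.iter_residues():
            for atom in residue.atoms:
                atom.position = coords[i].copy()
                i += 1

    def select_residues(self, keys: Sequence[tuple[str, int]]) -> "AtomicModel":
        """Sub-model containing exactly the residues named by (chain-id, number)."""
        wanted = set(keys)
        chains = []
        for chain in self.chains:
            kept = [r.copy() for r in chain.residues if (chain.id, r.number) in wanted]
            if kept:
                chains.append(Chain(chain.id, kept))
        return AtomicModel(chains, self.provenance)

    def validate(self) -> None:
        for chain in self.chains:
            keys = [r.sort_key for r in chain.residues]
            if keys != sorted(keys):
                raise ModelError(f"residues of chain {chain.id!r} are not sorted")
            if len(set(keys)) != len(keys):
                raise ModelError(f"duplicate residue numbers in chain {chain.id!r}")


@dataclass
class SymmetryOperator:
    """A crystallographic symmetry operation with optional allowed origin shift."""

    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3-vector
    fractional: bool = True
    allowed_origin_shift: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.allowed_origin_shift = np.asarray(self.allowed_origin_shift, dtype=float)
        identity = self.rotation @ self.rotation.T
        if not np.allclose(identity, np.eye(3), atol=1e-6):
            raise ModelError("symmetry rotation is not orthogonal")
        det = np.linalg.det(self.rotation)
        if not (abs(abs(det) - 1.0) < 1e-6):
            raise ModelError(f"symmetry rotation determinant {det} is not +/-1")

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(np.eye(3), np.zeros(3), fractional=True)


# ---------------------------------------------------------------------------
# File I/O (biotite-backed)
# ---------------------------------------------------------------------------

_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL", "UNK", "SEC", "PYL",
})


def _detect_format(path: Path, format: str) -> str:
    if format in ("pdb", "mmcif"):
        return format
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # content sniff: mmCIF files start with a data block
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            return "mmcif" if line.startswith(("data_", "#")) else "pdb"
    return "pdb"


def read_model(path: str | Path, format: str = "auto",
               provenance: Provenance = "deposited") -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Only the first model of multi-model files is used.  Alternate conformers
    other than blank/'A' are dropped, as are waters, ligands and nucleic
    acids (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    fmt = _detect_format(path, format)
    extra = ["b_factor", "occupancy"]
    if fmt == "pdb":
        pdb_file = PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1, extra_fields=extra)
    else:
        cif_file = CIFFile.read(str(path))
        array = cif_get_structure(cif_file, model=1, extra_fields=extra)
    return _from_atom_array(array, provenance)


def _from_atom_array(array: struc.AtomArray, provenance: Provenance) -> AtomicModel:
    # keep altloc blank or 'A' only
    if "altloc_id" in array.get_annotation_categories():
        keep = np.isin(array.altloc_id, ("", ".", "?", "A"))
        array = array[keep]
    is_protein = np.isin(array.res_name, list(_AMINO_ACIDS))
    n_dropped = int(np.sum(~is_protein))
    if n_dropped:
        logger.info("dropped %d non-protein atoms on read", n_dropped)
    array = array[is_protein]
    if array.array_length() == 0:
        raise EmptyModelError("no protein atoms parsed from file")

    model = AtomicModel(provenance=provenance)
    chain: Chain | None = None
    residue: Residue | None = None
    ins_codes = (array.ins_code if "ins_code" in array.get_annotation_categories()
                 else np.full(array.array_length(), "", dtype="U1"))
    for i in range(array.array_length()):
        cid = str(array.chain_id[i])
        resnum = int(array.res_id[i])
        icode = str(ins_codes[i]).strip()
        rname = str(array.res_name[i])
        if chain is None or chain.id != cid:
            chain = Chain(cid)
            model.chains.append(chain)
            residue = None
        if residue is None or (residue.number, residue.insertion_code) != (resnum, icode):
            residue = Residue(resnum, rname, icode)
            chain.residues.append(residue)
        residue.atoms.append(Atom(
            name=str(array.atom_name[i]),
            element=str(array.element[i]).upper(),
            position=np.round(array.coord[i].astype(float), 3),
            b_iso=float(array.b_factor[i]),
            occupancy=float(array.occupancy[i]),
        ))
    for chain in model.chains:
        chain.residues.sort(key=lambda r: r.sort_key)
    return model


def _to_atom_array(model: AtomicModel) -> struc.AtomArray:
    n = model.n_atoms
    array = struc.AtomArray(n)
    array.add_annotation("b_factor", dtype=float)
    array.add_annotation("occupancy", dtype=float)
    i = 0
    for chain in model.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                array.chain_id[i] = chain.id
                array.res_id[i] = residue.number
                array.ins_code[i] = residue.insertion_code
                array.res_name[i] = residue.name
                array.atom_name[i] = atom.name
                array.element[i] = atom.element
                array.coord[i] = atom.position
                array.b_factor[i] = round(float(atom.b_iso), 2)
                array.occupancy[i] = atom.occupancy
                array.hetero[i] = False
                i += 1
    return array


def write_model(model: AtomicModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB (fixed-column) or mmCIF."""
    path = Path(path)
    if model.n_atoms == 0:
        raise EmptyModelError("refusing to write an empty model")
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "pdb":
        if model.n_atoms > 99999:
            raise ModelError("more than 99999 atoms cannot be written as PDB; use mmCIF")
        if any(len(c.id) > 1 for c in model.chains):
            raise ModelError("chain ids longer than 1 character cannot be written as "
                             "PDB; use mmCIF")
        pdb_file = PDBFile()
        pdb_file.set_structure(_to_atom_array(model))
        pdb_file.write(str(path))
    elif fmt == "mmcif":
        cif_file = CIFFile()
        cif_set_structure(cif_file, _to_atom_array(model))
        cif_file.write(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# CA extraction
# ---------------------------------------------------------------------------


def extract_ca(model: AtomicModel) -> tuple[list[tuple[str, int, np.ndarray]], int]:
    """Ordered (chain-id, residue-number, CA position) entries.

    Residues lacking a CA atom are skipped; the skip count is returned
    alongside the entries.
    """
    entries: list[tuple[str, int, np.ndarray]] = []
    skipped = 0
    for cid, residue in model.iter_chain_residues():
        ca = residue.ca
        if ca is None:
            skipped += 1
        else:
            entries.append((cid, residue.number, ca.position.copy()))
    return entries, skipped


def ca_coords(model: AtomicModel) -> np.ndarray:
    """CA positions as an (n, 3) array, model order; residues without CA skipped."""
    entries, _ = extract_ca(model)
    if not entries:
        return np.empty((0, 3))
    return np.array([pos for _, _, pos in entries])
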