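"""Readers/writers for the molecular formats the pipeline touches.

Proteins arrive as PDB files and are normalised into a flat array-of-atoms
container (:class:`ProteinStructure`); ligands arrive as SDF/MOL2/PDB with
3-D coordinates, bond orders and explicit polar hydrogens and are wrapped
around an RDKit molecule (:class:`Ligand`).  Predicted or crystallographic
waters are exchanged as PDB ``HETATM`` oxygen records
(:class:`WaterRecord`).

Conventions
-----------
* Coordinates are in Angstrom throughout; no unit conversion anywhere.
* Alternate locations: the highest-occupancy conformer is kept, ties broken
  by file order.  Only the first MODEL of a multi-model file is read.
* Protonation is an input contract: the ligand must arrive with its polar
  hydrogens; the package never changes protonation silently.
* In water output the B-factor column carries the docking score times -10
  (rounded to 2 decimals) for predicted sites, so that favourable sites get
  large positive B values; the convention is restated in the file header.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "H2O", "TIP", "TIP3", "SOL", "DOD"}

#: per-atom interaction classes used by the scorer
HYDROPHOBIC = "hydrophobic"
DONOR = "donor"
ACCEPTOR = "acceptor"
DONOR_ACCEPTOR = "donor_acceptor"
OTHER = "other"


@dataclass
class WaterRecord:
    """A single water oxygen: predicted by the pipeline or crystallographic."""

    coords: np.ndarray
    source: str = "predicted"  # "predicted" | "crystallographic"
    score: Optional[float] = None  # kcal/mol, present iff predicted
    structure_tag: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("water coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("water coordinates must be finite")
        if self.source == "predicted" and self.score is None:
            raise ValueError("predicted waters must carry a score")
        if self.source == "crystallographic" and self.score is not None:
            raise ValueError("crystallographic waters carry no score")


@dataclass
class ProteinStructure:
    """Flat atom table for the receptor.

    ``interaction_types`` holds the per-atom class used by the scoring
    function (one of the module-level constants); entries may be ``None``
    until :func:`aquabridge.water_scoring.assign_interaction_types` runs.
    Synthetic pockets may declare types up front, in which case assignment
    is a pass-through.
    """

    serial: np.ndarray
    name: list
    residue_name: list
    residue_id: np.ndarray
    chain: list
    element: list
    coords: np.ndarray
    occupancy: np.ndarray
    interaction_types: list = field(default_factory=list)
    waters: list = field(default_factory=list)  # crystallographic WaterRecord

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("protein coordinates must be finite")
        if not self.interaction_types:
            self.interaction_types = [None] * self.n_atoms

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.element], dtype=bool)


@dataclass
class Ligand:
    """Ligand with 3-D coordinates, bond orders and resolved polar hydrogens.

    Wraps the RDKit molecule it was built from (``mol``, hydrogens kept
    explicit) next to plain numpy views used by the geometry code.  Atom
    indices refer to ``mol``'s atom numbering.
    """

    mol: Chem.Mol
    elements: list
    coords: np.ndarray
    formal_charges: np.ndarray
    bonds: list  # (i, j, order) with order in {1, 2, 3, "ar"}
    approximate_bonds: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_indices(self) -> list:
        return [i for i, e in enumerate(self.elements) if e != "H"]

    def heavy_coords(self) -> np.ndarray:
        return self.coords[[i for i, e in enumerate(self.elements) if e != "H"]]

    def n_hydrogens(self, idx: int) -> int:
        """Total hydrogen count (explicit + implicit) on heavy atom ``idx``."""
        return self.mol.GetAtomWithIdx(idx).GetTotalNumHs(includeNeighbors=True)

    def hydrogen_neighbors(self, idx: int) -> list:
        return [
            nb.GetIdx()
            for nb in self.mol.GetAtomWithIdx(idx).GetNeighbors()
            if nb.GetAtomicNum() == 1
        ]

    def heavy_neighbors(self, idx: int) -> list:
        return sorted(
            nb.GetIdx()
            for nb in self.mol.GetAtomWithIdx(idx).GetNeighbors()
            if nb.GetAtomicNum() != 1
        )


def mol_to_ligand(mol: Chem.Mol, approximate_bonds: bool = False) -> Ligand:
    """Normalise an RDKit molecule (explicit Hs kept) into a :class:`Ligand`."""
    if mol is None:
        raise ValueError("could not parse ligand molecule")
    if mol.GetNumConformers() == 0:
        raise ValueError("ligand has no 3-D coordinates")
    conf = mol.GetConformer()
    if not conf.Is3D() and mol.GetNumAtoms() > 1:
        coords = conf.GetPositions()
        if np.allclose(coords[:, 2], 0.0) and np.allclose(coords[:, 1], 0.0):
            raise ValueError("ligand coordinates are not 3-D")
    coords = np.asarray(conf.GetPositions(), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("ligand coordinates must be finite")
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if len(heavy) > 1:
        frags = Chem.GetMolFrags(mol)
        heavy_frags = {
            f for f, atoms in enumerate(frags)
            if any(mol.GetAtomWithIdx(i).GetAtomicNum() > 1 for i in atoms)
        }
        if len(heavy_frags) > 1:
            raise ValueError("ligand heavy-atom graph is disconnected")
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: "ar",
    }
    bonds = []
    for b in mol.GetBonds():
        o = order_map.get(b.GetBondType())
        if o is None:
            o = 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), o))
    return Ligand(
        mol=mol,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        formal_charges=np.array([a.GetFormalCharge() for a in mol.GetAtoms()]),
        bonds=bonds,
        approximate_bonds=approximate_bonds,
    )


def read_ligand(path, format: Optional[str] = None, on_missing_bonds: str = "error") -> Ligand:
    """Read a ligand from SDF / MOL2 / PDB.

    PDB input carries no bond orders; they are perceived from the geometry
    and flagged approximate.  ``on_missing_bonds`` controls whether a PDB
    ligand without CONECT records and without hydrogens is an ``"error"``
    (default) or a ``"warn"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    approximate = False
    if fmt in ("sdf", "mol", "sd"):
        mol = Chem.MolFromMolFile(str(path), removeHs=False)
    elif fmt == "mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    elif fmt == "pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
        approximate = True
        if mol is not None:
            has_h = any(a.GetAtomicNum() == 1 for a in mol.GetAtoms())
            has_conect = any(
                line.startswith("CONECT") for line in path.read_text().splitlines()
            )
            if not has_h and not has_conect:
                msg = (
                    "PDB ligand has neither hydrogens nor CONECT records; "
                    "bond orders and protonation are guesses"
                )
                if on_missing_bonds == "error":
                    raise ValueError(msg)
                warnings.warn(msg)
    else:
        raise ValueError(f"unsupported ligand format: {fmt!r}")
    if mol is None:
        raise ValueError(f"could not parse ligand file {path}")
    return mol_to_ligand(mol, approximate_bonds=approximate)


def read_protein(path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Polymer ``ATOM`` records populate the atom table; ``HETATM`` waters are
    collected on ``.waters``.  Highest-occupancy altloc wins (ties: first in
    file); only the first model is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no atoms parsed from {path}")
    model = st[0]

    serial, name, resname, resid, chain_ids, element, coords, occ = (
        [], [], [], [], [], [], [], []
    )
    waters = []
    # altloc bookkeeping: key -> index into the retained lists
    seen: dict = {}
    for ch in model:
        for res in ch:
            is_water = res.name.strip() in WATER_RESNAMES or res.is_water()
            for atom in res:
                if is_water:
                    if atom.element.name.upper() == "O" or atom.name.strip().startswith("O"):
                        waters.append(
                            WaterRecord(
                                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                source="crystallographic",
                                structure_tag=path.stem,
                            )
                        )
                    continue
                if res.het_flag == "H":
                    continue  # non-water heteroatoms (ligands, ions) are not receptor
                key = (ch.name, res.seqid.num, res.seqid.icode, atom.name)
                if key in seen:
                    prev = seen[key]
                    if atom.occ > occ[prev]:
                        # replace in place, preserving file order of first sighting
                        serial[prev] = atom.serial
                        coords[prev] = [atom.pos.x, atom.pos.y, atom.pos.z]
                        occ[prev] = atom.occ
                    continue
                seen[key] = len(serial)
                serial.append(atom.serial)
                name.append(atom.name)
                resname.append(res.name)
                resid.append(res.seqid.num)
                chain_ids.append(ch.name)
                element.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                occ.append(atom.occ)
    if not serial and not waters:
        # a coordinate-free but well-formed PDB (e.g. a header-only waters
        # file) is an empty structure; anything else is unreadable
        keywords = ("REMARK", "HEADER", "TITLE", "CRYST1", "MODEL", "TER", "END")
        text = path.read_text(errors="replace")
        has_records = any(
            line.startswith(("ATOM", "HETATM")) for line in text.splitlines()
        )
        well_formed = any(
            line.startswith(keywords) for line in text.splitlines()
        )
        if has_records or not well_formed:
            raise ValueError(f"zero atoms parsed from {path}")
    return ProteinStructure(
        serial=np.array(serial, dtype=int),
        name=name,
        residue_name=resname,
        residue_id=np.array(resid, dtype=int),
        chain=chain_ids,
        element=element,
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        occupancy=np.array(occ, dtype=float),
        waters=waters,
    )


def write_waters(records: Sequence[WaterRecord], path) -> Path:
    """Write waters as a PDB of HETATM HOH oxygen records.

    For predicted sites the B-factor column carries ``score * -10`` rounded
    to two decimals (documented in the header); crystallographic waters get
    B = 0.
    """
    path = Path(path)
    lines = [
        "REMARK   3 AQUABRIDGE PREDICTED WATER OXYGENS",
        "REMARK   3 B-FACTOR COLUMN = DOCKING SCORE (KCAL/MOL) * -10",
    ]
    for i, rec in enumerate(records, start=1):
        if not np.all(np.isfinite(rec.coords)):
            raise ValueError("cannot write non-finite water coordinates")
        b = 0.0 if rec.score is None else round(rec.score * -10.0, 2)
        x, y, z = rec.coords
        lines.append(
            f"HETATM{i:5d}  O   HOH W{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           O"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_protein(protein: ProteinStructure, path) -> Path:
    """Write a :class:`ProteinStructure` (plus its waters) back to PDB."""
    path = Path(path)
    lines = []
    for i in range(protein.n_atoms):
        nm = protein.name[i]
        nm4 = f" {nm:<3s}" if len(nm) < 4 else nm[:4]
        x, y, z = protein.coords[i]
        lines.append(
            f"ATOM  {int(protein.serial[i]) % 100000:5d} {nm4}"
            f" {protein.residue_name[i][:3]:>3s} {protein.chain[i][:1]:1s}"
            f"{int(protein.residue_id[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{protein.occupancy[i]:6.2f}{0.0:6.2f}"
            f"          {protein.element[i]:>2s}"
        )
    for j, w in enumerate(protein.waters, start=1):
        x, y, z = w.coords
        lines.append(
            f"HETATM{(protein.n_atoms + j) % 100000:5d}  O   HOH W{j % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           O"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
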