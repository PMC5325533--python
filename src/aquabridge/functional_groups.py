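"""Detection of the polar functional-group motifs that carry hydration shells.

Eleven motif kinds are recognised (carbonyl, carboxyl, cyano, imine, nitro,
amine, sulfonyl, phosphoryl, hydroxyl, ether, halogen), each with a
hydrogen-bond saturation limit derived from VSEPR lone pairs or bound
hydrogens.  Detection runs SMARTS patterns in a fixed precedence order so
that every polar atom is claimed by at most one motif:

    carboxyl > nitro > sulfonyl/phosphoryl > carbonyl > hydroxyl/ether
    > amine/imine/cyano > halogen

Chemistry notes baked into the defaults:

* amide oxygens count as carbonyl and amide N-H as amine (per-atom logic;
  there is no separate amide motif);
* ester alkoxy oxygens are ethers; deprotonated carboxylates behave exactly
  like protonated carboxyls;
* pyridine-like aromatic N (no H) maps to imine, pyrrole-like N-H to amine;
* the amine saturation limit is the number of bound hydrogens; the carboxyl
  (and every per-oxygen) limit applies per oxygen atom.

Each motif also carries a right-handed orthonormal local frame per polar
atom: z points from the bonded heavy neighbour to the polar atom, x lies in
the plane spanned with the neighbour's other heavy substituent, y = z x x.
For linear groups (cyano) there is no plane; x falls back deterministically
to the smallest-index Cartesian axis not parallel to z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from aquabridge.structure_io import Ligand

logger = logging.getLogger(__name__)


class MotifKind(str, Enum):
    CARBONYL = "carbonyl"
    CARBOXYL = "carboxyl"
    CYANO = "cyano"
    IMINE = "imine"
    NITRO = "nitro"
    AMINE = "amine"
    SULFONYL = "sulfonyl"
    PHOSPHORYL = "phosphoryl"
    HYDROXYL = "hydroxyl"
    ETHER = "ether"
    HALOGEN = "halogen"


#: hydrogen-bond saturation limits; amine resolves to its hydrogen count
HBOND_LIMITS: Dict[MotifKind, Optional[int]] = {
    MotifKind.CARBONYL: 2,
    MotifKind.CARBOXYL: 2,
    MotifKind.CYANO: 1,
    MotifKind.IMINE: 1,
    MotifKind.NITRO: 2,
    MotifKind.AMINE: None,  # number of bound hydrogens
    MotifKind.SULFONYL: 2,
    MotifKind.PHOSPHORYL: 2,
    MotifKind.HYDROXYL: 3,
    MotifKind.ETHER: 2,
    MotifKind.HALOGEN: 1,
}

# SMARTS per kind; the first atom map in each tuple lists which match
# positions are the shell-bearing polar atoms.  Users may override these in
# a config file; the shipped defaults reproduce the definitions above.
MOTIF_SMARTS: List[Tuple[MotifKind, str, Tuple[int, ...]]] = [
    (MotifKind.CARBOXYL, "[CX3](=[OX1])[OX2H1,OX1-]", (1, 2)),
    (MotifKind.NITRO, "[$([NX3](=O)=O),$([NX3+](=O)[O-])](~[OX1])~[OX1]", (1, 2)),
    (MotifKind.SULFONYL, "[#16X4](=[OX1])(=[OX1])", (1, 2)),
    (MotifKind.PHOSPHORYL, "[PX4](=[OX1])", (1,)),
    (MotifKind.CARBONYL, "[CX3]=[OX1]", (1,)),
    (MotifKind.HYDROXYL, "[OX2H1][#6,#16X4,PX4]", (0,)),
    (MotifKind.ETHER, "[OX2H0]([!#1])[!#1]", (0,)),
    (MotifKind.CYANO, "[NX1]#[CX2]", (0,)),
    (MotifKind.IMINE, "[NX2;$([NX2]=[#6]);H0,H1]", (0,)),
    (MotifKind.IMINE, "[nX2H0]", (0,)),  # pyridine-like aromatic N
    (MotifKind.AMINE, "[#7;X3,X4;!$([#7]=*);!$([#7]#*);H1,H2,H3]", (0,)),
    (MotifKind.HALOGEN, "[F,Cl,Br,I;$([F,Cl,Br,I][#6])]", (0,)),
]

#: deprotonated phosphate/phosphonate oxygens join the phosphoryl motif
_PHOSPHORYL_ANION = "[PX4][OX1-]"


@dataclass
class Motif:
    """A detected functional group: shell-bearing atoms, limit and frames."""

    kind: MotifKind
    polar_atoms: List[int]
    neighbor_atoms: Dict[int, List[int]]
    hbond_limit: int
    frames: Dict[int, np.ndarray] = field(default_factory=dict)  # 3x3, rows x,y,z

    def frame(self, polar_atom: int) -> np.ndarray:
        return self.frames[polar_atom]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector cannot be normalised")
    return v / n


def build_frame(ligand: Ligand, motif: Motif, polar_atom: int) -> np.ndarray:
    """Right-handed orthonormal triad (rows x, y, z) for one polar atom.

    z points from the anchoring heavy neighbour to the polar atom; x lies in
    the plane of (polar atom, neighbour, neighbour's other heavy
    substituent).  Linear/degenerate cases fall back to the smallest-index
    Cartesian axis not parallel to z, orthogonalised against z.
    """
    heavy_nb = ligand.heavy_neighbors(polar_atom)
    if not heavy_nb:
        # hydroxyl O bonded only to H would be water, not a ligand group
        raise ValueError(f"atom {polar_atom} has no heavy neighbour; cannot frame")
    anchor = heavy_nb[0]
    p = ligand.coords[polar_atom]
    n = ligand.coords[anchor]
    z = _unit(p - n)

    # other heavy substituent of the anchor defines the motif plane; prefer
    # a sibling polar atom of the same motif (e.g. the second carboxyl O),
    # which pins the frame to the motif plane exactly
    other = sorted(
        (i for i in ligand.heavy_neighbors(anchor) if i != polar_atom),
        key=lambda i: (i not in motif.polar_atoms, i),
    )
    x = None
    if other:
        v = ligand.coords[other[0]] - n
        v_perp = v - np.dot(v, z) * z
        if np.linalg.norm(v_perp) > 1e-8:
            x = _unit(v_perp)
    if x is None:
        # deterministic fallback: smallest-index axis not parallel to z
        for axis in np.eye(3):
            if abs(np.dot(axis, z)) < 1.0 - 1e-9:
                v_perp = axis - np.dot(axis, z) * z
                x = _unit(v_perp)
                break
    y = np.cross(z, x)
    frame = np.vstack([x, y, z])
    # orthonormality guard
    assert np.allclose(frame @ frame.T, np.eye(3), atol=1e-9)
    return frame


def _match_sets(mol: Chem.Mol, smarts: str) -> List[Tuple[int, ...]]:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:  # pragma: no cover - shipped SMARTS are valid
        raise ValueError(f"invalid SMARTS {smarts!r}")
    return list(mol.GetSubstructMatches(patt))


def detect_motifs(ligand: Ligand, exclude_heavy_halogens: bool = False,
                  smarts_table: Optional[Sequence] = None) -> List[Motif]:
    """Detect all shell-bearing motifs on a ligand.

    Every N/O/halogen atom is claimed by at most one motif; precedence is
    the table order of ``MOTIF_SMARTS``.  Unmatched polar atoms are logged,
    never fatal.  ``exclude_heavy_halogens`` drops Cl/Br/I motifs (F is
    always kept), reflecting that heavier halogens are rarely hydrated.
    """
    mol = ligand.mol
    table = smarts_table if smarts_table is not None else MOTIF_SMARTS
    claimed: set = set()
    motifs: List[Motif] = []

    for kind_name, smarts, polar_pos in table:
        kind = kind_name if isinstance(kind_name, MotifKind) else MotifKind(kind_name)
        groups: Dict[Tuple[int, ...], List[int]] = {}
        for match in _match_sets(mol, smarts):
            polar = [match[i] for i in polar_pos]
            # one motif per distinct polar-atom set (symmetric SMARTS can
            # match a group twice with swapped atom order)
            key = tuple(sorted(polar))
            groups.setdefault(key, polar)
        for polar in groups.values():
            if any(a in claimed for a in polar):
                continue
            if kind is MotifKind.PHOSPHORYL:
                # fold P-O(-) oxygens of the same phosphorus into the motif
                p_idx = next(
                    nb for nb in ligand.heavy_neighbors(polar[0])
                    if mol.GetAtomWithIdx(nb).GetAtomicNum() == 15
                )
                for m in _match_sets(mol, _PHOSPHORYL_ANION):
                    if m[0] == p_idx and m[1] not in claimed and m[1] not in polar:
                        polar.append(m[1])
            if kind is MotifKind.HALOGEN and exclude_heavy_halogens:
                if mol.GetAtomWithIdx(polar[0]).GetAtomicNum() != 9:
                    claimed.update(polar)
                    continue
            limit = HBOND_LIMITS[kind]
            if limit is None:  # amine: number of bound hydrogens
                limit = ligand.n_hydrogens(polar[0])
                if limit == 0:
                    continue  # tertiary amine: no shell
            neighbor_atoms = {a: ligand.heavy_neighbors(a) for a in polar}
            motif = Motif(
                kind=kind,
                polar_atoms=list(polar),
                neighbor_atoms=neighbor_atoms,
                hbond_limit=limit,
            )
            for a in polar:
                motif.frames[a] = build_frame(ligand, motif, a)
            motifs.append(motif)
            claimed.update(polar)

    unmatched = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetAtomicNum() in (7, 8) and a.GetIdx() not in claimed
    ]
    if unmatched:
        logger.info("polar atoms not assigned to any motif: %s", unmatched)
    return motifs
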