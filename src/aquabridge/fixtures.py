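"""Synthetic inputs for testing and demonstration; no downloads required.

Three generators cover the pipeline's input space:

* :func:`make_ligand` — small rigid molecules with idealised geometry and
  explicit hydrogens, one or more per functional-group motif (built from
  SMILES with a fixed embedding seed, so results are bit-reproducible);
* :func:`make_pocket` — a synthetic "binding pocket" of typed pseudo-atoms
  arranged so that the scoring function has favourable minima exactly at a
  chosen subset of the ligand's shell sites (the *planted* sites) and is
  unfavourable at every other shell site.  The arrangement is verified at
  generation time by refining every shell site; generation fails loudly if
  the certificate does not hold, which makes end-to-end recovery tests
  well-posed by construction;
* :func:`make_trajectory` — water-oxygen frames sampled from isotropic
  Gaussian clouds around known centres plus uniform background noise,
  emulating the saved frames of a solvated-ligand simulation at reduced
  scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from aquabridge.functional_groups import MotifKind, detect_motifs
from aquabridge.hydration_model import build_all_shells
from aquabridge.site_selection import SelectionParams
from aquabridge.structure_io import (
    ACCEPTOR,
    DONOR,
    HYDROPHOBIC,
    Ligand,
    ProteinStructure,
    mol_to_ligand,
)
from aquabridge.water_scoring import ScoringParams, local_refine, _scoring_arrays

logger = logging.getLogger(__name__)

#: embedding seed for ligand templates (fixed: fixtures are reproducible)
_EMBED_SEED = 61437

LIGAND_SMILES = {
    "ethanol": "CCO",
    "acetate": "CC(=O)[O-]",
    "acetamide": "CC(N)=O",
    "methylamine": "CN",
    "dimethylether": "COC",
    "acetonitrile": "CC#N",
    "nitromethane": "C[N+](=O)[O-]",
    "methanesulfonyl": "CS(C)(=O)=O",
    "methylphosphate": "COP(=O)(O)O",
    "chlorobenzene": "Clc1ccccc1",
    "pyridine": "c1ccncc1",
    # apolar control
    "benzene": "c1ccccc1",
}


@dataclass
class FixtureSpec:
    """Parameters of a seeded synthetic fixture."""

    seed: int = 0
    ligand_template: str = "acetamide"
    n_planted: int = 1
    n_hydrophobic: int = 4
    # trajectory parameters
    n_frames: int = 2000
    cloud_sigma: float = 0.3  # A
    cloud_centres: Sequence = field(default_factory=list)
    noise_per_frame: int = 1
    box_half: float = 6.0  # A, uniform-noise box half-width


def make_ligand(template: str) -> Ligand:
    """Build a named small-molecule template with explicit hydrogens."""
    if template not in LIGAND_SMILES:
        raise KeyError(f"unknown ligand template {template!r}; "
                       f"choose from {sorted(LIGAND_SMILES)}")
    mol = Chem.MolFromSmiles(LIGAND_SMILES[template])
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:  # pragma: no cover
        raise RuntimeError(f"embedding failed for template {template!r}")
    AllChem.MMFFOptimizeMolecule(mol)
    return mol_to_ligand(mol)


def _pocket_atoms_for_site(site: np.ndarray, away: np.ndarray, rng: np.random.Generator,
                           contact_dist: float = 2.75, cone_deg: float = 35.0
                           ) -> List[np.ndarray]:
    """Three acceptor positions around a planted site, on its solvent side.

    One H-bond partner alone reaches only about -0.2 kcal/mol, so each
    planted site gets a triad of acceptors at a surface distance of about
    -0.45 A (centre distance 2.75 A for O...O), together well below the
    -0.55 kcal/mol cutoff.
    """
    away = away / np.linalg.norm(away)
    # deterministic orthogonal pair
    ref = np.eye(3)[int(np.argmin(np.abs(away)))]
    u = np.cross(away, ref)
    u /= np.linalg.norm(u)
    v = np.cross(away, u)
    cone = np.radians(cone_deg)
    out = []
    phase = rng.uniform(0.0, 2 * np.pi)
    for k in range(3):
        ang = phase + 2 * np.pi * k / 3
        direction = np.cos(cone) * away + np.sin(cone) * (np.cos(ang) * u + np.sin(ang) * v)
        out.append(site + contact_dist * direction)
    return out


def make_pocket(spec: FixtureSpec,
                scoring: Optional[ScoringParams] = None,
                selection: Optional[SelectionParams] = None
                ) -> Tuple[ProteinStructure, Ligand, List[np.ndarray]]:
    """Synthetic pocket with score minima planted at chosen shell sites.

    Returns ``(pocket, ligand, planted_sites)``.  The generation-time
    certificate refines every candidate shell site of the ligand and
    requires planted sites below ``score_cutoff - 0.05`` and all other
    sites above ``-0.30`` (comfortably over the cutoff); otherwise it
    raises ``RuntimeError``.
    """
    scoring = scoring or ScoringParams()
    selection = selection or SelectionParams()
    rng = np.random.default_rng(spec.seed)
    ligand = make_ligand(spec.ligand_template)
    motifs = detect_motifs(ligand)
    sites = build_all_shells(ligand, motifs)
    if spec.n_planted > 0 and not sites:
        raise ValueError("ligand template generates no shell sites to plant at")

    lig_heavy = ligand.heavy_coords()
    lig_centre = lig_heavy.mean(axis=0)

    # choose planted sites: at most one per polar atom, mutually well
    # separated so clustering cannot merge them, preferring sites far from
    # the ligand body
    chosen: List[int] = []
    order = sorted(
        range(len(sites)),
        key=lambda i: -float(np.linalg.norm(sites[i].coords - lig_centre)),
    )
    used_atoms: set = set()
    for i in order:
        if len(chosen) >= spec.n_planted:
            break
        s = sites[i]
        if (s.motif_id, s.polar_atom) in used_atoms:
            continue
        if any(np.linalg.norm(s.coords - sites[j].coords) < 2.0 * selection.cluster_distance + 0.4
               for j in chosen):
            continue
        chosen.append(i)
        used_atoms.add((s.motif_id, s.polar_atom))
    if len(chosen) < spec.n_planted:
        raise RuntimeError(
            f"could not plant {spec.n_planted} separated sites on "
            f"{spec.ligand_template!r} (placed {len(chosen)})"
        )
    planted = [np.asarray(sites[i].coords, float) for i in chosen]

    # pocket pseudo-atoms: acceptor triads at planted sites ...
    coords: List[np.ndarray] = []
    types: List[str] = []
    elements: List[str] = []
    names: List[str] = []
    for site in planted:
        away = site - lig_centre
        for pos in _pocket_atoms_for_site(site, away, rng):
            coords.append(pos)
            types.append(ACCEPTOR)
            elements.append("O")
            names.append("O")
    # ... plus a hydrophobic rim far from every shell site
    shell_coords = np.array([s.coords for s in sites]).reshape(-1, 3)
    attempts = 0
    n_placed = 0
    while n_placed < spec.n_hydrophobic and attempts < 500:
        attempts += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = lig_centre + (7.0 + 2.0 * rng.uniform()) * direction
        if np.linalg.norm(shell_coords - pos, axis=1).min() < 4.5:
            continue
        coords.append(pos)
        types.append(HYDROPHOBIC)
        elements.append("C")
        names.append("C")
        n_placed += 1

    pocket = ProteinStructure(
        serial=np.arange(1, len(coords) + 1),
        name=names,
        residue_name=["PSA"] * len(coords),
        residue_id=np.arange(1, len(coords) + 1),
        chain=["A"] * len(coords),
        element=elements,
        coords=np.array(coords).reshape(-1, 3),
        occupancy=np.ones(len(coords)),
        interaction_types=list(types),
    )

    _certify(pocket, sites, chosen, scoring, selection)
    return pocket, ligand, planted


def _certify(pocket: ProteinStructure, sites, chosen, scoring: ScoringParams,
             selection: SelectionParams, margin: float = 0.05,
             off_floor: float = -0.30) -> None:
    """Grid-scan certificate: planted sites deep, all others shallow."""
    arrays = _scoring_arrays(pocket)
    for i, site in enumerate(sites):
        e = local_refine(pocket, site.coords, scoring, _arrays=arrays).energy
        if i in chosen:
            if e > selection.score_cutoff - margin:
                raise RuntimeError(
                    f"pocket certificate failed: planted site {i} refines to "
                    f"{e:.3f} kcal/mol (needs <= {selection.score_cutoff - margin:.3f})"
                )
        elif e < off_floor:
            raise RuntimeError(
                f"pocket certificate failed: non-planted site {i} refines to "
                f"{e:.3f} kcal/mol (needs >= {off_floor:.3f})"
            )


def make_trajectory(spec: FixtureSpec) -> List[np.ndarray]:
    """Water-oxygen frames: Gaussian clouds at known centres plus noise.

    Each frame holds one sample per centre (isotropic sigma =
    ``cloud_sigma``) and ``noise_per_frame`` points uniform in a cube of
    half-width ``box_half`` about the origin.
    """
    rng = np.random.default_rng(spec.seed)
    centres = np.asarray(list(spec.cloud_centres), dtype=float).reshape(-1, 3)
    frames: List[np.ndarray] = []
    for _ in range(spec.n_frames):
        pts = []
        for c in centres:
            pts.append(c + rng.normal(scale=spec.cloud_sigma, size=3))
        for _ in range(spec.noise_per_frame):
            pts.append(rng.uniform(-spec.box_half, spec.box_half, size=3))
        frames.append(np.array(pts, dtype=float).reshape(-1, 3))
    return frames
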