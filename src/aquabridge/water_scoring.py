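"""Empirical docking-style scoring of a water probe against the protein.

The scorer re-implements the published AutoDock Vina functional form with
its published weights, evaluated for a single united-atom water oxygen
typed as both hydrogen-bond donor and acceptor.  For a protein heavy atom
at centre distance ``r`` the surface distance is

    d = r - R_vdw(water O) - R_vdw(atom)

and the interaction terms are

    gauss1      exp(-(d / 0.5)^2)
    gauss2      exp(-((d - 3) / 2)^2)
    repulsion   d^2            (only where d < 0)
    hbond       piecewise linear in d: 1 below -0.7 A, 0 above 0 A,
                active only when the partner is a donor or acceptor
    hydrophobic identically 0 for a polar probe

The energy is the weight-dot-term sum over all heavy atoms within the
distance cutoff (8 A); with a rigid single-atom probe there is no torsion
penalty, so the sum is already in kcal/mol.

Each candidate site is refined by an exhaustive grid search over a tiny
cube (half-width 0.25 A, i.e. a 0.5 A box, step 0.05 A) centred on the
seed.  This replaces the stochastic optimiser of an external docking run
with a deterministic equivalent: the box is small enough that exhaustive
search is exact to the grid resolution.  An external-binary backend with
the same per-site contract is provided for users wanting bit-compatibility
with an AutoDock Vina workflow.
"""

from __future__ import annotations

import logging
import math
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from aquabridge.structure_io import (
    ACCEPTOR,
    DONOR,
    DONOR_ACCEPTOR,
    HYDROPHOBIC,
    OTHER,
    ProteinStructure,
)

logger = logging.getLogger(__name__)

#: published Vina 1.1.x conformation-dependent term weights (kcal/mol)
VINA_WEIGHTS = {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439,
}

#: X-score-style van der Waals radii (A) used for the surface distance
VDW_RADII: Dict[str, float] = {
    "C": 1.9, "N": 1.75, "O": 1.6, "S": 2.0, "P": 2.1,
    "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2,
    "SE": 2.0, "B": 1.8,
}
DEFAULT_RADIUS = 1.8
WATER_O_RADIUS = VDW_RADII["O"]


@dataclass(frozen=True)
class ScoringParams:
    """Weights and search-box geometry for the internal scorer."""

    weights: Dict[str, float] = field(default_factory=lambda: dict(VINA_WEIGHTS))
    cutoff: float = 8.0  # A, neighbour cutoff for term evaluation
    box_half_width: float = 0.25  # A, half of the 0.5 A local-search box
    grid_step: float = 0.05  # A, exhaustive-search step

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.box_half_width <= 0 or self.grid_step <= 0:
            raise ValueError("cutoff, box_half_width and grid_step must be positive")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("weights must be finite")


@dataclass
class SiteScore:
    """Refined position and energy of one candidate site."""

    best_coords: np.ndarray
    energy: float  # kcal/mol


# ---------------------------------------------------------------------------
# protein typing

# side-chain donor/acceptor atoms of the standard amino acids
_SIDECHAIN_TYPES = {
    ("SER", "OG"): DONOR_ACCEPTOR,
    ("THR", "OG1"): DONOR_ACCEPTOR,
    ("TYR", "OH"): DONOR_ACCEPTOR,
    ("ASN", "OD1"): ACCEPTOR, ("ASN", "ND2"): DONOR,
    ("GLN", "OE1"): ACCEPTOR, ("GLN", "NE2"): DONOR,
    ("ASP", "OD1"): ACCEPTOR, ("ASP", "OD2"): ACCEPTOR,
    ("GLU", "OE1"): ACCEPTOR, ("GLU", "OE2"): ACCEPTOR,
    ("LYS", "NZ"): DONOR,
    ("ARG", "NE"): DONOR, ("ARG", "NH1"): DONOR, ("ARG", "NH2"): DONOR,
    ("HIS", "ND1"): DONOR_ACCEPTOR, ("HIS", "NE2"): DONOR_ACCEPTOR,
    ("TRP", "NE1"): DONOR,
}


def _type_atom(residue_name: str, atom_name: str, element: str) -> str:
    el = element.upper()
    res = residue_name.strip().upper()
    nm = atom_name.strip().upper()
    key = (res, nm)
    if key in _SIDECHAIN_TYPES:
        return _SIDECHAIN_TYPES[key]
    if el == "N":
        return DONOR  # backbone amide N and generic N-H
    if el == "O":
        return ACCEPTOR  # backbone carbonyl O, OXT, generic O
    if el == "C":
        return HYDROPHOBIC
    if el == "H":
        return OTHER
    return OTHER  # S, P, metals, unknown


def assign_interaction_types(protein: ProteinStructure) -> ProteinStructure:
    """Fill per-atom interaction classes in place (and return the protein).

    Atoms with a declared type (synthetic pockets) pass through unchanged.
    Unknown elements are typed ``other`` with a warning.
    """
    known = set(VDW_RADII) | {"H"}
    for i in range(protein.n_atoms):
        if protein.interaction_types[i] is not None:
            continue
        el = protein.element[i].upper()
        if el not in known:
            logger.warning("unknown element %r at atom %d typed 'other'",
                           protein.element[i], i)
        protein.interaction_types[i] = _type_atom(
            protein.residue_name[i], protein.name[i], protein.element[i]
        )
    return protein


# ---------------------------------------------------------------------------
# internal scorer

def _scoring_arrays(protein: ProteinStructure):
    """Heavy-atom coordinates, vdW radii and H-bond-partner mask."""
    mask = protein.heavy_mask()
    coords = protein.coords[mask]
    radii = np.array(
        [VDW_RADII.get(e.upper(), DEFAULT_RADIUS)
         for e, m in zip(protein.element, mask) if m]
    )
    types = [t for t, m in zip(protein.interaction_types, mask) if m]
    if any(t is None for t in types):
        raise ValueError("protein atoms are untyped; run assign_interaction_types first")
    polar = np.array([t in (DONOR, ACCEPTOR, DONOR_ACCEPTOR) for t in types])
    return coords, radii, polar


def _hbond_factor(d: np.ndarray) -> np.ndarray:
    """Piecewise-linear H-bond term: 1 for d <= -0.7, 0 for d >= 0."""
    return np.clip(-d / 0.7, 0.0, 1.0)


def score_water_at(protein: ProteinStructure, pos, params: Optional[ScoringParams] = None,
                   _arrays=None) -> float:
    """Energy (kcal/mol) of the water probe at ``pos``.

    The probe is a single oxygen typed donor-and-acceptor, so the H-bond
    term is active against every protein donor/acceptor heavy atom and the
    hydrophobic term vanishes.  Atoms beyond the cutoff contribute nothing;
    an empty neighbourhood scores exactly 0.
    """
    params = params or ScoringParams()
    pos = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("probe position must be finite")
    coords, radii, polar = _arrays if _arrays is not None else _scoring_arrays(protein)
    if len(coords) == 0:
        return 0.0
    r = np.linalg.norm(coords - pos, axis=1)
    near = r < params.cutoff
    if not np.any(near):
        return 0.0
    d = r[near] - WATER_O_RADIUS - radii[near]
    w = params.weights
    e = (
        w["gauss1"] * np.exp(-((d / 0.5) ** 2))
        + w["gauss2"] * np.exp(-(((d - 3.0) / 2.0) ** 2))
        + w["repulsion"] * np.where(d < 0.0, d * d, 0.0)
    )
    e = e.sum() + w["hbond"] * (_hbond_factor(d) * polar[near]).sum()
    return float(e)


def local_refine(protein: ProteinStructure, seed,
                 params: Optional[ScoringParams] = None, _arrays=None) -> SiteScore:
    """Exhaustive grid search over the small box centred on ``seed``.

    Deterministic: ties are broken toward the seed (then by lexicographic
    grid order), so a uniform-field region returns the seed itself with
    energy 0.
    """
    params = params or ScoringParams()
    seed = np.asarray(seed, dtype=float)
    coords, radii, polar = _arrays if _arrays is not None else _scoring_arrays(protein)
    h, s = params.box_half_width, params.grid_step
    n = int(round(h / s))
    off = np.arange(-n, n + 1) * s
    dx, dy, dz = np.meshgrid(off, off, off, indexing="ij")
    deltas = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    pts = seed[None, :] + deltas

    # prune protein atoms that cannot reach any grid point
    if len(coords):
        reach = params.cutoff + h * math.sqrt(3.0)
        near = np.linalg.norm(coords - seed, axis=1) < reach
        coords, radii, polar = coords[near], radii[near], polar[near]
    if len(coords) == 0:
        return SiteScore(best_coords=seed, energy=0.0)

    r = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    d = r - WATER_O_RADIUS - radii[None, :]
    in_range = r < params.cutoff
    w = params.weights
    terms = (
        w["gauss1"] * np.exp(-((d / 0.5) ** 2))
        + w["gauss2"] * np.exp(-(((d - 3.0) / 2.0) ** 2))
        + w["repulsion"] * np.where(d < 0.0, d * d, 0.0)
        + w["hbond"] * _hbond_factor(d) * polar[None, :]
    )
    energies = np.where(in_range, terms, 0.0).sum(axis=1)

    # ties broken toward the seed, then lexicographically in grid order
    seed_dist = np.linalg.norm(deltas, axis=1)
    order = np.lexsort((np.arange(len(pts)), seed_dist, energies))
    best = order[0]
    return SiteScore(best_coords=pts[best], energy=float(energies[best]))


def score_sites(protein: ProteinStructure, sites,
                params: Optional[ScoringParams] = None) -> List[SiteScore]:
    """Refine and score a list of hydration sites with the internal backend."""
    params = params or ScoringParams()
    arrays = _scoring_arrays(protein)
    return [local_refine(protein, s.coords, params, _arrays=arrays) for s in sites]


# ---------------------------------------------------------------------------
# external backend (AutoDock Vina subprocess)

_VINA_RESULT_RE = re.compile(r"^\s*1\s+(-?\d+\.\d+)", re.MULTILINE)


def _write_pdbqt_receptor(protein: ProteinStructure, path: Path) -> None:
    ad_types = {"C": "C", "N": "N", "O": "OA", "S": "SA", "P": "P",
                "F": "F", "CL": "Cl", "BR": "Br", "I": "I"}
    lines = []
    for i in range(protein.n_atoms):
        el = protein.element[i].upper()
        if el == "H":
            continue
        t = ad_types.get(el, "C")
        x, y, z = protein.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  {protein.name[i][:3]:<3s} "
            f"{protein.residue_name[i][:3]:>3s} A{int(protein.residue_id[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    0.000 {t}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_pdbqt_water(pos: np.ndarray, path: Path) -> None:
    x, y, z = pos
    path.write_text(
        "ROOT\n"
        f"ATOM      1  O   HOH W   1    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        "    0.000 OA\n"
        "ENDROOT\nTORSDOF 0\n"
    )


def score_backend_external(protein: ProteinStructure, sites: Sequence,
                           vina_executable: str = "vina",
                           exhaustiveness: int = 5,
                           box_size: float = 0.5) -> List[SiteScore]:
    """Score sites through an external AutoDock Vina binary.

    Per site, a single-oxygen water probe is docked in a ``box_size`` cube
    centred on the seed with ``num_modes`` 1; the top-mode affinity is
    parsed from the output PDBQT.  Missing executable or unparseable output
    are fatal with a diagnostic naming the site index.
    """
    if not sites:
        return []
    exe = shutil.which(vina_executable)
    if exe is None:
        raise RuntimeError(
            f"external docking backend requested but executable "
            f"{vina_executable!r} was not found on PATH"
        )
    results: List[SiteScore] = []
    with tempfile.TemporaryDirectory(prefix="aquabridge_vina_") as tmp:
        tmpdir = Path(tmp)
        receptor = tmpdir / "receptor.pdbqt"
        _write_pdbqt_receptor(protein, receptor)
        for idx, site in enumerate(sites):
            seed = np.asarray(site.coords, dtype=float)
            probe = tmpdir / f"water_{idx}.pdbqt"
            out = tmpdir / f"out_{idx}.pdbqt"
            _write_pdbqt_water(seed, probe)
            cmd = [
                exe, "--receptor", str(receptor), "--ligand", str(probe),
                "--center_x", f"{seed[0]:.3f}", "--center_y", f"{seed[1]:.3f}",
                "--center_z", f"{seed[2]:.3f}",
                "--size_x", str(box_size), "--size_y", str(box_size),
                "--size_z", str(box_size),
                "--num_modes", "1", "--exhaustiveness", str(exhaustiveness),
                "--out", str(out),
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"external docking failed for site {idx}: {proc.stderr.strip()}"
                )
            energy, coords = _parse_vina_output(out, idx, seed)
            results.append(SiteScore(best_coords=coords, energy=energy))
    return results


def _parse_vina_output(out: Path, idx: int, seed: np.ndarray):
    if not out.exists():
        raise RuntimeError(f"external backend produced no output for site {idx}")
    text = out.read_text()
    m = re.search(r"REMARK VINA RESULT:\s+(-?\d+\.\d+)", text)
    if m is None:
        raise RuntimeError(f"could not parse docking result for site {idx}")
    energy = float(m.group(1))
    coords = seed
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            try:
                coords = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise RuntimeError(
                    f"malformed coordinates in docking output for site {idx}"
                ) from exc
            break
    return energy, coords
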