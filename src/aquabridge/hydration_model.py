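"""Semi-empirical hydration shells around ligand functional groups.

Candidate water-oxygen positions are placed on a 3.0 A sphere around each
shell-bearing polar atom (the experimental hydrogen-bond length), tiled so
that distinct sites sit at least 2.0 A apart.  The angular extent of the
tiling is motif-specific, expressed in the local frame of the polar atom
(theta measured from z, phi from x within the x-y plane, folded to
[0, 180] degrees):

===========  =====================  ====================
motif        theta range (deg)      phi range (deg)
===========  =====================  ====================
carbonyl     40 - 140               20 - 160
carboxyl     60 - 160               0 - 180
phosphoryl   60 - 160               0 - 180
nitro, sulfonyl, cyano, halogen: as carboxyl
ether        arc at theta = 90      0 - 180
imine        arc at theta = 90      0 - 180
amine        one site per N-H, on the N->H line at 3.0 A
hydroxyl     ether-style arc on O  +  amine-style site along O-H
===========  =====================  ====================

The tiling uses an angular step of ``2*arcsin(1.0/3.0)`` (about 38.94 deg,
the angle subtending a 2.0 A chord on a 3.0 A sphere) in both theta and
phi, anchored at the midpoint of each range.  Because phi arcs shorten by
sin(theta) away from the equator, the raw grid is pruned greedily (closest
to the range midpoint first, deterministic order) until every retained pair
of sites is >= 2.0 A apart.

Sites closer than 2.0 A to any ligand heavy atom cannot hold a water and
are discarded with a log entry before scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from aquabridge.functional_groups import Motif, MotifKind
from aquabridge.structure_io import Ligand

logger = logging.getLogger(__name__)

#: polar-atom -> water-oxygen distance, A (experimental H-bond length)
SHELL_RADIUS = 3.0
#: minimum distance between distinct modelled sites, A
SITE_SPACING = 2.0
#: angular step subtending a SITE_SPACING chord on the SHELL_RADIUS sphere
ANGULAR_STEP_DEG = math.degrees(2.0 * math.asin(SITE_SPACING / (2.0 * SHELL_RADIUS)))
#: minimum site -> ligand-heavy-atom distance, A (self-clash filter)
CLASH_DISTANCE = 2.0


@dataclass(frozen=True)
class AngularRange:
    """Box in (theta, phi), degrees, in the per-atom local frame."""

    theta_min: float
    theta_max: float
    phi_min: float
    phi_max: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_min <= self.theta_max <= 180.0):
            raise ValueError("theta range must satisfy 0 <= min <= max <= 180")
        if not (0.0 <= self.phi_min <= self.phi_max <= 180.0):
            raise ValueError("phi range must satisfy 0 <= min <= max <= 180")

    def contains(self, theta: float, phi: float, tol: float = 1e-9) -> bool:
        return (
            self.theta_min - tol <= theta <= self.theta_max + tol
            and self.phi_min - tol <= phi <= self.phi_max + tol
        )


#: per-kind angular ranges; amine has no range (site per N-H), hydroxyl is a
#: composite of the ether arc and an amine-style site.
CARBOXYL_LIKE = AngularRange(60.0, 160.0, 0.0, 180.0)
ARC_90 = AngularRange(90.0, 90.0, 0.0, 180.0)
ANGULAR_RANGES: Dict[MotifKind, AngularRange] = {
    MotifKind.CARBONYL: AngularRange(40.0, 140.0, 20.0, 160.0),
    MotifKind.CARBOXYL: CARBOXYL_LIKE,
    MotifKind.PHOSPHORYL: CARBOXYL_LIKE,
    MotifKind.NITRO: CARBOXYL_LIKE,
    MotifKind.SULFONYL: CARBOXYL_LIKE,
    MotifKind.CYANO: CARBOXYL_LIKE,
    MotifKind.HALOGEN: CARBOXYL_LIKE,
    MotifKind.ETHER: ARC_90,
    MotifKind.IMINE: ARC_90,
}


@dataclass
class HydrationSite:
    """One candidate water-oxygen position attached to its parent motif."""

    coords: np.ndarray
    motif_id: int
    polar_atom: int
    score: Optional[float] = None
    generation_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


def _grid_values(lo: float, hi: float, step: float) -> List[float]:
    """Symmetric grid anchored at the midpoint of [lo, hi], inclusive."""
    mid = 0.5 * (lo + hi)
    ks = [0]
    k = 1
    while mid - k * step >= lo - 1e-9 or mid + k * step <= hi + 1e-9:
        ks.extend([k, -k])
        k += 1
        if k > 1000:  # pragma: no cover - defensive
            break
    vals = [mid + k * step for k in ks if lo - 1e-9 <= mid + k * step <= hi + 1e-9]
    return vals


def _tile_range(rng: AngularRange, step: float = ANGULAR_STEP_DEG) -> List[tuple]:
    """(theta, phi) grid over the range, ordered outward from the midpoint.

    Order is deterministic: by theta offset index (0, +1, -1, ...), then phi
    offset index, exactly the order :func:`_grid_values` produces.
    """
    thetas = [rng.theta_min] if rng.theta_min == rng.theta_max else _grid_values(
        rng.theta_min, rng.theta_max, step
    )
    phis = [rng.phi_min] if rng.phi_min == rng.phi_max else _grid_values(
        rng.phi_min, rng.phi_max, step
    )
    return [(t, p) for t in thetas for p in phis]


def _sphere_point(origin: np.ndarray, frame: np.ndarray, theta_deg: float,
                  phi_deg: float, radius: float = SHELL_RADIUS) -> np.ndarray:
    x, y, z = frame
    t = math.radians(theta_deg)
    p = math.radians(phi_deg)
    direction = math.sin(t) * (math.cos(p) * x + math.sin(p) * y) + math.cos(t) * z
    return origin + radius * direction


def _greedy_min_dist(points: List[np.ndarray], min_dist: float = SITE_SPACING) -> List[int]:
    """Indices of points kept so that all pairwise distances >= min_dist.

    Greedy in input order (input is midpoint-outward), so the midpoint
    anchor always survives.
    """
    kept: List[int] = []
    for i, pt in enumerate(points):
        if all(np.linalg.norm(pt - points[j]) >= min_dist - 1e-9 for j in kept):
            kept.append(i)
    return kept


def _shell_for_polar_atom(ligand: Ligand, motif: Motif, motif_id: int,
                          polar_atom: int, rng: AngularRange,
                          radius: float, spacing: float) -> List[np.ndarray]:
    frame = motif.frames[polar_atom]
    origin = ligand.coords[polar_atom]
    step = math.degrees(2.0 * math.asin(min(1.0, spacing / (2.0 * radius))))
    angles = _tile_range(rng, step)
    pts = [_sphere_point(origin, frame, t, p, radius) for t, p in angles]
    kept = _greedy_min_dist(pts, spacing)
    return [pts[i] for i in kept]


def _amine_sites(ligand: Ligand, polar_atom: int, radius: float) -> List[np.ndarray]:
    """One site per N-H (or O-H), on the extension of the X->H unit vector."""
    sites = []
    n = ligand.coords[polar_atom]
    for h in ligand.hydrogen_neighbors(polar_atom):
        v = ligand.coords[h] - n
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            continue
        sites.append(n + radius * v / nv)
    return sites


def build_shell(ligand: Ligand, motif: Motif, motif_id: int = 0,
                radius: float = SHELL_RADIUS, spacing: float = SITE_SPACING,
                ranges: Optional[Dict[MotifKind, AngularRange]] = None,
                clash_distance: float = CLASH_DISTANCE) -> List[HydrationSite]:
    """Generate the candidate hydration sites of one motif.

    Sites are exactly ``radius`` from their polar atom and pairwise at least
    ``spacing`` apart within each polar atom's set.  Sites clashing with any
    ligand heavy atom (< ``clash_distance``) are discarded with a log entry.
    """
    ranges = ranges or ANGULAR_RANGES
    heavy = ligand.heavy_coords()
    sites: List[HydrationSite] = []
    gen_idx = 0
    for polar_atom in motif.polar_atoms:
        if motif.kind is MotifKind.AMINE:
            pts = _amine_sites(ligand, polar_atom, radius)
        elif motif.kind is MotifKind.HYDROXYL:
            # O-H-directed site first so the min-distance pruning keeps it
            pts = _amine_sites(ligand, polar_atom, radius)
            pts.extend(
                _shell_for_polar_atom(
                    ligand, motif, motif_id, polar_atom, ranges[MotifKind.ETHER],
                    radius, spacing,
                )
            )
            keep = _greedy_min_dist(pts, spacing)
            pts = [pts[i] for i in keep]
        else:
            pts = _shell_for_polar_atom(
                ligand, motif, motif_id, polar_atom, ranges[motif.kind],
                radius, spacing,
            )
        for pt in pts:
            d = np.linalg.norm(heavy - pt, axis=1)
            if np.any(d < clash_distance):
                logger.debug(
                    "discarding shell site of atom %d: %.2f A from a ligand heavy atom",
                    polar_atom, float(d.min()),
                )
                continue
            sites.append(
                HydrationSite(coords=pt, motif_id=motif_id, polar_atom=polar_atom,
                              generation_index=gen_idx)
            )
            gen_idx += 1
    return sites


def build_all_shells(ligand: Ligand, motifs: List[Motif],
                     radius: float = SHELL_RADIUS, spacing: float = SITE_SPACING,
                     ranges: Optional[Dict[MotifKind, AngularRange]] = None,
                     clash_distance: float = CLASH_DISTANCE) -> List[HydrationSite]:
    """Concatenate per-motif shells (no cross-motif deduplication here;
    overlapping sites are merged by clustering after scoring)."""
    sites: List[HydrationSite] = []
    for mid, motif in enumerate(motifs):
        shell = build_shell(ligand, motif, motif_id=mid, radius=radius,
                            spacing=spacing, ranges=ranges,
                            clash_distance=clash_distance)
        for s in shell:
            s.generation_index = len(sites)
            sites.append(s)
    return sites
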