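"""Occupancy-grid accumulation and quality-threshold discretisation.

This module reproduces the machinery used to derive functional-group
hydration geometry from simulation: water-oxygen positions from a set of
frames (the ligand held fixed) are histogrammed on a regular 3-D grid
(0.25 A spacing, extending 4 A beyond the ligand heavy atoms), and the
grid is discretised into hydration sites by a greedy quality-threshold
rule: repeatedly take the highest-count unclaimed voxel as a site centre
and claim everything within the minimum separation (2 A), stopping when
the next centre's own count falls below an occupancy floor (a fraction of
the frame count; default 5%).  Site occupancy integrates the counts within
half the minimum separation of the centre so that it is comparable across
grid spacings.

Discretised sites are assigned to the motif with the nearest polar atom
(within 4 A) and can be expressed as (theta, phi) angles in that atom's
local frame, the same convention the shell generator uses - so shells
analysed here land inside their defining angular ranges by construction.

Frames arrive as plain multi-frame XYZ text (one block per frame, ``O``
records) or as in-memory coordinate arrays; running the simulation itself
is out of scope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from aquabridge.functional_groups import Motif
from aquabridge.structure_io import Ligand

logger = logging.getLogger(__name__)

GRID_SPACING = 0.25  # A
GRID_EXTENT = 4.0  # A beyond the ligand heavy-atom bounding box
MIN_SITE_SEPARATION = 2.0  # A
OCCUPANCY_FLOOR = 0.05  # fraction of frames
ASSIGN_RADIUS = 4.0  # A, site -> polar atom assignment cutoff


@dataclass
class OccupancyGrid:
    """3-D histogram of water-oxygen residency."""

    origin: np.ndarray
    spacing: float
    dims: Tuple[int, int, int]
    counts: np.ndarray
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self.counts = np.asarray(self.counts)

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


@dataclass
class DiscreteSite:
    """A discretised hydration site with its integrated occupancy."""

    coords: np.ndarray
    occupancy: int
    assigned_motif: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


def build_grid(ligand_heavy_coords, water_O_frames: Sequence,
               spacing: float = GRID_SPACING, extent: float = GRID_EXTENT
               ) -> OccupancyGrid:
    """Accumulate water-oxygen residency over frames.

    The grid covers the ligand heavy-atom bounding box padded by
    ``extent``; each water oxygen inside the box increments its containing
    voxel once per frame, waters outside are ignored.
    """
    frames = list(water_O_frames)
    if not frames:
        raise ValueError("no frames supplied")
    heavy = np.asarray(ligand_heavy_coords, dtype=float).reshape(-1, 3)
    lo = heavy.min(axis=0) - extent
    hi = heavy.max(axis=0) + extent
    dims = tuple(int(math.ceil((hi[k] - lo[k]) / spacing)) for k in range(3))
    counts = np.zeros(dims, dtype=np.int64)
    for frame in frames:
        pts = np.asarray(frame, dtype=float).reshape(-1, 3)
        if len(pts) == 0:
            continue
        idx = np.floor((pts - lo) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(dims)), axis=1)
        for i, j, k in idx[inside]:
            counts[i, j, k] += 1
    return OccupancyGrid(origin=lo, spacing=spacing, dims=dims, counts=counts,
                         n_frames=len(frames))


def qt_discretise(grid: OccupancyGrid, min_sep: float = MIN_SITE_SEPARATION,
                  occupancy_floor: float = OCCUPANCY_FLOOR) -> List[DiscreteSite]:
    """Greedy quality-threshold discretisation of the occupancy grid.

    Iteratively promotes the highest-count unclaimed voxel to a site centre
    (count ties broken by lexicographic voxel index), claims all voxels
    within ``min_sep`` of it, and stops when the next candidate's own count
    drops below ``occupancy_floor * n_frames``.  Site occupancy sums the
    counts within ``min_sep / 2`` of the centre.
    """
    nz = np.argwhere(grid.counts > 0)
    if len(nz) == 0:
        return []
    counts = grid.counts[tuple(nz.T)]
    centers = grid.origin + (nz + 0.5) * grid.spacing
    # sort by descending count, then lexicographic voxel index
    order = np.lexsort((nz[:, 2], nz[:, 1], nz[:, 0], -counts))
    nz, counts, centers = nz[order], counts[order], centers[order]
    tree = cKDTree(centers)
    floor = occupancy_floor * max(grid.n_frames, 1)
    claimed = np.zeros(len(nz), dtype=bool)
    sites: List[DiscreteSite] = []
    for i in range(len(nz)):
        if claimed[i]:
            continue
        if counts[i] < floor:
            break  # every later voxel has an equal or lower count
        center = centers[i]
        within_half = tree.query_ball_point(center, min_sep / 2.0)
        occupancy = int(counts[within_half].sum())
        claimed[tree.query_ball_point(center, min_sep)] = True
        sites.append(DiscreteSite(coords=center, occupancy=occupancy))
    return sites


def assign_to_motifs(sites: Sequence[DiscreteSite], ligand: Ligand,
                     motifs: Sequence[Motif], radius: float = ASSIGN_RADIUS
                     ) -> List[DiscreteSite]:
    """Assign each site to the motif owning the nearest polar atom.

    Sites farther than ``radius`` from every polar atom stay unassigned
    (logged).  Exact distance ties resolve to the lower motif index.
    """
    polar: List[Tuple[int, np.ndarray]] = []
    for mid, motif in enumerate(motifs):
        for a in motif.polar_atoms:
            polar.append((mid, ligand.coords[a]))
    for site in sites:
        best: Optional[Tuple[float, int]] = None
        for mid, pos in polar:
            d = float(np.linalg.norm(site.coords - pos))
            if d <= radius and (best is None or (d, mid) < best):
                best = (d, mid)
        if best is None:
            site.assigned_motif = None
            logger.info("site at %s unassigned (> %.1f A from every polar atom)",
                        np.round(site.coords, 2), radius)
        else:
            site.assigned_motif = best[1]
    return list(sites)


def angular_distribution(sites: Sequence, ligand: Ligand, motif: Motif,
                         polar_atom: Optional[int] = None
                         ) -> List[Tuple[float, float, bool]]:
    """(theta, phi) of each site in the polar atom's local frame, degrees.

    theta is the angle from z; phi is the angle of the x-y-plane projection
    from x, folded to [0, 180].  For a site along z the projection vanishes
    and phi is reported as 0 with the degenerate flag set (third element).
    """
    atom = polar_atom if polar_atom is not None else motif.polar_atoms[0]
    frame = motif.frames[atom]
    origin = ligand.coords[atom]
    x, y, z = frame
    out = []
    for site in sites:
        coords = site.coords if hasattr(site, "coords") else np.asarray(site, float)
        v = coords - origin
        nv = np.linalg.norm(v)
        if nv < 1e-9:
            raise ValueError("site coincides with the polar atom")
        u = v / nv
        theta = math.degrees(math.acos(np.clip(np.dot(u, z), -1.0, 1.0)))
        proj = v - np.dot(v, z) * z
        if np.linalg.norm(proj) < 1e-9:
            out.append((theta, 0.0, True))
            continue
        pu = proj / np.linalg.norm(proj)
        phi = math.degrees(math.atan2(np.dot(pu, y), np.dot(pu, x)))
        phi = abs(phi)  # fold to [0, 180]
        out.append((theta, phi, False))
    return out


# ---------------------------------------------------------------------------
# plain-text frame I/O

def read_xyz_frames(path) -> List[np.ndarray]:
    """Read multi-frame XYZ (atom count / comment / element x y z blocks).

    Only ``O`` records are kept; per-frame atom counts may vary.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: List[np.ndarray] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"bad XYZ frame header at line {i + 1}") from exc
        block = lines[i + 2:i + 2 + n]
        pts = []
        for ln in block:
            parts = ln.split()
            if len(parts) >= 4 and parts[0].upper().startswith("O"):
                pts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(np.array(pts, dtype=float).reshape(-1, 3))
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames parsed from {path}")
    return frames


def write_xyz_frames(frames: Sequence[np.ndarray], path) -> Path:
    """Write water-oxygen frames as multi-frame XYZ."""
    path = Path(path)
    chunks = []
    for t, frame in enumerate(frames):
        pts = np.asarray(frame, dtype=float).reshape(-1, 3)
        chunks.append(f"{len(pts)}\nframe {t}")
        for xx, yy, zz in pts:
            chunks.append(f"O {xx:.4f} {yy:.4f} {zz:.4f}")
    path.write_text("\n".join(chunks) + "\n")
    return path


def sites_table(sites: Sequence[DiscreteSite], ligand: Ligand,
                motifs: Sequence[Motif]):
    """TSV-ready rows (x, y, z, occupancy, motif, theta, phi) per site."""
    import pandas as pd

    rows = []
    for site in sites:
        theta = phi = float("nan")
        motif_kind = ""
        if site.assigned_motif is not None:
            motif = motifs[site.assigned_motif]
            motif_kind = motif.kind.value
            theta, phi, _ = angular_distribution([site], ligand, motif)[0]
        x, y, z = site.coords
        rows.append({"x": x, "y": y, "z": z, "occupancy": site.occupancy,
                     "motif": motif_kind, "theta": theta, "phi": phi})
    return pd.DataFrame(rows)
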