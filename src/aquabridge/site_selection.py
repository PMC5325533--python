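"""Turning scored candidate sites into final predicted bridging waters.

Three stages run in a fixed order after scoring:

1. **energetic cutoff** — sites scoring more positive than the trained
   cutoff (-0.55 kcal/mol by default) are discarded; the boundary value is
   retained.
2. **hydrogen-bond saturation** — per shell-bearing polar atom at most
   ``hbond_limit`` sites survive, keeping the most negative energies (ties
   broken by site generation order).
3. **clustering** — single-linkage connected components at 1.8 A merge
   sites subtended by multiple functional groups; each component yields one
   water at its best-scoring member's position, carrying that score.

Swapping stages 2 and 3 changes results; the order above (saturation before
clustering) is part of the method definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from aquabridge.functional_groups import Motif, detect_motifs
from aquabridge.hydration_model import HydrationSite, build_all_shells
from aquabridge.structure_io import Ligand, ProteinStructure, WaterRecord
from aquabridge.water_scoring import (
    ScoringParams,
    assign_interaction_types,
    score_backend_external,
    score_sites,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Cutoff and clustering constants of the selection stages."""

    score_cutoff: float = -0.55  # kcal/mol
    cluster_distance: float = 1.8  # A
    cluster_representative: str = "best"  # "best" | "centroid"

    def __post_init__(self) -> None:
        if self.cluster_distance <= 0:
            raise ValueError("cluster_distance must be positive")
        if self.cluster_representative not in ("best", "centroid"):
            raise ValueError("cluster_representative must be 'best' or 'centroid'")


def filter_by_score(sites: Sequence[HydrationSite], cutoff: float = -0.55
                    ) -> List[HydrationSite]:
    """Retain sites with energy <= cutoff (boundary value retained)."""
    for s in sites:
        if s.score is None:
            raise ValueError("unscored site passed to filter_by_score")
    return [s for s in sites if s.score <= cutoff]


def enforce_saturation(sites: Sequence[HydrationSite], motifs: Sequence[Motif]
                       ) -> List[HydrationSite]:
    """Keep at most ``hbond_limit`` sites per shell-bearing polar atom.

    The most negative energies win; ties fall back to generation order, so
    the outcome is deterministic and independent of input ordering.
    """
    by_atom: dict = {}
    for s in sites:
        if s.score is None:
            raise ValueError("unscored site passed to enforce_saturation")
        by_atom.setdefault((s.motif_id, s.polar_atom), []).append(s)
    kept: List[HydrationSite] = []
    for (motif_id, _atom), group in sorted(by_atom.items()):
        limit = motifs[motif_id].hbond_limit
        group.sort(key=lambda s: (s.score, s.generation_index))
        kept.extend(group[:limit])
    kept.sort(key=lambda s: s.generation_index)
    return kept


def cluster_sites(sites: Sequence[HydrationSite], cluster_distance: float = 1.8,
                  representative: str = "best") -> List[WaterRecord]:
    """Merge sites within ``cluster_distance`` (single linkage, transitive).

    Each connected component contributes one water: the best-scoring
    member's position and score (default), or the component centroid
    carrying the best member's score.
    """
    sites = list(sites)
    if not sites:
        return []
    coords = np.array([s.coords for s in sites])
    if len(sites) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(coords), method="single")
        labels = fcluster(z, t=cluster_distance, criterion="distance")
    waters: List[WaterRecord] = []
    for lab in sorted(set(labels)):
        members = [s for s, l in zip(sites, labels) if l == lab]
        best = min(members, key=lambda s: (s.score, s.generation_index))
        if representative == "centroid":
            pos = np.mean([m.coords for m in members], axis=0)
        else:
            pos = best.coords
        waters.append(WaterRecord(coords=pos, source="predicted", score=best.score))
    return waters


def predict(protein: ProteinStructure, ligand: Ligand,
            params: Optional[SelectionParams] = None,
            scoring: Optional[ScoringParams] = None,
            backend: str = "internal",
            vina_executable: str = "vina",
            return_report: bool = False):
    """Full pipeline: motifs -> shells -> score -> cutoff -> saturation -> cluster.

    Returns the predicted :class:`WaterRecord` list, or ``(waters, report)``
    with per-stage counts when ``return_report`` is set.
    """
    params = params or SelectionParams()
    scoring = scoring or ScoringParams()

    motifs = detect_motifs(ligand)
    sites = build_all_shells(ligand, motifs)
    logger.info("detected %d motifs, generated %d candidate sites",
                len(motifs), len(sites))

    assign_interaction_types(protein)
    if backend == "external":
        scored = score_backend_external(protein, sites, vina_executable,
                                        box_size=2 * scoring.box_half_width)
    elif backend == "internal":
        scored = score_sites(protein, sites, scoring)
    else:
        raise ValueError(f"unknown scoring backend {backend!r}")
    for site, result in zip(sites, scored):
        site.score = result.energy
        site.coords = np.asarray(result.best_coords, dtype=float)

    favourable = filter_by_score(sites, params.score_cutoff)
    saturated = enforce_saturation(favourable, motifs)
    waters = cluster_sites(saturated, params.cluster_distance,
                           params.cluster_representative)
    logger.info("pipeline counts: %d scored -> %d favourable -> %d saturated -> %d waters",
                len(sites), len(favourable), len(saturated), len(waters))
    if return_report:
        report = {
            "n_motifs": len(motifs),
            "n_candidate_sites": len(sites),
            "n_after_cutoff": len(favourable),
            "n_after_saturation": len(saturated),
            "n_predicted_waters": len(waters),
            "score_cutoff": params.score_cutoff,
            "cluster_distance": params.cluster_distance,
            "backend": backend,
            "scorer_weights": dict(scoring.weights),
        }
        return waters, report
    return waters
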