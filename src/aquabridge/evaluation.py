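"""Training and validation statistics for bridging-water prediction.

* consensus-water extraction from superposed holo structures (a water
  within 3.2 A of both ligand and protein, seen in more than one
  structure);
* greedy one-to-one matching of predictions to consensus waters at a 2.0 A
  (or 1.4 A) radius, yielding true/false-positive counts and the mean
  error over true positives;
* the decision-stump training rule: the score threshold minimising the
  weighted Gini impurity of the conserved/displaced split;
* Kendall rank correlation (tau-b) between score and distance;
* Boschloo's unconditional exact test for comparing two methods' hit rates
  at fixed prediction totals.

The Boschloo test is implemented directly: the test statistic is the
one-sided Fisher exact (hypergeometric) p-value of the observed table, and
the reported p-value is the supremum over the nuisance success probability
of the binomial-product probability of all tables at least as extreme.
The supremum is taken on a dense grid (1001 points) followed by bounded
local refinement, giving p to ~1e-4.  This test is uniformly at least as
powerful as Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from scipy.stats import binom, hypergeom, kendalltau

from aquabridge.structure_io import ProteinStructure, WaterRecord

logger = logging.getLogger(__name__)

CONSENSUS_RADIUS = 3.2  # A, water -> ligand and water -> protein
CONSENSUS_MERGE_RADIUS = 2.0  # A, cross-structure merging of candidates
MATCH_RADIUS = 2.0  # A, default prediction -> consensus match radius


@dataclass
class ConsensusWater:
    """A crystallographic water supported by at least two structures."""

    coords: np.ndarray
    supporting_structures: frozenset

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.supporting_structures) < 2:
            raise ValueError("consensus requires support from >= 2 structures")


@dataclass
class MatchReport:
    """TP/FP bookkeeping of one prediction-vs-consensus comparison."""

    n_consensus: int
    n_predicted: int
    n_true_positive: int
    n_false_positive: int
    match_radius: float
    nearest_consensus_distance: List[float] = field(default_factory=list)
    mean_error: float = float("nan")  # mean matched distance over TPs

    def __post_init__(self) -> None:
        assert self.n_true_positive + self.n_false_positive == self.n_predicted
        assert self.n_true_positive <= self.n_consensus


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = methods, columns = (outcome, total - outcome)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("row sums must be positive")


# ---------------------------------------------------------------------------
# consensus waters and matching

def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of paired coordinates (helper plumbing).

    Returns (rotation matrix, translation, rmsd) such that
    ``mobile @ R.T + t`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    rmsd = rssd / np.sqrt(len(mobile))
    r = rot.as_matrix()
    t = rc - mc @ r.T
    return r, t, float(rmsd)


def consensus_waters(structures: Sequence[Tuple], radius: float = CONSENSUS_RADIUS,
                     merge_radius: float = CONSENSUS_MERGE_RADIUS
                     ) -> List[ConsensusWater]:
    """Consensus waters from >= 2 superposed structures.

    ``structures`` is a sequence of ``(protein, ligand_coords, waters)``
    per structure, already in a common frame.  A candidate is any
    crystallographic water within ``radius`` of both its own structure's
    ligand and protein; candidates are merged across structures by
    single-linkage at ``merge_radius`` (centroid representative) and groups
    supported by more than one structure become consensus waters.
    """
    if len(structures) < 2:
        raise ValueError("consensus extraction needs at least 2 structures")
    cand_coords: List[np.ndarray] = []
    cand_tags: List[str] = []
    for k, (protein, ligand_coords, waters) in enumerate(structures):
        pcoords = protein.coords if isinstance(protein, ProteinStructure) \
            else np.asarray(protein, float).reshape(-1, 3)
        lcoords = np.asarray(ligand_coords, float).reshape(-1, 3)
        for w in waters:
            wc = w.coords if isinstance(w, WaterRecord) else np.asarray(w, float)
            tag = (w.structure_tag if isinstance(w, WaterRecord) and w.structure_tag
                   else f"structure_{k}")
            d_lig = np.linalg.norm(lcoords - wc, axis=1).min()
            d_prot = np.linalg.norm(pcoords - wc, axis=1).min() if len(pcoords) else np.inf
            if d_lig <= radius and d_prot <= radius:
                cand_coords.append(np.asarray(wc, float))
                cand_tags.append(tag)
    if not cand_coords:
        return []
    coords = np.array(cand_coords)
    if len(coords) == 1:
        labels = np.array([1])
    else:
        labels = fcluster(linkage(pdist(coords), method="single"),
                          t=merge_radius, criterion="distance")
    out: List[ConsensusWater] = []
    for lab in sorted(set(labels)):
        idx = np.where(labels == lab)[0]
        tags = frozenset(cand_tags[i] for i in idx)
        if len(tags) >= 2:
            out.append(ConsensusWater(coords=coords[idx].mean(axis=0),
                                      supporting_structures=tags))
    return out


def match_predictions(predicted: Sequence, consensus: Sequence,
                      radius: float = MATCH_RADIUS) -> MatchReport:
    """Greedy nearest-first one-to-one matching of predictions to consensus.

    Each consensus water absorbs at most one prediction; predictions left
    unmatched within ``radius`` are false positives.  This encodes the
    "chaining" convention: two predictions flanking one crystallographic
    water count as one true positive plus one false positive.
    """
    pred = [p.coords if hasattr(p, "coords") else np.asarray(p, float)
            for p in predicted]
    cons = [c.coords if hasattr(c, "coords") else np.asarray(c, float)
            for c in consensus]
    pairs = []
    for i, p in enumerate(pred):
        for j, c in enumerate(cons):
            d = float(np.linalg.norm(p - c))
            if d <= radius:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set = set()
    used_c: set = set()
    matched_d: List[float] = []
    for d, i, j in pairs:
        if i in used_p or j in used_c:
            continue
        used_p.add(i)
        used_c.add(j)
        matched_d.append(d)
    nearest = [
        min((float(np.linalg.norm(p - c)) for c in cons), default=float("inf"))
        for p in pred
    ]
    tp = len(used_p)
    return MatchReport(
        n_consensus=len(cons),
        n_predicted=len(pred),
        n_true_positive=tp,
        n_false_positive=len(pred) - tp,
        match_radius=radius,
        nearest_consensus_distance=nearest,
        mean_error=float(np.mean(matched_d)) if matched_d else float("nan"),
    )


# ---------------------------------------------------------------------------
# cutoff training and correlation

def gini_split_cutoff(scores: Sequence[float], conserved: Sequence[bool]) -> float:
    """Decision-stump threshold minimising weighted Gini impurity.

    Evaluates every midpoint between adjacent sorted unique scores; sites
    with score <= threshold form the "retained" leaf.  Ties resolve to the
    most negative threshold.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    conserved = np.asarray(conserved, dtype=bool)
    if len(scores) != len(conserved):
        raise ValueError("scores and labels differ in length")
    if conserved.all() or (~conserved).all():
        raise ValueError("both classes must be present to train a cutoff")
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct scores")
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(scores)

    def gini(labels: np.ndarray) -> float:
        if len(labels) == 0:
            return 0.0
        p = labels.mean()
        return 2.0 * p * (1.0 - p)

    best_t, best_imp = None, np.inf
    for t in thresholds:  # ascending, so strict '<' keeps the most negative tie
        left = conserved[scores <= t]
        right = conserved[scores > t]
        imp = (len(left) * gini(left) + len(right) * gini(right)) / n
        if imp < best_imp - 1e-15:
            best_imp, best_t = imp, t
    return float(best_t)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Kendall tau-b with its p-value.

    Exact p by enumeration for n <= 8 without ties; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 8 and not has_ties) else "asymptotic"
    res = kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Boschloo's unconditional exact test

def _fisher_p_matrix(n1: int, n2: int, alternative: str) -> np.ndarray:
    """One-sided Fisher p for every table (x1 of n1, x2 of n2).

    Conditional on the column total m = x1 + x2, X1 is hypergeometric.
    ``alternative='less'`` tests p1 < p2 (small x1 extreme), ``'greater'``
    the reverse.
    """
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    m = x1 + x2
    if alternative == "less":
        return hypergeom.cdf(x1, n1 + n2, m, n1)
    if alternative == "greater":
        return hypergeom.sf(x1 - 1, n1 + n2, m, n1)
    raise ValueError("alternative must be 'less' or 'greater'")


def boschloo_test(table: ContingencyTable2x2, alternative: str = "less",
                  grid_points: int = 1001) -> float:
    """Boschloo's unconditional exact test for a 2x2 table.

    Rows are the two methods, columns (outcome, non-outcome); row totals
    are fixed.  ``alternative='less'`` tests that row 1's outcome rate is
    below row 2's.  Statistic: the one-sided Fisher p of the observed
    table.  The p-value is the supremum over the nuisance probability of
    the total binomial-product mass of tables with Fisher p at most the
    observed one (dense grid plus bounded refinement; accurate to ~1e-4).
    """
    n1 = table.a + table.b
    n2 = table.c + table.d
    fisher = _fisher_p_matrix(n1, n2, alternative)
    observed = fisher[table.a, table.c]
    extreme = fisher <= observed * (1.0 + 1e-12)
    i1 = np.arange(n1 + 1)
    i2 = np.arange(n2 + 1)

    def mass(pi: float) -> float:
        p = np.outer(binom.pmf(i1, n1, pi), binom.pmf(i2, n2, pi))
        return float(p[extreme].sum())

    grid = np.linspace(1e-8, 1.0 - 1e-8, grid_points)
    values = np.array([mass(pi) for pi in grid])
    k = int(values.argmax())
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid_points - 1)]
    refined = minimize_scalar(lambda pi: -mass(pi), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-8})
    p = max(float(values[k]), float(-refined.fun))
    return min(p, 1.0)
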