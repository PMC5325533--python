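# Methods

This note documents the model implemented by `aquabridge`, the defaults and
why they hold, the numerical conventions, and what the synthetic fixtures
do and do not establish about real data.

## Model overview

A bridging water is predicted where (i) the ligand's local hydration
structure says a water prefers to sit, and (ii) an empirical protein–water
interaction score says the protein rewards that position. The pipeline is
strictly feed-forward:

```
detect motifs → build hydration shells → score each site (boxed refinement)
→ energetic cutoff → H-bond saturation per polar atom → 1.8 Å clustering
```

Stage order matters: saturation runs **before** clustering, so a cluster
can still merge the survivors of two different functional groups into one
water. Swapping the two stages changes results.

## Functional-group motifs

Motifs are detected with SMARTS patterns on the RDKit molecule, in a fixed
precedence that guarantees each N/O/halogen atom belongs to at most one
motif: carboxyl > nitro > sulfonyl/phosphoryl > carbonyl > hydroxyl/ether >
amine/imine/cyano > halogen. Precedence resolves genuine chemical overlap
(a carboxyl oxygen also matches the carbonyl pattern). Decisions worth
spelling out:

* **Amides** decompose per atom: the carbonyl O is a carbonyl motif, the
  N–H an amine motif. There is no separate amide entry.
* **Esters**: alkoxy O is an ether; the carbonyl O a carbonyl.
* **Carboxylates** (deprotonated) behave exactly like carboxylic acids.
* **Aromatic N**: pyridine-like (no H) → imine (limit 1); pyrrole-like
  (N–H) → amine.
* **Halogens** carry a shell with limit 1. Heavier halogens (Cl/Br/I) are
  rarely hydrated in solution simulations; `detect_motifs`
  (`exclude_heavy_halogens=True`) can drop them while always keeping F.
* The saturation limit of per-oxygen motifs (carboxyl, nitro, sulfonyl,
  phosphoryl) applies **per oxygen**, not per group — consistent with the
  VSEPR lone-pair rationale behind the limits.

Each polar atom gets a right-handed orthonormal frame: ẑ from the anchoring
heavy neighbour to the polar atom; x̂ in the plane spanned with the
neighbour's other heavy substituent, preferring a sibling polar atom of the
same motif (this pins carboxyl frames to the O–C–O plane exactly); for
linear groups (cyano) x̂ falls back deterministically to the smallest-index
Cartesian axis not parallel to ẑ. ŷ = ẑ × x̂.

## Hydration shells

Sites sit on a sphere of radius **3.0 Å** (experimental H-bond length)
about each polar atom and are spaced **≥ 2.0 Å** apart. Angular extents per
motif (θ from ẑ, φ from x̂, folded to [0°, 180°]):

| motif | θ | φ |
|---|---|---|
| carbonyl | 40–140° | 20–160° |
| carboxyl, phosphoryl, nitro, sulfonyl, cyano, halogen | 60–160° | 0–180° |
| ether, imine | arc at θ = 90° | 0–180° |
| amine | one site per N–H along the N→H direction | — |
| hydroxyl | ether arc on O ∪ one site along O–H | — |

The continuous ranges are discretised with an angular step of
2·arcsin(1/3) ≈ 38.94° — the angle subtending a 2.0 Å chord on a 3.0 Å
sphere — in both θ and φ, anchored at each range midpoint. Because φ arcs
shorten by sin θ away from the equator, the raw grid can violate the 2.0 Å
spacing off the θ = 90° ring; the grid is therefore pruned greedily,
midpoint-outward in deterministic order, until all retained pairs are
≥ 2.0 Å apart. This concretisation is canonical for this package: it
reproduces the "2.0 Å apart" packing exactly, is rotation-equivariant, and
involves no randomness.

Sites closer than 2.0 Å to any ligand heavy atom cannot physically hold a
water (the shell of a buried group folds back onto the ligand) and are
discarded before scoring, with a log entry.

## Scoring

The internal scorer evaluates the published AutoDock Vina functional form
with its published 1.1.x weights

| term | weight (kcal/mol) |
|---|---|
| gauss1 `exp(−(d/0.5)²)` | −0.035579 |
| gauss2 `exp(−((d−3)/2)²)` | −0.005156 |
| repulsion `d²·1[d<0]` | 0.840245 |
| hydrophobic | −0.035069 (inactive: the probe is polar) |
| H-bond (piecewise linear on d ∈ [−0.7, 0]) | −0.587439 |

over protein heavy atoms within 8 Å, where `d = r − R_O − R_atom` is the
vdW-surface distance (X-score radii: C 1.9, N 1.75, O 1.6, S 2.0 Å; table
in `water_scoring.VDW_RADII`). The water probe is a single united-atom
oxygen typed donor-and-acceptor — the deterministic equivalent of a rigid
water whose hydrogens are present but unconstrained. With no rotatable
bonds there is no torsion normalisation, so the weighted sum is the energy
in kcal/mol.

Each candidate site is refined by **exhaustive grid search** in a cube of
half-width 0.25 Å (the 0.5 Å box) at 0.05 Å steps (11³ points): the box is
small enough that exhaustive search replaces a stochastic optimiser
exactly, making the whole pipeline bit-deterministic. Ties break toward
the seed, then lexicographically. An `external` backend drives an AutoDock
Vina binary per site (box 0.5 Å, `num_modes` 1, `exhaustiveness` 5) for
users wanting bit-compatibility with a Vina workflow; it requires `vina`
on PATH and is never used by default.

Protein atom typing is name/residue based (backbone N donor, backbone O
acceptor, the usual side-chain donors/acceptors, His N and hydroxyl O as
donor-and-acceptor). Carbon typing cannot affect water scores — the
hydrophobic term needs both partners apolar — so carbons are typed
hydrophobic generically. Synthetic pockets may declare types directly;
assignment is then a pass-through.

## Selection defaults

| parameter | default | meaning |
|---|---|---|
| `score_cutoff` | −0.55 kcal/mol | discard less favourable sites; boundary **retained** (≤) |
| saturation | per Table above | keep best-energy sites per polar atom; ties by generation order |
| `cluster_distance` | 1.8 Å | single-linkage components; one water per component |
| representative | best-scoring member | centroid available via config |

The cutoff is the trained value of the decision-stump rule (below) and is
exposed, not hard-coded, because it is an empirical constant users may
retune for other scoring backends.

## Trajectory discretisation

`build_grid` histograms water-oxygen positions on a 0.25 Å grid covering
the ligand heavy-atom bounding box padded by 4 Å, one increment per water
per frame. `qt_discretise` then greedily promotes the highest-count
unclaimed voxel to a site centre, claims everything within 2 Å of it, and
stops when the next candidate's own count falls below
`occupancy_floor × n_frames` (default 5%). Site occupancy integrates
counts within 1 Å (half the separation) of the centre so values are
comparable across grid spacings. Raw counts are kept internally;
normalisation happens only at reporting time.

The stopping floor is the module's largest free parameter. Note the
interaction with diffuse density: a Gaussian site of width σ = 0.3 Å puts
only `(Φ(0.125/0.3) − Φ(−0.125/0.3))³ ≈ 3.4%` of its mass in the modal
voxel, below the 5% default. The default targets sharp, MD-like density
peaks; analyses of broader clouds should lower the floor accordingly (the
bundled Gaussian-recovery tests use 2%, from exactly this calculation).

Discretised sites are assigned to the motif with the nearest polar atom
(≤ 4 Å; ties to the lower motif index) and can be expressed as (θ, φ) in
that atom's frame — the same convention the shell generator uses, so
generated shells land inside their defining ranges by construction
(verified in the tests as a cross-module round trip).

## Training and validation statistics

* **Decision-stump cutoff** (`gini_split_cutoff`): scans every midpoint
  between adjacent sorted unique scores and minimises the weighted Gini
  impurity of the conserved/displaced partition (conserved = within 2 Å of
  a reference water); ties resolve to the most negative threshold.
* **Kendall τ-b** wraps `scipy.stats.kendalltau`: exact p by enumeration
  for n ≤ 8 without ties, tie-corrected normal approximation otherwise.
* **Consensus waters**: a crystallographic water within 3.2 Å of both its
  own structure's ligand and protein is a candidate; candidates merge
  across structures by single linkage at 2.0 Å (centroid representative)
  and groups seen in ≥ 2 structures are consensus sites. Structures must
  arrive superposed; a least-squares rigid-fit helper (`superpose`) is
  provided as plumbing.
* **Matching**: greedy nearest-first one-to-one assignment within the
  match radius (2.0 Å, or 1.4 Å for stricter comparisons). A consensus
  water absorbs at most one prediction, so two predictions "chaining"
  around one water count as 1 TP + 1 FP. The mean error is the mean
  matched distance over true positives.
* **Boschloo's unconditional exact test** (`boschloo_test`) is implemented
  directly: statistic = one-sided Fisher (hypergeometric) p of the
  observed table; p-value = supremum over the nuisance success probability
  π of the binomial-product mass of all tables at least as extreme,
  computed on a 1001-point grid with bounded local refinement (accurate to
  ~1e-4, p ∈ (0, 1]). The implementation is kept in-package because the
  statistic-ordering convention matters at the third decimal; an
  independent Fisher implementation serves as the power-bound oracle in
  the tests (Boschloo p ≤ Fisher p always).

## Synthetic fixtures: what they show and don't

`fixtures.make_ligand` builds eleven small rigid molecules (ethanol,
acetate, acetamide, methylamine, dimethyl ether, acetonitrile,
nitromethane, dimethyl sulfone, methyl phosphate, chlorobenzene, pyridine)
covering every motif kind, from SMILES with a fixed embedding seed and
MMFF relaxation — bit-reproducible idealised geometry.

`fixtures.make_pocket` arranges typed pseudo-atoms so the scorer has
minima below the cutoff exactly at chosen ("planted") shell sites: each
planted site receives a triad of acceptors at a 2.75 Å centre distance
(surface distance ≈ −0.45 Å; one H-bond partner alone tops out near
−0.22 kcal/mol, three together reach ≈ −0.67), plus a hydrophobic rim kept
≥ 4.5 Å from every shell site. A generation-time certificate refines
**every** shell site and requires planted sites ≤ cutoff − 0.05 and all
others ≥ −0.30 kcal/mol; generation fails loudly otherwise. End-to-end
recovery tests on such pockets are therefore well-posed by construction.

`fixtures.make_trajectory` emulates saved simulation frames at reduced
scale (default 2000 frames): per frame one sample per Gaussian cloud
(σ = 0.3 Å) plus uniform background noise.

These fixtures certify the algorithmic contracts — geometry, scoring
arithmetic, selection logic, discretisation, statistics — with exact
ground truth and no downloads. They do **not** establish accuracy on real
complexes: real pockets have dense heterogeneous environments, protonation
ambiguity, crystallographic water uncertainty, and ligand strain, none of
which the pseudo-atom pockets model. Benchmarking on real structures runs
through `scripts/reproduce_validation.py` with user-prepared, superposed
PDB inputs.

## Numerical conventions and edge cases

* Coordinates in Å everywhere; energies in kcal/mol; angles in degrees.
* Altlocs: highest occupancy wins, ties by file order; first MODEL only;
  insertion codes participate in atom identity.
* Score filter boundary: a site exactly at the cutoff is retained.
* Clustering threshold boundary: sites exactly at 1.8 Å merge.
* All tie-breaks (saturation, cluster representative, QT voxel order,
  refinement grid) are deterministic; identical inputs give identical
  outputs with the internal backend.
* An empty protein neighbourhood scores exactly 0; header-only water PDB
  files read back as empty structures.
* Degenerate angular case: a site along ẑ has undefined φ, reported as 0
  with a degeneracy flag.

## Problem sizes used in the bundled checks

The self-tests run on single-motif ligands (≤ 16 shell sites), pockets of
≤ 10 pseudo-atoms, trajectories of 400–2000 frames, and 2×2 tables with
row totals ≤ 114 — sizes at which every oracle (dense grid scans, O(n²)
pair counting, exhaustive impurity scans, union-find components) is exact
and fast. The pipeline itself scales linearly in shell sites × protein
atoms within the 8 Å cutoff.

## Known limitations

* Water orientation (hydrogen placement) is not predicted — oxygen
  positions only.
* Protonation/tautomer states are an input contract; nothing is titrated.
* The internal scorer pins the published Vina 1.1.x weights; other Vina
  versions' binaries may give slightly different energies (rank order is
  expected to agree).
* Metals and unusual elements type as `other` (no H-bond term).
* The consensus/matching machinery assumes structures are already
  superposed on the ligand; superposition quality is the caller's
  responsibility.
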