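# aquabridge

Prediction of **bridging water molecules** — waters hydrogen-bonded to both a
protein and its bound ligand — in *holo* protein–ligand complexes.

Bridging waters mediate a large fraction of protein–ligand interfaces and can
dominate ligand orientation and binding free energy, yet many structures
(NMR, homology models, docking poses) arrive without water coordinates.
`aquabridge` places them quickly and deterministically from the ligand side:
instead of searching the whole pocket, it exploits the fact that the
preferred hydration geometry of a polar functional group is largely
transferable between chemical environments.

## Method

For a prepared protein (PDB) and a ligand with 3-D coordinates, bond orders
and explicit polar hydrogens (SDF/MOL2/PDB):

1. **Motif detection.** Eleven polar motifs (carbonyl, carboxyl, cyano,
   imine, nitro, amine, sulfonyl, phosphoryl, hydroxyl, ether, halogen) are
   matched by SMARTS patterns in a fixed precedence order. Each motif
   carries a hydrogen-bond *saturation limit* from VSEPR lone-pair/bound-H
   counting (e.g. carboxyl 2 per oxygen, hydroxyl 3, cyano 1, amine = number
   of N–H).
2. **Hydration shells.** Candidate water oxygens are tiled on a 3.0 Å
   sphere about each polar atom (the experimental H-bond length), 2.0 Å
   apart, within motif-specific angular ranges expressed in a local frame
   (θ from the bond axis ẑ, φ from x̂): carbonyl θ∈[40°,140°], φ∈[20°,160°];
   carboxyl-like motifs θ∈[60°,160°], φ∈[0°,180°]; ether/imine a single arc
   at θ=90°; amine one site along each N–H; hydroxyl = ether arc + O–H site.
3. **Scoring.** Each site is scored against the protein with the published
   AutoDock Vina functional form (gauss1/gauss2/repulsion/H-bond terms,
   published weights) for a single united-atom water probe typed as donor
   and acceptor, refined by exhaustive grid search inside a 0.5 Å box
   (step 0.05 Å) — a deterministic equivalent of a tightly boxed docking
   run. An external `vina` binary can be substituted per configuration.
4. **Selection.** Sites scoring above −0.55 kcal/mol are discarded; at most
   the saturation limit survives per polar atom (best energies first);
   finally single-linkage clustering at 1.8 Å merges sites subtended by
   several functional groups into one water each.

The package also implements the machinery used to derive and validate such
a pipeline: occupancy-grid discretisation of water trajectories
(0.25 Å grid, quality-threshold clustering at 2 Å), consensus-water
extraction from superposed structures (3.2 Å criterion), greedy one-to-one
TP/FP matching, the Gini decision-stump cutoff training rule, Kendall τ-b,
and **Boschloo's unconditional exact test** for 2×2 method comparisons.

## Worked example

Generate a synthetic complex (an acetamide ligand in a self-certified
pseudo-atom pocket with one planted favourable water site) and run the
pipeline:

```sh
aquabridge fixtures --kind ligand --template acetamide --out lig.sdf
aquabridge fixtures --kind pocket --template acetamide --seed 3 --out pocket.pdb
aquabridge predict --protein pocket.pdb --ligand lig.sdf --out waters.pdb
```

Output:

```text
predicted 1 bridging waters -> waters.pdb
```

with `waters.pdb` containing one HETATM HOH oxygen (B-factor column =
score × −10, i.e. 6.74 for a −0.674 kcal/mol site) and a machine-readable
stage report `waters.report.json`:

```json
{
  "n_motifs": 2,
  "n_candidate_sites": 7,
  "n_after_cutoff": 1,
  "n_after_saturation": 1,
  "n_predicted_waters": 1
}
```

Read: the ligand carries a carbonyl and an amide N–H motif (7 candidate
sites); exactly one site scores below the −0.55 kcal/mol cutoff — the one
the pocket was built around — and it survives saturation and clustering as
the single predicted bridging water, 0.01 Å from the planted position.

The same stages are available as library calls
(`aquabridge.site_selection.predict`, `aquabridge.hydration_model.build_shell`,
`aquabridge.evaluation.boschloo_test`, …).

## Layout

```
src/aquabridge/
  structure_io.py       PDB / SDF / MOL2 I/O, water records
  functional_groups.py  SMARTS motif detection, saturation limits, frames
  hydration_model.py    hydration-shell site generation
  water_scoring.py      internal Vina-form scorer + external backend
  site_selection.py     cutoff / saturation / clustering pipeline
  md_discretise.py      occupancy grids, QT clustering, angular analysis
  evaluation.py         consensus waters, matching, Gini, Kendall, Boschloo
  fixtures.py           synthetic ligands, pockets, trajectories
  cli.py                `aquabridge` command-line entry point
```

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.
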