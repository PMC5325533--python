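#!/usr/bin/env python
"""Reproduce the crystal-structure validation benchmark on user-supplied data.

The full benchmark compares predicted bridging waters against consensus
crystallographic waters across pairs (or triples) of independently solved
holo structures, and against a 14-structure oligopeptide-binding-protein
series.  Those structures are not bundled here: reproducing the benchmark
requires downloading the PDB entries, verifying ligand protonation, and
superposing the structures on their ligands — choices that materially
affect the counts and that the user must control.

Given prepared inputs, this script runs the complete loop:

1. predict bridging waters for the (protein, ligand) complex;
2. extract consensus waters from >= 2 superposed reference structures
   (water within 3.2 A of both ligand and protein, seen more than once);
3. match predictions to consensus sites at a 2.0 A (or 1.4 A) radius and
   report true/false positives and the mean error over true positives.

Example:
    python scripts/reproduce_validation.py \
        --protein prepared/1xws_protein.pdb --ligand prepared/1xws_ligand.sdf \
        --reference prepared/1xws.pdb --reference prepared/2bik.pdb \
        --radius 2.0 --out pim1_report.json

Repeat per complex and sum the TP/FP columns; the 2x2 method comparison
can then be tested with aquabridge.evaluation.boschloo_test.
"""

import argparse
import json
from pathlib import Path

from aquabridge import evaluation, site_selection, structure_io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--protein", required=True, type=Path)
    parser.add_argument("--ligand", required=True, type=Path)
    parser.add_argument("--reference", action="append", required=True, type=Path,
                        help="superposed holo PDB with crystallographic waters "
                             "(give at least twice)")
    parser.add_argument("--radius", type=float, default=2.0)
    parser.add_argument("--out", required=True, type=Path)
    args = parser.parse_args()
    if len(args.reference) < 2:
        parser.error("need at least two --reference structures")

    protein = structure_io.read_protein(args.protein)
    ligand = structure_io.read_ligand(args.ligand)
    waters = site_selection.predict(protein, ligand)

    structures = []
    for ref in args.reference:
        prot = structure_io.read_protein(ref)
        structures.append((prot, ligand.heavy_coords(), prot.waters))
    consensus = evaluation.consensus_waters(structures)
    report = evaluation.match_predictions(waters, consensus, radius=args.radius)

    payload = {
        "n_consensus": report.n_consensus,
        "n_predicted": report.n_predicted,
        "n_true_positive": report.n_true_positive,
        "n_false_positive": report.n_false_positive,
        "match_radius": report.match_radius,
        "mean_error_A": report.mean_error,
    }
    args.out.write_text(json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
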