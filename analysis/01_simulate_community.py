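#!/usr/bin/env python
"""Generate the synthetic study community and summarise what was planted.

Writes the full workspace (sequences, evidence, read placements, hosts,
truth tables) under scratch/workspace and a compact composition summary
under results/.  Run from the repository root:

    python analysis/01_simulate_community.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from virocat.io import read_table, write_table
from virocat.simulate import simulate_workspace


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--workspace", type=Path, default=Path("scratch/workspace"))
    args = ap.parse_args()

    truths = simulate_workspace(args.workspace, n_genomes=60, n_samples=5,
                                seed=args.seed)
    truth = read_table(args.workspace / "truth" / "genomes.tsv")
    summary = (truth.assign(role=truth.apply(_role, axis=1))
               .groupby("role").size().rename("n_contigs").reset_index())
    Path("results").mkdir(exist_ok=True)
    write_table(summary, "results/community_composition.tsv")
    print(f"workspace: {args.workspace} (seed {args.seed})")
    print(summary.to_string(index=False))
    n_circ = int(truth["is_circular"].sum())
    print(f"\nplanted: {n_circ} circular genomes, "
          f"{int(truth['removed_as_bacterial'].sum())} bacterial contaminants, "
          f"{int(truth['below_length'].sum())} sub-5kb fragments")


def _role(row) -> str:
    if row["removed_as_bacterial"]:
        return "bacterial contaminant"
    if not row["is_viral"]:
        return "non-viral background"
    if row["below_length"]:
        return "viral fragment (<5 kb)"
    if row["divergence"] > 0.1:
        return "mosaic (partial-novelty)"
    if row["divergence"] > 0:
        return "cluster member (mutant)"
    return "cluster founder"


if __name__ == "__main__":
    main()
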