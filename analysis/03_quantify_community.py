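#!/usr/bin/env python
"""Prevalence, diversity and rarefaction of the catalogue across samples.

Copies the per-sample Shannon indices, pairwise Bray-Curtis
dissimilarities, per-vOTU prevalence and the sample-accumulation
(rarefaction) curve into results/.  Requires analysis/02 to have run.
"""

import argparse
import shutil
from pathlib import Path

from virocat.io import read_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workspace", type=Path, default=Path("scratch/workspace"))
    args = ap.parse_args()
    derived = args.workspace / "derived"
    Path("results").mkdir(exist_ok=True)
    for name in ("shannon", "bray_curtis", "prevalence", "rarefaction"):
        shutil.copy(derived / f"{name}.tsv", f"results/{name}.tsv")
    sh = read_table(derived / "shannon.tsv")
    bc = read_table(derived / "bray_curtis.tsv")
    prev = read_table(derived / "prevalence.tsv")
    rare = read_table(derived / "rarefaction.tsv")
    print(f"Shannon index: mean {sh['shannon'].mean():.3f} nats "
          f"(range {sh['shannon'].min():.3f}-{sh['shannon'].max():.3f}) "
          f"over {len(sh)} samples")
    print(f"Bray-Curtis dissimilarity: mean {bc['bray_curtis'].mean():.3f} "
          f"over {len(bc)} sample pairs")
    print(f"prevalence: {int((prev['prevalence'] == 1.0).sum())} vOTUs in "
          f"every sample; {int((prev['prevalence'] == 0).sum())} in none")
    print(f"rarefaction: {rare['mean_unique'].iloc[0]:.1f} unique vOTUs at "
          f"1 sample -> {rare['mean_unique'].iloc[-1]:.1f} at "
          f"{int(rare['k'].iloc[-1])} samples")


if __name__ == "__main__":
    main()
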