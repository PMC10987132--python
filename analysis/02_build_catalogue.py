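#!/usr/bin/env python
"""Build the viral catalogue from the simulated workspace and report the
headline fractions (completeness, assembly-source groups, novelty).

Runs the calling, circularity, dereplication, novelty and clustering
stages, then copies the catalogue summary into results/.  Requires
analysis/01_simulate_community.py to have run first.
"""

import argparse
import json
import shutil
from pathlib import Path

from virocat.pipeline import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workspace", type=Path, default=Path("scratch/workspace"))
    args = ap.parse_args()

    run_pipeline(args.workspace)
    report = json.loads(
        (args.workspace / "catalogue" / "report.json").read_text())
    Path("results").mkdir(exist_ok=True)
    shutil.copy(args.workspace / "catalogue" / "report.json",
                "results/catalogue_report.json")
    print(f"catalogue: {report['n_votus']} vOTUs")
    print(f"  complete (circular): {report['pct_circular']}%")
    print(f"  long-read group {report['pct_group_long_read']}% / "
          f"short-read {report['pct_group_short_read']}% / "
          f"both {report['pct_group_both']}%")
    print(f"  novelty: {report['pct_novelty_novel']}% novel, "
          f"{report['pct_novelty_partial']}% partial, "
          f"{report['pct_novelty_identical']}% identical")
    print(f"  viral clusters: {report['n_vcs']} "
          f"({report['n_nonsingleton_vcs']} non-singleton)")


if __name__ == "__main__":
    main()
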