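#!/usr/bin/env python
"""Lifestyle composition, COG-category enrichment of novel vOTUs, host
assignment and the phage-host network.

Also recomputes the published worked example: the virulent-side share of
the reference gut catalogue from its printed per-category counts.
Requires analysis/02 to have run (host/lifestyle stages run here if
missing).
"""

import argparse
import shutil
from pathlib import Path

from virocat.clades import (cog_enrichment, published_lifestyle_reference,
                            virulent_side_percentage)
from virocat.io import read_table, write_table
from virocat.pipeline import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--workspace", type=Path, default=Path("scratch/workspace"))
    args = ap.parse_args()
    ws = args.workspace
    run_pipeline(ws)   # completes any remaining stages; no-op otherwise
    Path("results").mkdir(exist_ok=True)

    style = read_table(ws / "derived" / "lifestyle.tsv")
    counts = style["category"].value_counts().to_dict()
    pct = virulent_side_percentage(counts, len(style))
    print(f"simulated catalogue: {pct}% of {len(style)} vOTUs on the "
          f"virulent side")
    ref = published_lifestyle_reference()
    ref_pct = virulent_side_percentage(ref["counts"], ref["catalogue_size"])
    print(f"published worked example: {ref_pct}% of "
          f"{ref['catalogue_size']} vOTUs on the virulent side")

    # COG enrichment of novel vOTUs' proteins vs the rest
    cog = read_table(ws / "inputs" / "cog.tsv", schema="cog")
    novelty = read_table(ws / "derived" / "novelty.tsv")
    novel_ids = set(novelty.loc[novelty["class"] == "novel", "contig_id"])
    cog = cog[cog["contig_id"].isin(set(novelty["contig_id"]))]
    is_novel = cog["contig_id"].isin(novel_ids)
    novel_counts = cog[is_novel]["category"].value_counts().to_dict()
    other_counts = cog[~is_novel]["category"].value_counts().to_dict()
    enr = cog_enrichment(novel_counts, other_counts,
                         int(is_novel.sum()), int((~is_novel).sum()))
    write_table(enr, "results/cog_enrichment.tsv")
    for _, row in enr.iterrows():
        tag = "ENRICHED" if row["enriched"] else "-"
        print(f"  {row['category']}: chi2={row['chi2']:.2f} "
              f"p={row['p']:.2e} {tag}")

    ev = read_table(ws / "derived" / "host_evidence.tsv")
    hi = ev[ev["confidence"] == "high"]
    print(f"hosts: {ev['virus_id'].nunique()} viruses linked "
          f"({hi['virus_id'].nunique()} high-confidence)")
    for name in ("host_evidence", "host_range", "network_edges", "vt_ratio"):
        shutil.copy(ws / "derived" / f"{name}.tsv", f"results/{name}.tsv")


if __name__ == "__main__":
    main()
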