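"""Presence, prevalence, abundance, diversity and rarefaction statistics.

A vOTU is "present" in a sample when reads cover more than 50% of its
length at a mean depth above 4X.  Abundance is RPKM (reads per kilobase
per million mapped), renormalised over present vOTUs to relative
abundance; VC abundance is the sum over members.  Shannon diversity is in
nats; between-sample dissimilarity is Bray–Curtis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .config import PipelineConfig


@dataclass
class CoverageSummary:
    sample_id: str
    contig_id: str
    breadth: float       # fraction of positions covered >= 1
    mean_depth: float    # x-fold over the whole contig
    mapped_reads: int


def summarize_coverage(placements: pd.DataFrame,
                       contig_lengths: Mapping[str, int]) -> List[CoverageSummary]:
    """Per-sample per-contig breadth, mean depth and read counts.

    Depth is computed over the entire contig via a difference array of the
    read placements; ``mapped_reads`` counts distinct read ids.
    """
    out: List[CoverageSummary] = []
    if len(placements) == 0:
        return out
    for (sample, contig), grp in placements.groupby(
            ["sample_id", "contig_id"], sort=True):
        length = contig_lengths[contig]
        diff = np.zeros(length + 1, dtype=np.int64)
        starts = grp["start"].astype(int).to_numpy()
        ends = grp["end"].astype(int).to_numpy()
        if (starts < 0).any() or (ends > length).any():
            raise ValueError(f"placement outside contig bounds for {contig}")
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        depth = np.cumsum(diff[:-1])
        out.append(CoverageSummary(
            sample_id=str(sample), contig_id=str(contig),
            breadth=float((depth > 0).mean()),
            mean_depth=float(depth.mean()),
            mapped_reads=int(grp["read_id"].nunique())))
    return out


def is_present(cs: CoverageSummary, cfg: PipelineConfig | None = None) -> bool:
    """Presence rule: breadth strictly > 0.5 AND mean depth strictly > 4."""
    cfg = cfg or PipelineConfig()
    return cs.breadth > cfg.presence_breadth and cs.mean_depth > cfg.presence_depth


def rpkm(mapped_reads: float, length: int, total_mapped_in_sample: float) -> float:
    """Reads per kilobase of contig per million mapped reads in the sample."""
    if total_mapped_in_sample <= 0:
        raise ValueError("RPKM undefined for a sample with zero mapped reads")
    if length <= 0:
        raise ValueError("RPKM undefined for a non-positive contig length")
    return mapped_reads / (length / 1000.0) / (total_mapped_in_sample / 1e6)


def abundance_tables(coverage: Sequence[CoverageSummary],
                     contig_lengths: Mapping[str, int],
                     cfg: PipelineConfig | None = None):
    """RPKM, presence and relative-abundance matrices (sample x vOTU).

    Absent vOTUs are zeroed before normalisation, so each row with at least
    one present vOTU sums to 1; rows with none are all zero.
    """
    cfg = cfg or PipelineConfig()
    samples = sorted({cs.sample_id for cs in coverage})
    contigs = sorted(contig_lengths)
    rpkm_m = pd.DataFrame(0.0, index=samples, columns=contigs)
    pres = pd.DataFrame(False, index=samples, columns=contigs)
    totals = {s: sum(cs.mapped_reads for cs in coverage if cs.sample_id == s)
              for s in samples}
    for cs in coverage:
        if totals[cs.sample_id] > 0:
            rpkm_m.loc[cs.sample_id, cs.contig_id] = rpkm(
                cs.mapped_reads, contig_lengths[cs.contig_id],
                totals[cs.sample_id])
        pres.loc[cs.sample_id, cs.contig_id] = is_present(cs, cfg)
    rel = relative_abundance(rpkm_m, pres)
    return rpkm_m, pres, rel


def relative_abundance(rpkm_matrix: pd.DataFrame,
                       presence: pd.DataFrame) -> pd.DataFrame:
    if rpkm_matrix.shape != presence.shape:
        raise ValueError("RPKM and presence matrices must share shape")
    masked = rpkm_matrix.where(presence, 0.0)
    row_tot = masked.sum(axis=1)
    rel = masked.div(row_tot.where(row_tot > 0, 1.0), axis=0)
    return rel


def vc_abundance(rel: pd.DataFrame, presence: pd.DataFrame,
                 clusters: Mapping[str, Sequence[str]]):
    """Sum member abundances per VC; a VC is present when any member is."""
    vc_rel = pd.DataFrame(index=rel.index,
                          columns=sorted(clusters), dtype=float)
    vc_pres = pd.DataFrame(index=rel.index,
                           columns=sorted(clusters), dtype=bool)
    for vc, members in clusters.items():
        missing = [m for m in members if m not in rel.columns]
        if missing:
            raise ValueError(f"cluster {vc} references unknown vOTUs {missing}")
        vc_rel[vc] = rel[list(members)].sum(axis=1)
        vc_pres[vc] = presence[list(members)].any(axis=1)
    return vc_rel, vc_pres


def prevalence(presence: pd.DataFrame) -> pd.Series:
    """Per-vOTU fraction of samples in which it is present."""
    if presence.shape[0] == 0:
        raise ValueError("prevalence requires at least one sample")
    return presence.mean(axis=0)


def shannon(row: Sequence[float]) -> float:
    """Shannon diversity in nats over the positive entries of one sample."""
    p = np.asarray(row, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    p = p[p > 0]
    if p.size <= 1:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity: 1 - 2 sum(min) / (sum a + sum b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rows must share dimension")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero rows")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def rarefaction(sample_sets: Mapping[str, Set[str]], seed: int,
                n_resamples: int = 10) -> pd.DataFrame:
    """Mean unique-vOTU accumulation over random sample subsets.

    For each subset size k, draws ``n_resamples`` random k-subsets of the
    samples and records the mean and standard deviation of the union-set
    size.  Deterministic for a fixed seed.
    """
    samples = sorted(sample_sets)
    if not samples:
        raise ValueError("rarefaction requires at least one sample")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, len(samples) + 1):
        sizes = []
        for _ in range(n_resamples):
            chosen = rng.choice(samples, size=k, replace=False)
            union: Set[str] = set()
            for s in chosen:
                union |= sample_sets[s]
            sizes.append(len(union))
        rows.append({"k": k, "mean_unique": float(np.mean(sizes)),
                     "sd_unique": float(np.std(sizes, ddof=0))})
    return pd.DataFrame(rows, columns=["k", "mean_unique", "sd_unique"])
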