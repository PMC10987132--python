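"""Contig-level viral calling, bacterial decontamination and length filter.

A contig is annotated viral if it is circular, or meets at least two of
five detector criteria, or meets one criterion while CheckV rates it
high-quality (>=90% complete):

  C1  VirSorter score >= 0.7
  C2  VirFinder score >  0.6
  C3  PPR-Meta phage score > 0.7
  C4  viral RefSeq hit with > 50% identity and > 90% coverage
  C5  >= 3 ORFs with phage-orthologue (POG) hits, at least 2 per 10 kb

Missing detector output never satisfies a criterion.  Candidate viral
contigs matching a prophage-masked bacterial catalogue at >=90% identity
over >=50% of their length are removed as bacterial; finally only contigs
strictly longer than 5 kb are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import PipelineConfig
from .homology import Hsp, _merge_intervals
from .io import Contig


@dataclass
class EvidenceRecord:
    """Per-contig detector scores and hit statistics; None = tool silent."""

    contig_id: str
    virsorter_score: Optional[float] = None
    virfinder_score: Optional[float] = None
    pprmeta_score: Optional[float] = None
    refseq_hit_identity: Optional[float] = None
    refseq_hit_coverage: Optional[float] = None
    pog_hit_orfs: int = 0
    checkv_completeness: Optional[float] = None
    checkv_quality: Optional[str] = None


@dataclass
class CallResult:
    contig_id: str
    satisfied_criteria: Set[str]
    circular: bool
    hq_rescue: bool
    is_virus: bool
    removed_as_bacterial: bool = False
    passed_length: bool = True


def _num(x) -> Optional[float]:
    if x is None:
        return None
    try:
        if isinstance(x, float) and math.isnan(x):
            return None
    except TypeError:
        pass
    return float(x)


def evaluate_criteria(e: EvidenceRecord, length: int,
                      cfg: PipelineConfig | None = None) -> Set[str]:
    """Which of the five calling criteria the evidence satisfies."""
    cfg = cfg or PipelineConfig()
    if length <= 0:
        raise ValueError(f"non-positive contig length for {e.contig_id}")
    crit: Set[str] = set()
    vs = _num(e.virsorter_score)
    if vs is not None and vs >= cfg.virsorter_min:
        crit.add("C1")
    vf = _num(e.virfinder_score)
    if vf is not None and vf > cfg.virfinder_min:
        crit.add("C2")
    pm = _num(e.pprmeta_score)
    if pm is not None and pm > cfg.pprmeta_min:
        crit.add("C3")
    ident, cov = _num(e.refseq_hit_identity), _num(e.refseq_hit_coverage)
    if (ident is not None and cov is not None
            and ident > cfg.refseq_min_identity
            and cov > cfg.refseq_min_coverage):
        crit.add("C4")
    orfs = int(e.pog_hit_orfs or 0)
    if orfs >= cfg.pog_min_orfs and orfs / (length / 10000) >= cfg.pog_min_per_10kb:
        crit.add("C5")
    return crit


def call_virus(criteria: Set[str], circular: bool, e: EvidenceRecord,
               cfg: PipelineConfig | None = None) -> bool:
    """Viral iff circular, >=2 criteria, or 1 criterion + CheckV high-quality."""
    cfg = cfg or PipelineConfig()
    if circular or len(criteria) >= 2:
        return True
    comp = _num(e.checkv_completeness)
    return (len(criteria) == 1 and comp is not None
            and comp >= cfg.checkv_hq_completeness)


def mask_prophages(genome: Contig,
                   intervals: Sequence[Tuple[int, int]]) -> Contig:
    """Excise prophage intervals (0-based half-open, merged first)."""
    for a, b in intervals:
        if not (0 <= a < b <= genome.length):
            raise ValueError(
                f"prophage interval [{a},{b}) out of bounds for "
                f"{genome.id} (length {genome.length})")
    merged = _merge_intervals(intervals)
    kept = []
    pos = 0
    for a, b in merged:
        kept.append(genome.sequence[pos:a])
        pos = b
    kept.append(genome.sequence[pos:])
    return Contig(id=genome.id, sequence="".join(kept) or "N",
                  sample_id=genome.sample_id,
                  assembly_source=genome.assembly_source)


def decontaminate(contig: Contig, bacterial_hits: Sequence[Hsp],
                  cfg: PipelineConfig | None = None) -> bool:
    """True when the contig should be removed as bacterial.

    Hits (against the prophage-masked bacterial set) at >=90% identity are
    merged on the contig; removal requires the merged regions to cover
    >=50% of the contig length.  Invariant to how one aligned region is
    split across HSPs.
    """
    cfg = cfg or PipelineConfig()
    keep = [(h.q_start, h.q_end) for h in bacterial_hits
            if h.identity >= cfg.decontam_identity]
    covered = sum(b - a for a, b in _merge_intervals(keep))
    return covered >= (cfg.decontam_coverage / 100.0) * contig.length


def length_filter(contigs: Sequence[Contig],
                  cfg: PipelineConfig | None = None) -> List[Contig]:
    """Keep contigs strictly longer than 5 kb, longest first (ties by id)."""
    cfg = cfg or PipelineConfig()
    kept = [c for c in contigs if c.length > cfg.min_contig_len]
    return sorted(kept, key=lambda c: (-c.length, c.id))


def evidence_from_row(row) -> EvidenceRecord:
    """Build an EvidenceRecord from a parsed evidence-table row."""
    def get(col):
        v = row.get(col)
        return None if pd.isna(v) else v

    return EvidenceRecord(
        contig_id=str(row["contig_id"]),
        virsorter_score=get("virsorter_score"),
        virfinder_score=get("virfinder_score"),
        pprmeta_score=get("pprmeta_score"),
        refseq_hit_identity=get("refseq_hit_identity"),
        refseq_hit_coverage=get("refseq_hit_coverage"),
        pog_hit_orfs=int(get("pog_hit_orfs") or 0),
        checkv_completeness=get("checkv_completeness"),
        checkv_quality=get("checkv_quality"),
    )


def calls_table(results: Sequence[CallResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        mask = "".join("1" if f"C{i}" in r.satisfied_criteria else "0"
                       for i in range(1, 6))
        rows.append({"contig_id": r.contig_id, "criteria": mask,
                     "n_criteria": len(r.satisfied_criteria),
                     "circular": r.circular, "hq_rescue": r.hq_rescue,
                     "is_virus": r.is_virus,
                     "removed_as_bacterial": r.removed_as_bacterial,
                     "passed_length": r.passed_length})
    return pd.DataFrame(rows, columns=["contig_id", "criteria", "n_criteria",
                                       "circular", "hq_rescue", "is_virus",
                                       "removed_as_bacterial",
                                       "passed_length"])
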