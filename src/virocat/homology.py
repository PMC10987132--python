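"""Nucleotide homology engine: HSP detection, merged-region ANI,
dereplication, assembly-source attribution and novelty classification.

The local-alignment search is a classical seed-and-extend scheme: exact
k-mer anchors (k=15, both strands) grouped by diagonal, extended without
gaps under an X-drop criterion (match +1 / mismatch -2, drop 20).  Ungapped
extension is the right model here because every downstream rule in the
catalogue (95% dereplication identity, 95/70 novelty classes, 90%-identity
cluster-graph coverage) operates far above the divergence where indel
handling changes merged-region coverage materially; a gapped
Smith–Waterman is used only as a test oracle, never in the pipeline.

`N` bases never count as matches anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .io import Contig

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Hsp:
    """A high-scoring ungapped segment pair; coordinates 0-based half-open.

    ``s_start``/``s_end`` are always on the forward strand of the subject;
    ``strand`` '-' means the query matches the reverse complement.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float      # percent
    aligned_len: int
    strand: str          # '+' | '-'
    score: float

    def __post_init__(self) -> None:
        assert self.q_end > self.q_start
        assert self.aligned_len == self.q_end - self.q_start


@dataclass
class AniResult:
    query_id: str
    subject_id: str
    ani: float                 # percent of query covered by merged regions
    merged_coverage: float     # fraction of query
    n_regions: int
    novelty_class: str         # identical | partial | novel


@dataclass
class DerepResult:
    representative_id: str
    member_ids: List[str]
    identity_to_rep: Dict[str, float]   # percent, per member


def _as_seq(x) -> Tuple[str, str]:
    if isinstance(x, Contig):
        return x.id, x.sequence
    return "seq", str(x).upper()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


def _seed_index(seq: str, k: int) -> Dict[str, List[int]]:
    idx: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _xdrop_right(scores: np.ndarray, xdrop: float) -> int:
    """Length of the best extension into ``scores`` under the X-drop rule.

    Walk the cumulative score; stop once it falls ``xdrop`` below its running
    maximum; return the offset just past the maximum (0 = no extension).
    """
    if scores.size == 0:
        return 0
    cum = np.cumsum(scores)
    runmax = np.maximum.accumulate(cum)
    dropped = np.nonzero(runmax - cum > xdrop)[0]
    stop = dropped[0] if dropped.size else scores.size
    if stop == 0:
        return 0
    best = int(np.argmax(cum[:stop]))
    return best + 1 if cum[best] > 0 else 0


def find_hsps(query, subject, min_identity: float = 90.0, min_len: int = 100,
              *, k: int = 15, xdrop: float = 20.0, match: float = 1.0,
              mismatch: float = -2.0, both_strands: bool = True) -> List[Hsp]:
    """Find ungapped local-alignment segments between two sequences.

    Returns segments with identity >= ``min_identity`` percent and length
    >= ``min_len``, sorted by query start.  Overlapping segments on the same
    diagonal are merged before filtering.
    """
    q_id, q_seq = _as_seq(query)
    s_id, s_seq = _as_seq(subject)
    if not q_seq or not s_seq:
        raise ValueError("find_hsps requires non-empty sequences")
    hsps: List[Hsp] = []
    qa = _encode(q_seq)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        sub = s_seq if strand == "+" else revcomp(s_seq)
        segs = _hsps_one_strand(qa, q_seq, sub, k, xdrop, match, mismatch)
        for qb, qe, sb, se, n_match, score in segs:
            length = qe - qb
            ident = 100.0 * n_match / length
            if length >= min_len and ident >= min_identity:
                if strand == "+":
                    s0, s1 = sb, se
                else:
                    s0, s1 = len(s_seq) - se, len(s_seq) - sb
                hsps.append(Hsp(q_id, s_id, qb, qe, s0, s1, ident, length,
                                strand, score))
    hsps.sort(key=lambda h: (h.q_start, h.q_end, h.strand))
    return hsps


def _hsps_one_strand(qa: np.ndarray, q_seq: str, s_seq: str, k: int,
                     xdrop: float, match: float, mismatch: float):
    """Seed, extend and merge on one subject strand.

    Yields ``(q_start, q_end, s_start, s_end, n_matches, score)`` tuples with
    subject coordinates on the strand searched.
    """
    lq, ls = len(q_seq), len(s_seq)
    if lq < k or ls < k:
        return []
    index = _seed_index(s_seq, k)
    sa = _encode(s_seq)
    # diagonal -> list of (q_start, q_end) already-extended intervals
    covered: Dict[int, List[Tuple[int, int]]] = {}
    match_cache: Dict[int, Tuple[np.ndarray, int]] = {}
    raw: Dict[int, List[Tuple[int, int]]] = {}

    for qpos in range(lq - k + 1):
        kmer = q_seq[qpos:qpos + k]
        if "N" in kmer:
            continue
        for spos in index.get(kmer, ()):
            diag = qpos - spos
            if any(a <= qpos and qpos + k <= b for a, b in covered.get(diag, ())):
                continue
            if diag not in match_cache:
                q0 = max(0, diag)               # first query pos on diagonal
                q1 = min(lq, ls + diag)         # one past last
                qs = qa[q0:q1]
                ss = sa[q0 - diag:q1 - diag]
                m = (qs == ss) & (qs != _N)
                match_cache[diag] = (m, q0)
            m, q0 = match_cache[diag]
            scores = np.where(m, match, mismatch)
            i0, i1 = qpos - q0, qpos - q0 + k   # seed inside diagonal array
            right = _xdrop_right(scores[i1:], xdrop)
            left = _xdrop_right(scores[:i0][::-1], xdrop)
            qb, qe = qpos - left, qpos + k + right
            covered.setdefault(diag, []).append((qb, qe))
            raw.setdefault(diag, []).append((qb, qe))

    out = []
    for diag, ivals in raw.items():
        m, q0 = match_cache[diag]
        for qb, qe in _merge_intervals(ivals):
            seg = m[qb - q0:qe - q0]
            n_match = int(seg.sum())
            score = match * n_match + mismatch * (len(seg) - n_match)
            out.append((qb, qe, qb - diag, qe - diag, n_match, score))
    return out


def _merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivals = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for a, b in ivals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# Merged-region ANI and novelty
# ---------------------------------------------------------------------------

def merge_regions(hsps: Sequence[Hsp], min_identity: float,
                  min_len: int) -> List[Tuple[int, int]]:
    """Filter HSPs and merge their query projections into disjoint intervals.

    Only segments with identity >= ``min_identity`` and aligned length >=
    ``min_len`` contribute; both strands project onto the query the same way.
    """
    if hsps:
        queries = {h.query_id for h in hsps}
        if len(queries) > 1:
            raise ValueError(f"HSPs span multiple queries: {sorted(queries)}")
    keep = [(h.q_start, h.q_end) for h in hsps
            if h.identity >= min_identity and h.aligned_len >= min_len]
    return _merge_intervals(keep)


def classify_novelty(ani: float, cfg: PipelineConfig) -> str:
    if ani >= cfg.novelty_identical:
        return "identical"
    if ani >= cfg.novelty_partial:
        return "partial"
    return "novel"


def compute_ani(query, subject, cfg: PipelineConfig | None = None) -> AniResult:
    """Merged-region ANI of ``query`` against ``subject``.

    ANI here is the percentage of the query covered by merged >=95%-identity
    alignment regions of >=500 bp — the operational definition behind the
    95/70 identical/partial/novel class cuts.  It is asymmetric
    (query-normalised): the catalogue sequence is always the query.
    """
    cfg = cfg or PipelineConfig()
    q_id, q_seq = _as_seq(query)
    s_id, _ = _as_seq(subject)
    hsps = find_hsps(query, subject, min_identity=cfg.novelty_hsp_identity,
                     min_len=cfg.novelty_hsp_minlen)
    regions = merge_regions(hsps, cfg.novelty_hsp_identity,
                            cfg.novelty_hsp_minlen)
    covered = sum(b - a for a, b in regions)
    frac = covered / len(q_seq)
    ani = 100.0 * frac
    return AniResult(q_id, s_id, ani, frac, len(regions),
                     classify_novelty(ani, cfg))


def novelty_vs_catalogues(votus: Sequence[Contig],
                          catalogues: Mapping[str, Sequence[Contig]],
                          cfg: PipelineConfig | None = None):
    """Best novelty class of each vOTU over all reference catalogues.

    Returns a DataFrame (contig_id, best_reference, best_catalogue, ani,
    class): the max-ANI reference across every catalogue decides the class.
    """
    import pandas as pd

    cfg = cfg or PipelineConfig()
    if not catalogues or all(len(v) == 0 for v in catalogues.values()):
        raise ValueError("novelty classification requires non-empty references")
    rows = []
    for votu in votus:
        best_ani, best_ref, best_cat = 0.0, "", ""
        for cat_name, refs in sorted(catalogues.items()):
            for ref in refs:
                r = compute_ani(votu, ref, cfg)
                if r.ani > best_ani:
                    best_ani, best_ref, best_cat = r.ani, ref.id, cat_name
        rows.append({"contig_id": votu.id, "best_reference": best_ref,
                     "best_catalogue": best_cat, "ani": best_ani,
                     "class": classify_novelty(best_ani, cfg)})
    return pd.DataFrame(rows, columns=["contig_id", "best_reference",
                                       "best_catalogue", "ani", "class"])


# ---------------------------------------------------------------------------
# Global identity and dereplication
# ---------------------------------------------------------------------------

def global_identity(a, b, *, k: int = 15) -> float:
    """CD-HIT-style global identity: matched bases over the shorter sequence.

    The best chain of ungapped HSPs is projected onto the shorter sequence;
    matched bases in non-overlapping portions are summed and divided by the
    shorter length.  Returns a fraction in [0, 1].
    """
    a_id, a_seq = _as_seq(a)
    b_id, b_seq = _as_seq(b)
    if len(a_seq) <= len(b_seq):
        query, subject, lq = (a_id, a_seq), (b_id, b_seq), len(a_seq)
    else:
        query, subject, lq = (b_id, b_seq), (a_id, a_seq), len(b_seq)
    hsps = find_hsps(Contig(*query), Contig(*subject), min_identity=0.0,
                     min_len=k)
    # Greedy claim of query positions by descending score: overlapping HSPs
    # contribute only their unclaimed span, credited at the HSP's identity.
    claimed: List[Tuple[int, int]] = []
    matched = 0.0
    for h in sorted(hsps, key=lambda h: -h.score):
        span = [(h.q_start, h.q_end)]
        for a0, a1 in claimed:
            nxt = []
            for s0, s1 in span:
                if s1 <= a0 or s0 >= a1:
                    nxt.append((s0, s1))
                else:
                    if s0 < a0:
                        nxt.append((s0, a0))
                    if s1 > a1:
                        nxt.append((a1, s1))
            span = nxt
        free = sum(s1 - s0 for s0, s1 in span)
        matched += free * h.identity / 100.0
        claimed = _merge_intervals(claimed + [(h.q_start, h.q_end)])
    return min(1.0, matched / lq)


def dereplicate(contigs: Sequence[Contig],
                cfg: PipelineConfig | None = None) -> List[DerepResult]:
    """Greedy longest-first clustering at 95% global identity.

    Contigs are visited by descending length (ties by id); each joins the
    first existing representative it matches at >= ``derep_identity`` over
    the shorter sequence, else founds a new cluster.  Deterministic.
    """
    cfg = cfg or PipelineConfig()
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in dereplication input")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    clusters: List[DerepResult] = []
    reps: List[Contig] = []
    for c in ordered:
        placed = False
        for rep, cl in zip(reps, clusters):
            ident = global_identity(c, rep)
            if ident >= cfg.derep_identity:
                cl.member_ids.append(c.id)
                cl.identity_to_rep[c.id] = 100.0 * ident
                placed = True
                break
        if not placed:
            clusters.append(DerepResult(c.id, [c.id], {c.id: 100.0}))
            reps.append(c)
    return clusters


# ---------------------------------------------------------------------------
# Assembly-source group attribution
# ---------------------------------------------------------------------------

LONG_SOURCES = {"long", "hybrid"}


def _covers_majority(votu: Contig, other: Contig, cfg: PipelineConfig) -> bool:
    """True when >=95%-identity regions of ``other`` cover >50% of the vOTU."""
    hsps = find_hsps(votu, other, min_identity=cfg.novelty_identical,
                     min_len=100)
    regions = merge_regions(hsps, cfg.novelty_identical, 100)
    return sum(b - a for a, b in regions) > 0.5 * votu.length


def assign_source_group(votu: Contig, all_contigs: Sequence[Contig],
                        cfg: PipelineConfig | None = None) -> str:
    """Attribute a vOTU to the long-read, short-read or both group.

    A long/hybrid-assembled representative is ``long_read`` unless some
    short-read contig anywhere in the workspace (cluster member or
    dereplication discard) shares >95% ANI over >50% of its length, in which
    case it is ``both``; symmetrically for short-read representatives.
    """
    cfg = cfg or PipelineConfig()
    for c in all_contigs:
        if c.assembly_source not in ("short", "long", "hybrid"):
            raise ValueError(f"unknown assembly source {c.assembly_source!r} "
                             f"for contig {c.id}")
    if votu.assembly_source in LONG_SOURCES:
        counterparts = [c for c in all_contigs
                        if c.assembly_source == "short" and c.id != votu.id]
        fallback = "long_read"
    elif votu.assembly_source == "short":
        counterparts = [c for c in all_contigs
                        if c.assembly_source in LONG_SOURCES and c.id != votu.id]
        fallback = "short_read"
    else:
        raise ValueError(f"unknown assembly source {votu.assembly_source!r}")
    for other in counterparts:
        if _covers_majority(votu, other, cfg):
            return "both"
    return fallback
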