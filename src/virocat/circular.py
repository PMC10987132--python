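"""Circular (complete) genome detection.

Assembling a circular phage genome linearly leaves the same sequence at
both contig ends; an exact terminal repeat of >=30 bp is taken as evidence
of circularity.  Independently, reads that map with >=50-bp segments to
both the front and the tail of a contig span the circular junction; two or
more such reads also call the genome circular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import pandas as pd

from .config import PipelineConfig
from .io import Contig


@dataclass
class CircularityCall:
    contig_id: str
    tr_detected: bool
    tr_length: int
    read_support_count: int
    is_circular: bool
    method: str     # terminal_repeat | read_support | both | none


def detect_terminal_repeat(seq: str, cfg: PipelineConfig | None = None):
    """Maximal exact terminal repeat of length >= ``tr_min_len``.

    Scans overlap lengths from the longest possible (half the sequence,
    so prefix and suffix cannot overlap) down to the minimum; the first
    exact match wins, giving the maximal repeat length.  A repeat containing
    N is rejected: N never matches.
    """
    cfg = cfg or PipelineConfig()
    seq = seq.upper()
    n = len(seq)
    for length in range(n // 2, cfg.tr_min_len - 1, -1):
        if seq[:length] == seq[-length:] and "N" not in seq[:length]:
            return True, length
    return False, 0


def read_support_circularity(contig_id: str, length: int,
                             placements: pd.DataFrame,
                             cfg: PipelineConfig | None = None) -> int:
    """Count junction-spanning reads for one contig.

    A read supports circularity when, on a single strand, it has one
    alignment segment of >= ``circ_min_hit`` bp ending within
    ``circ_end_window`` of the contig end and another of >= ``circ_min_hit``
    bp starting within ``circ_end_window`` of the contig start.
    """
    cfg = cfg or PipelineConfig()
    rows = placements[placements["contig_id"] == contig_id]
    count = 0
    for (_, strand), grp in rows.groupby(["read_id", "strand"], sort=True):
        starts = grp["start"].astype(int).to_numpy()
        ends = grp["end"].astype(int).to_numpy()
        seglen = ends - starts
        ok = seglen >= cfg.circ_min_hit
        at_tail = ok & (ends >= length - cfg.circ_end_window)
        at_front = ok & (starts <= cfg.circ_end_window)
        # two distinct segments are required: one at the tail, one at the front
        if any(at_tail[i] and at_front[j]
               for i in range(len(seglen)) for j in range(len(seglen))
               if i != j):
            count += 1
    return count


def call_circularity(contig: Contig, placements: pd.DataFrame | None,
                     cfg: PipelineConfig | None = None) -> CircularityCall:
    """Combine the terminal-repeat and read-support detectors."""
    cfg = cfg or PipelineConfig()
    tr, tr_len = detect_terminal_repeat(contig.sequence, cfg)
    support = 0
    if placements is not None and len(placements):
        support = read_support_circularity(contig.id, contig.length,
                                           placements, cfg)
    by_reads = support >= cfg.circ_min_reads
    if tr and by_reads:
        method = "both"
    elif tr:
        method = "terminal_repeat"
    elif by_reads:
        method = "read_support"
    else:
        method = "none"
    return CircularityCall(contig.id, tr, tr_len, support, tr or by_reads,
                           method)


def circularity_table(contigs: Iterable[Contig],
                      placements: pd.DataFrame | None,
                      cfg: PipelineConfig | None = None) -> pd.DataFrame:
    calls = [call_circularity(c, placements, cfg) for c in contigs]
    return pd.DataFrame(
        [{"contig_id": c.contig_id, "tr_detected": c.tr_detected,
          "tr_length": c.tr_length,
          "read_support_count": c.read_support_count,
          "is_circular": c.is_circular, "method": c.method} for c in calls],
        columns=["contig_id", "tr_detected", "tr_length",
                 "read_support_count", "is_circular", "method"])
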