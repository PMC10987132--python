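"""Virus-host assignment from CRISPR spacers and tRNA genes.

A spacer hit is a full-length exact substring match (either strand) of a
host-labelled spacer inside a viral genome; spacers shorter than 20 bp only
ever support low-confidence links.  A tRNA hit pairs a viral tRNA gene with
a bacterial one at >=95% identity over 100% of the viral gene length
(ungapped).  Evidence is aggregated per (virus, host species): links backed
by >=2 distinct spacers, >=2 tRNA genes, or >=1 of each are high
confidence; all others are low.  Multi-host viruses get a host range = the
rank of the last common ancestor of their hosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import PipelineConfig
from .homology import revcomp
from .io import Contig, Taxonomy


@dataclass
class SpacerMatch:
    spacer_id: str
    host_species_id: str
    virus_id: str
    position: int
    strand: str
    spacer_len: int
    short: bool        # below the confidence-eligible length


@dataclass
class TrnaMatch:
    viral_trna_id: str
    virus_id: str
    bacterial_trna_id: str
    host_species_id: str
    identity: float    # percent over the full viral gene


@dataclass
class HostEvidence:
    virus_id: str
    host_species_id: str
    n_spacer_matches: int       # distinct qualifying spacer sequences
    n_trna_matches: int         # distinct viral tRNA genes matched
    any_short_spacer_only: bool
    confidence: str             # high | low


@dataclass
class HostRange:
    virus_id: str
    lca_rank: str
    lca_node: str
    n_hosts: int


def match_spacers(spacers: Sequence[Tuple[str, str, str]],
                  votus: Sequence[Contig],
                  cfg: PipelineConfig | None = None,
                  max_mismatches: int = 0) -> List[SpacerMatch]:
    """Exact full-length spacer matching against vOTU sequences.

    ``spacers`` holds (spacer_id, host_species_id, sequence) tuples; both
    the spacer and its reverse complement are searched.  ``max_mismatches``
    of 1 enables a tolerant mode (off by default).
    """
    cfg = cfg or PipelineConfig()
    out: List[SpacerMatch] = []
    for spacer_id, host, seq in spacers:
        seq = seq.upper()
        if len(seq) < 10:
            raise ValueError(f"spacer {spacer_id} shorter than 10 bp")
        short = len(seq) < cfg.spacer_min_len
        for votu in votus:
            for strand, probe in (("+", seq), ("-", revcomp(seq))):
                for pos in _find_all(votu.sequence, probe, max_mismatches):
                    out.append(SpacerMatch(spacer_id, host, votu.id, pos,
                                           strand, len(seq), short))
    return out


def _find_all(haystack: str, needle: str, max_mismatches: int) -> List[int]:
    if max_mismatches == 0:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    hits = []
    n = len(needle)
    for pos in range(len(haystack) - n + 1):
        window = haystack[pos:pos + n]
        mm = sum(1 for x, y in zip(window, needle) if x != y or x == "N")
        if mm <= max_mismatches:
            hits.append(pos)
    return hits


def match_trnas(viral_trnas: Sequence[Tuple[str, str, str]],
                bacterial_trnas: Sequence[Tuple[str, str, str]],
                cfg: PipelineConfig | None = None) -> List[TrnaMatch]:
    """Pair viral and bacterial tRNA genes at >=95% identity over the full
    viral gene length.

    Inputs are (gene_id, owner_id, sequence) tuples — owner is the virus for
    viral genes and the host species for bacterial ones.  The comparison is
    an ungapped sliding scan on both strands: short gene lengths (70-90 bp)
    make seed-based search unreliable, and the 100%-length rule is exactly a
    windowed Hamming identity.
    """
    cfg = cfg or PipelineConfig()
    out: List[TrnaMatch] = []
    for v_id, virus, v_seq in viral_trnas:
        v_seq = v_seq.upper()
        if not 50 <= len(v_seq) <= 120:
            raise ValueError(f"viral tRNA {v_id} outside 50-120 bp")
        for b_id, host, b_seq in bacterial_trnas:
            ident = _best_window_identity(v_seq, b_seq.upper())
            if ident is not None and ident >= cfg.trna_identity:
                out.append(TrnaMatch(v_id, virus, b_id, host, ident))
    return out


def _best_window_identity(probe: str, target: str) -> Optional[float]:
    """Best percent identity of ``probe`` against any full-length window of
    ``target`` (both strands); None when the target is shorter."""
    n = len(probe)
    best = None
    for t in (target, revcomp(target)):
        for pos in range(len(t) - n + 1):
            window = t[pos:pos + n]
            m = sum(1 for x, y in zip(window, probe) if x == y and x != "N")
            ident = 100.0 * m / n
            if best is None or ident > best:
                best = ident
    return best


def assign_hosts(spacer_matches: Sequence[SpacerMatch],
                 trna_matches: Sequence[TrnaMatch],
                 spacer_seqs: Mapping[str, str] | None = None) -> List[HostEvidence]:
    """Aggregate evidence per (virus, host species) and tier the confidence.

    Distinctness is by spacer *sequence* (two placements of one spacer count
    once) and by viral tRNA gene id.  Only spacers of qualifying length
    count toward the confidence tier; short-spacer matches are reported but
    can never make a link high confidence.
    """
    spacer_seqs = spacer_seqs or {}
    pairs: Dict[Tuple[str, str], dict] = {}
    for m in spacer_matches:
        key = (m.virus_id, m.host_species_id)
        rec = pairs.setdefault(key, {"spacers": set(), "short": set(),
                                     "trnas": set()})
        token = spacer_seqs.get(m.spacer_id, m.spacer_id)
        (rec["short"] if m.short else rec["spacers"]).add(token)
    for t in trna_matches:
        key = (t.virus_id, t.host_species_id)
        rec = pairs.setdefault(key, {"spacers": set(), "short": set(),
                                     "trnas": set()})
        rec["trnas"].add(t.viral_trna_id)
    out = []
    for (virus, host), rec in sorted(pairs.items()):
        ns, nt = len(rec["spacers"]), len(rec["trnas"])
        high = ns >= 2 or nt >= 2 or (ns >= 1 and nt >= 1)
        out.append(HostEvidence(
            virus_id=virus, host_species_id=host,
            n_spacer_matches=ns, n_trna_matches=nt,
            any_short_spacer_only=bool(rec["short"]) and ns == 0 and nt == 0,
            confidence="high" if high else "low"))
    return out


def host_range(evidence: Sequence[HostEvidence], taxonomy: Taxonomy,
               high_only: bool = True) -> List[HostRange]:
    """LCA host range per virus over its (optionally high-confidence) hosts."""
    by_virus: Dict[str, Set[str]] = {}
    for ev in evidence:
        if high_only and ev.confidence != "high":
            continue
        by_virus.setdefault(ev.virus_id, set()).add(ev.host_species_id)
    out = []
    for virus, hosts in sorted(by_virus.items()):
        lca = taxonomy.lca(sorted(hosts))
        out.append(HostRange(virus, taxonomy.rank[lca], lca, len(hosts)))
    return out


def export_network(vc_members: Mapping[str, Sequence[str]],
                   evidence: Sequence[HostEvidence], taxonomy: Taxonomy,
                   lifestyle: Mapping[str, str] | None = None):
    """VC-to-host-genus interaction edges from high-confidence evidence.

    Returns (edges, vc_attrs, host_attrs) DataFrames: edges are
    deduplicated (vc_id, host_genus) pairs; VC attributes carry the
    majority lifestyle of linked members, host attributes the genus phylum.
    """
    member_to_vc = {m: vc for vc, members in vc_members.items()
                    for m in members}
    lifestyle = lifestyle or {}
    edge_set: Set[Tuple[str, str]] = set()
    genus_seen: Set[str] = set()
    vc_styles: Dict[str, List[str]] = {}
    for ev in evidence:
        if ev.confidence != "high":
            continue
        vc = member_to_vc.get(ev.virus_id)
        if vc is None:
            continue
        genus = taxonomy.ancestor_at_rank(ev.host_species_id, "genus")
        if genus is None:
            continue
        edge_set.add((vc, genus))
        genus_seen.add(genus)
        if ev.virus_id in lifestyle:
            vc_styles.setdefault(vc, []).append(lifestyle[ev.virus_id])
    edges = pd.DataFrame(sorted(edge_set), columns=["vc_id", "host_genus"])
    vc_attrs = pd.DataFrame(
        [{"vc_id": vc,
          "majority_lifestyle": max(sorted(set(styles)), key=styles.count)}
         for vc, styles in sorted(vc_styles.items())],
        columns=["vc_id", "majority_lifestyle"])
    host_attrs = pd.DataFrame(
        [{"host_genus": g,
          "phylum": taxonomy.ancestor_at_rank(g, "phylum") or ""}
         for g in sorted(genus_seen)],
        columns=["host_genus", "phylum"])
    return edges, vc_attrs, host_attrs
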