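"""Viral-cluster (VC) construction: filtered genome-homology graph + MCL.

Edges join genome pairs whose merged >=90%-identity alignment regions cover
more than 70% of the larger and more than 90% of the smaller genome; the
resulting unweighted graph is clustered with a from-scratch Markov
clustering (MCL) at inflation 4.0.  VC labels are assigned by descending
cluster size (VC_1 is the largest).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .homology import find_hsps, merge_regions, _merge_intervals
from .io import Contig, log


@dataclass
class HomologyEdge:
    a_id: str
    b_id: str
    cov_on_larger: float    # percent
    cov_on_smaller: float   # percent
    passes: bool


@dataclass
class ViralCluster:
    vc_id: str
    member_ids: List[str]
    size: int
    is_singleton: bool


def pair_coverage(a: Contig, b: Contig,
                  cfg: PipelineConfig | None = None) -> Tuple[float, float]:
    """Merged >=90%-identity coverage of each genome in a pair (percent).

    Returns (coverage on larger, coverage on smaller).
    """
    cfg = cfg or PipelineConfig()
    hsps = find_hsps(a, b, min_identity=cfg.vc_hsp_identity, min_len=15)
    cov_a = sum(e - s for s, e in
                merge_regions(hsps, cfg.vc_hsp_identity, 1)) / a.length
    s_ivals = [(h.s_start, h.s_end) for h in hsps
               if h.identity >= cfg.vc_hsp_identity]
    cov_b = sum(e - s for s, e in _merge_intervals(s_ivals)) / b.length
    if a.length >= b.length:
        return 100.0 * cov_a, 100.0 * cov_b
    return 100.0 * cov_b, 100.0 * cov_a


def build_graph(votus: Sequence[Contig],
                cfg: PipelineConfig | None = None) -> List[HomologyEdge]:
    """All-vs-all homology edges over the vOTUs (each unordered pair once)."""
    cfg = cfg or PipelineConfig()
    if not votus:
        raise ValueError("build_graph requires at least one vOTU")
    ordered = sorted(votus, key=lambda c: c.id)
    edges: List[HomologyEdge] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            cov_l, cov_s = pair_coverage(a, b, cfg)
            passes = cov_l > cfg.vc_cov_large and cov_s > cfg.vc_cov_small
            if cov_l > 0 or cov_s > 0:
                edges.append(HomologyEdge(a.id, b.id, cov_l, cov_s, passes))
    return edges


def mcl(node_ids: Sequence[str], edges: Sequence[HomologyEdge] | Sequence[Tuple[str, str]],
        inflation: float = 4.0, *, prune: float = 1e-6, tol: float = 1e-8,
        max_iter: int = 200) -> List[List[str]]:
    """Markov clustering of an undirected unit-weight graph with self-loops.

    Column-normalise the adjacency-plus-identity matrix, then alternate
    expansion (matrix square) and inflation (entrywise power + renormalise)
    with pruning of entries below ``prune``, until the matrix changes by
    less than ``tol`` or ``max_iter`` iterations.  Clusters are read off as
    connected components of the limit matrix's support; every node lands in
    exactly one cluster.
    """
    if inflation <= 1:
        raise ValueError("MCL inflation must exceed 1")
    nodes = sorted(dict.fromkeys(node_ids))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    m = np.eye(n)
    for e in edges:
        a, b = (e.a_id, e.b_id) if isinstance(e, HomologyEdge) else e
        if isinstance(e, HomologyEdge) and not e.passes:
            continue
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = 1.0
    m /= m.sum(axis=0, keepdims=True)
    for it in range(max_iter):
        prev = m
        m = m @ m                                   # expansion
        m = np.power(m, inflation)                  # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            break
    else:
        log.warning("MCL did not converge in %d iterations; interpreting "
                    "current state", max_iter)
    # connected components of the support give the clusters
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(m > prune)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(nodes[i] for i in comp)
             for comp in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def rank_and_label(memberships: Sequence[Sequence[str]]) -> List[ViralCluster]:
    """VC_k labels by descending size (ties by smallest member id)."""
    ordered = sorted((sorted(m) for m in memberships),
                     key=lambda c: (-len(c), c[0]))
    return [ViralCluster(f"VC_{k}", list(m), len(m), len(m) == 1)
            for k, m in enumerate(ordered, 1)]


def cluster_votus(votus: Sequence[Contig],
                  cfg: PipelineConfig | None = None) -> List[ViralCluster]:
    cfg = cfg or PipelineConfig()
    edges = build_graph(votus, cfg)
    comps = mcl([c.id for c in votus], edges, inflation=cfg.mcl_inflation)
    return rank_and_label(comps)


def co_cluster_with_references(votus: Sequence[Contig],
                               references: Mapping[str, str],
                               ref_contigs: Sequence[Contig],
                               cfg: PipelineConfig | None = None) -> Dict[str, str]:
    """Label vOTUs that share an MCL cluster with a labelled reference genome.

    ``references`` maps reference contig id -> clade label (e.g. Gubaphage).
    Returns vOTU id -> label for labelled vOTUs only.
    """
    cfg = cfg or PipelineConfig()
    union = list(votus) + [c for c in ref_contigs if c.id in references]
    clusters = cluster_votus(union, cfg)
    votu_ids = {c.id for c in votus}
    labels: Dict[str, str] = {}
    for cl in clusters:
        ref_labels = sorted({references[m] for m in cl.member_ids
                             if m in references})
        if not ref_labels:
            continue
        for m in cl.member_ids:
            if m in votu_ids:
                labels[m] = ref_labels[0]
    return labels


def clusters_table(clusters: Sequence[ViralCluster]) -> pd.DataFrame:
    rows = [{"vc_id": cl.vc_id, "member_id": m, "size": cl.size,
             "is_singleton": cl.is_singleton}
            for cl in clusters for m in cl.member_ids]
    return pd.DataFrame(rows, columns=["vc_id", "member_id", "size",
                                       "is_singleton"])
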