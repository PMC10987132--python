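"""Spacer/tRNA matching, confidence tiers, LCA host range, network export."""

import pytest

from virocat.config import PipelineConfig
from virocat.hosts import (SpacerMatch, TrnaMatch, assign_hosts, export_network,
                           host_range, match_spacers, match_trnas)
from virocat.io import Contig, Taxonomy
from virocat.homology import revcomp
from virocat.simulate import gen_genome, mutate

from conftest import random_seq

CFG = PipelineConfig()


def toy_taxonomy():
    parent = {"D": "", "P1": "D", "P2": "D", "G1": "P1", "G2": "P1",
              "G3": "P2", "S1": "G1", "S2": "G1", "S3": "G2", "S4": "G3"}
    rank = {"D": "domain", "P1": "phylum", "P2": "phylum", "G1": "genus",
            "G2": "genus", "G3": "genus", "S1": "species", "S2": "species",
            "S3": "species", "S4": "species"}
    return Taxonomy(parent=parent, rank=rank,
                    name={k: k for k in parent})


class TestSpacerMatching:
    def test_planted_spacer_found_once(self):
        votu = gen_genome(3000, 0.5, 1, id="v")
        spacer = votu.sequence[500:532]
        [m] = match_spacers([("sp1", "S1", spacer)], [votu], CFG)
        assert (m.position, m.strand, m.short) == (500, "+", False)

    def test_reverse_complement_matched(self):
        votu = gen_genome(3000, 0.5, 2, id="v")
        spacer = revcomp(votu.sequence[100:135])
        [m] = match_spacers([("sp1", "S1", spacer)], [votu], CFG)
        assert m.strand == "-"

    def test_short_spacer_flagged(self):
        votu = gen_genome(3000, 0.5, 3, id="v")
        spacer = votu.sequence[50:68]          # 18 bp < 20
        [m] = match_spacers([("sp1", "S1", spacer)], [votu], CFG)
        assert m.short

    def test_random_spacers_never_match(self):
        votu = gen_genome(5000, 0.5, 4, id="v")
        spacers = [(f"sp{i}", "S1", random_seq(30, 100 + i))
                   for i in range(20)]
        assert match_spacers(spacers, [votu], CFG) == []

    def test_sub_10bp_spacer_rejected(self):
        with pytest.raises(ValueError):
            match_spacers([("sp", "S1", "ACGTACG")],
                          [gen_genome(1000, 0.5, 5)], CFG)


class TestTrnaMatching:
    def test_identical_genes_match(self):
        gene = random_seq(75, 1)
        [m] = match_trnas([("vt1", "v", gene)], [("bt1", "S1", gene)], CFG)
        assert m.identity == 100.0

    def test_90_percent_identity_rejected(self):
        gene = random_seq(80, 2)
        diverged = mutate(Contig("g", gene), 0.10, 3).sequence
        assert match_trnas([("vt1", "v", gene)], [("bt1", "S1", diverged)],
                           CFG) == []

    def test_partial_length_alignment_rejected(self):
        gene = random_seq(80, 4)
        truncated = gene[:72]     # bacterial gene shorter than viral gene
        assert match_trnas([("vt1", "v", gene)], [("bt1", "S1", truncated)],
                           CFG) == []

    def test_gene_embedded_in_longer_target_matches(self):
        gene = random_seq(78, 5)
        target = random_seq(20, 6) + gene + random_seq(20, 7)
        [m] = match_trnas([("vt1", "v", gene)], [("bt1", "S1", target)], CFG)
        assert m.identity == 100.0


class TestConfidenceTiers:
    def _sp(self, sid, short=False):
        return SpacerMatch(sid, "S1", "v", 0, "+", 18 if short else 32, short)

    def _tr(self, tid):
        return TrnaMatch(tid, "v", f"b_{tid}", "S1", 100.0)

    def test_two_spacers_high(self):
        [ev] = assign_hosts([self._sp("a"), self._sp("b")], [])
        assert ev.confidence == "high" and ev.n_spacer_matches == 2

    def test_two_trnas_high(self):
        [ev] = assign_hosts([], [self._tr("t1"), self._tr("t2")])
        assert ev.confidence == "high"

    def test_one_of_each_high(self):
        [ev] = assign_hosts([self._sp("a")], [self._tr("t1")])
        assert ev.confidence == "high"

    def test_single_spacer_low(self):
        [ev] = assign_hosts([self._sp("a")], [])
        assert ev.confidence == "low"

    def test_short_spacer_never_high(self):
        [ev] = assign_hosts([self._sp("a", short=True),
                             self._sp("b", short=True)], [])
        assert ev.confidence == "low" and ev.any_short_spacer_only

    def test_duplicate_placements_of_same_spacer_count_once(self):
        m1 = SpacerMatch("sp", "S1", "v", 10, "+", 32, False)
        m2 = SpacerMatch("sp", "S1", "v", 500, "-", 32, False)
        [ev] = assign_hosts([m1, m2], [], {"sp": "ACGT" * 8})
        assert ev.n_spacer_matches == 1 and ev.confidence == "low"


class TestHostRange:
    def _ev(self, host, conf="high"):
        from virocat.hosts import HostEvidence

        return HostEvidence("v", host, 2, 0, False, conf)

    def test_single_species(self):
        tax = toy_taxonomy()
        [hr] = host_range([self._ev("S1")], tax)
        assert (hr.lca_rank, hr.lca_node, hr.n_hosts) == ("species", "S1", 1)

    def test_same_genus(self):
        [hr] = host_range([self._ev("S1"), self._ev("S2")], toy_taxonomy())
        assert (hr.lca_rank, hr.lca_node) == ("genus", "G1")

    def test_cross_phylum_lca_is_root(self):
        [hr] = host_range([self._ev("S1"), self._ev("S4")], toy_taxonomy())
        assert (hr.lca_rank, hr.lca_node) == ("domain", "D")

    def test_permutation_and_duplication_invariance(self):
        tax = toy_taxonomy()
        a = host_range([self._ev("S1"), self._ev("S3")], tax)
        b = host_range([self._ev("S3"), self._ev("S1"), self._ev("S1")], tax)
        assert a == b

    def test_low_confidence_excluded_by_default(self):
        assert host_range([self._ev("S1", "low")], toy_taxonomy()) == []

    def test_unknown_host_rejected(self):
        with pytest.raises(Exception, match="ghost"):
            host_range([self._ev("ghost")], toy_taxonomy())


class TestNetworkExport:
    def test_genus_dedup_and_low_confidence_exclusion(self):
        from virocat.hosts import HostEvidence

        tax = toy_taxonomy()
        evidence = [HostEvidence("v1", "S1", 2, 0, False, "high"),
                    HostEvidence("v1", "S2", 2, 0, False, "high"),
                    HostEvidence("v2", "S4", 1, 0, False, "low")]
        edges, vc_attrs, host_attrs = export_network(
            {"VC_1": ["v1", "v2"]}, evidence, tax, {"v1": "virulent"})
        assert edges.values.tolist() == [["VC_1", "G1"]]
        assert host_attrs.iloc[0]["phylum"] == "P1"
        assert vc_attrs.iloc[0]["majority_lifestyle"] == "virulent"

    def test_no_high_confidence_gives_empty_edges(self):
        from virocat.hosts import HostEvidence

        edges, _, _ = export_network(
            {"VC_1": ["v1"]},
            [HostEvidence("v1", "S1", 1, 0, False, "low")],
            toy_taxonomy(), {})
        assert len(edges) == 0
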