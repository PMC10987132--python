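"""Generator contracts: determinism, analytic divergence, planted structure."""

import numpy as np
import pandas as pd
import pytest

from virocat.config import PipelineConfig
from virocat.io import Contig
from virocat.simulate import (gen_community, gen_evidence, gen_genome,
                              gen_hosts, gen_taxonomy, make_circular,
                              make_mosaic, mutate)


class TestGenGenome:
    def test_deterministic_for_fixed_seed(self):
        a = gen_genome(1000, 0.5, 7)
        b = gen_genome(1000, 0.5, 7)
        assert a.sequence == b.sequence and a.length == 1000

    def test_gc_content_within_binomial_bound(self):
        # 100 kb at GC 0.2: 3 sigma ~ 0.0038, well inside +-0.01
        g = gen_genome(100_000, 0.2, 3)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert abs(gc - 0.2) < 0.01

    @pytest.mark.parametrize("length,gc", [(50, 0.5), (1000, 0.0), (1000, 1.0)])
    def test_invalid_arguments_rejected(self, length, gc):
        with pytest.raises(ValueError):
            gen_genome(length, gc, 1)


class TestMutate:
    def test_zero_divergence_is_identity(self):
        g = gen_genome(5000, 0.5, 1)
        assert mutate(g, 0.0, 2).sequence == g.sequence

    def test_mismatch_count_within_3_sigma(self):
        # 10 kb at 5%: expect 500 +- 3*sqrt(10000*0.05*0.95) ~ 500 +- 65
        g = gen_genome(10_000, 0.5, 1)
        m = mutate(g, 0.05, 2)
        mm = sum(1 for a, b in zip(g.sequence, m.sequence) if a != b)
        assert abs(mm - 500) <= 70

    def test_substitutions_never_keep_the_base(self):
        g = gen_genome(2000, 0.5, 5)
        m = mutate(g, 0.5, 6)
        assert m.length == g.length
        mm = sum(1 for a, b in zip(g.sequence, m.sequence) if a != b)
        assert 800 < mm < 1200  # every hit changed the base


class TestMakeCircular:
    def test_terminal_copy_construction(self):
        g = gen_genome(1000, 0.5, 1)
        c = make_circular(g, 40)
        assert c.length == 1040
        assert c.sequence[:40] == c.sequence[-40:]

    def test_tr_len_bounds(self):
        g = gen_genome(200, 0.5, 1)
        with pytest.raises(ValueError):
            make_circular(g, 0)
        with pytest.raises(ValueError):
            make_circular(g, 200)


class TestMakeMosaic:
    def test_shared_block_position_and_length_preserved(self):
        donor = gen_genome(4000, 0.5, 1, id="d")
        bg = gen_genome(4000, 0.5, 2)
        mz = make_mosaic(donor, bg, 0.75, 3)
        assert mz.length == donor.length

    def test_expected_ani_monotone_in_shared_fraction(self):
        from virocat.homology import compute_ani

        donor = gen_genome(6000, 0.5, 1, id="d")
        bg = gen_genome(6000, 0.5, 2)
        anis = [compute_ani(make_mosaic(donor, bg, f, 3), donor).ani
                for f in (0.3, 0.6, 0.9)]
        assert anis[0] < anis[1] < anis[2]


class TestGenEvidence:
    def _genomes(self, n=10):
        return [gen_genome(8000, 0.5, 100 + i, id=f"g{i}") for i in range(n)]

    def test_noise_zero_viruses_meet_two_criteria(self, cfg):
        from virocat.identify import evaluate_criteria, evidence_from_row

        genomes = self._genomes()
        viral = {g.id: i < 5 for i, g in enumerate(genomes)}
        ev = gen_evidence(genomes, viral, 0.0, 9, cfg)
        for _, row in ev.iterrows():
            crit = evaluate_criteria(evidence_from_row(row), 8000, cfg)
            if viral[row["contig_id"]]:
                assert len(crit) >= 2
            else:
                assert len(crit) == 0

    def test_hq_rescue_path_planted(self, cfg):
        from virocat.identify import (call_virus, evaluate_criteria,
                                      evidence_from_row)

        genomes = self._genomes(4)
        viral = {g.id: True for g in genomes}
        ev = gen_evidence(genomes, viral, 0.0, 9, cfg,
                          hq_rescue_ids=[genomes[0].id])
        row = ev[ev["contig_id"] == genomes[0].id].iloc[0]
        rec = evidence_from_row(row)
        crit = evaluate_criteria(rec, 8000, cfg)
        assert len(crit) == 1
        assert call_virus(crit, False, rec, cfg)

    def test_deterministic(self, cfg):
        genomes = self._genomes(5)
        viral = {g.id: True for g in genomes}
        a = gen_evidence(genomes, viral, 0.1, 3, cfg)
        b = gen_evidence(genomes, viral, 0.1, 3, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGenCommunity:
    def test_read_conservation_and_presence_margins(self, cfg):
        from virocat.quantify import is_present, summarize_coverage
        from virocat.simulate import SimulationTruth

        genomes = [gen_genome(6000, 0.5, 200 + i, id=f"g{i}")
                   for i in range(8)]
        truths = {g.id: SimulationTruth(g.id, True, False, "", "", 0.0,
                                        "novel", 0.5) for g in genomes}
        pl = gen_community(genomes, 3, 42, truths, cfg=cfg)
        # per-sample totals equal the sum of per-contig read counts
        per_sample = pl.groupby("sample_id")["read_id"].nunique()
        split = pl.groupby(["sample_id", "contig_id"])["read_id"].nunique()
        for s in per_sample.index:
            assert per_sample[s] == split[s].sum()
        # planted presence is recovered by the presence rule
        lengths = {g.id: g.length for g in genomes}
        for cs in summarize_coverage(pl, lengths):
            assert is_present(cs, cfg) == truths[cs.contig_id].present_in[cs.sample_id]

    def test_junction_reads_for_circular_genomes(self, cfg):
        from virocat.circular import read_support_circularity
        from virocat.simulate import SimulationTruth

        g = make_circular(gen_genome(5000, 0.5, 7, id="c0"), 50, id="c0")
        truths = {"c0": SimulationTruth("c0", True, True, "", "", 0.0,
                                        "novel", 0.5)}
        pl = gen_community([g], 2, 13, truths, circular_ids=["c0"],
                           cfg=cfg, present_prob=1.0)
        for s, grp in pl.groupby("sample_id"):
            assert read_support_circularity("c0", g.length, grp, cfg) >= 2


class TestGenHosts:
    def test_taxonomy_is_balanced_with_seven_ranks(self):
        df = gen_taxonomy(10)
        assert set(df["rank"]) == {"domain", "phylum", "class", "order",
                                   "family", "genus", "species"}
        assert (df["parent_id"] == "").sum() == 1

    def test_planted_patterns_cover_all_confidence_tiers(self, cfg):
        viruses = [gen_genome(4000, 0.5, 300 + i, id=f"v{i}")
                   for i in range(5)]
        _, spacers, vtr, btr, _, links = gen_hosts(viruses, 6, 99, cfg)
        assert list(links["expected_confidence"]) == \
               ["high", "high", "high", "low", "low"]
        assert any(len(seq) < cfg.spacer_min_len for _, _, seq in spacers)
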