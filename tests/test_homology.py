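"""The HSP engine against a gapped Smith-Waterman oracle, merged-region
ANI, dereplication and assembly-source attribution."""

import numpy as np
import pytest

from virocat.config import PipelineConfig
from virocat.homology import (Hsp, classify_novelty, compute_ani, dereplicate,
                              find_hsps, global_identity, merge_regions,
                              novelty_vs_catalogues, assign_source_group,
                              revcomp)
from virocat.io import Contig
from virocat.simulate import gen_genome, make_mosaic, mutate

from conftest import plant_region, random_seq, sw_oracle_region

CFG = PipelineConfig()


class TestFindHsps:
    def test_identical_sequences_single_full_hsp(self):
        seq = random_seq(600, 1)
        hsps = find_hsps(Contig("a", seq), Contig("b", seq), 95, 500)
        assert len(hsps) == 1
        h = hsps[0]
        assert (h.q_start, h.q_end, h.identity, h.aligned_len) == (0, 600, 100.0, 600)

    def test_reverse_complement_match_reported_on_forward_coords(self):
        seq = random_seq(600, 2)
        hsps = find_hsps(Contig("a", seq), Contig("b", revcomp(seq)), 95, 500)
        assert len(hsps) == 1
        assert hsps[0].strand == "-"
        assert (hsps[0].s_start, hsps[0].s_end) == (0, 600)

    def test_planted_region_recovered_vs_oracle(self):
        q = random_seq(300, 10)
        s = plant_region(random_seq(300, 11), q, 80, 150, 3, 12)
        oracle = sw_oracle_region(q, s, 95.0, 100)
        assert oracle is not None
        hsps = find_hsps(Contig("q", q), Contig("s", s), 95.0, 100)
        assert len(hsps) >= 1
        assert abs(hsps[0].q_start - oracle[0]) <= 5
        assert abs(hsps[0].q_end - oracle[1]) <= 5

    def test_unrelated_sequences_no_hsp(self):
        q, s = random_seq(1000, 20), random_seq(1000, 21)
        assert sw_oracle_region(q, s, 95.0, 500) is None
        assert find_hsps(Contig("q", q), Contig("s", s), 95.0, 500) == []

    def test_oracle_agreement_over_many_planted_pairs(self):
        """Engine and Smith-Waterman agree on 25 planted / 10 empty pairs."""
        rng = np.random.default_rng(77)
        for trial in range(25):
            L = int(rng.integers(200, 301))
            reg = int(rng.integers(100, min(180, L - 20)))
            start = int(rng.integers(0, L - reg))
            q = random_seq(L, 1000 + trial)
            s = plant_region(random_seq(L, 2000 + trial), q, start, reg,
                             max(1, reg // 60), 3000 + trial)
            oracle = sw_oracle_region(q, s, 95.0, 100)
            hsps = find_hsps(Contig("q", q), Contig("s", s), 95.0, 100)
            if oracle is None:
                assert hsps == []
            else:
                assert hsps, f"trial {trial}: oracle region {oracle} missed"
                assert abs(hsps[0].q_start - oracle[0]) <= 5
                assert abs(hsps[0].q_end - oracle[1]) <= 5
        for trial in range(10):
            q = random_seq(300, 5000 + trial)
            s = random_seq(300, 6000 + trial)
            assert sw_oracle_region(q, s, 95.0, 100) is None
            assert find_hsps(Contig("q", q), Contig("s", s), 95.0, 100) == []


class TestMergeRegions:
    def _hsp(self, q0, q1, ident=99.0):
        return Hsp("q", "s", q0, q1, q0, q1, ident, q1 - q0, "+", q1 - q0)

    def test_overlapping_passing_hsps_union(self):
        got = merge_regions([self._hsp(100, 700), self._hsp(600, 1200)],
                            95, 500)
        assert got == [(100, 1200)]

    def test_short_hit_filtered(self):
        assert merge_regions([self._hsp(0, 400)], 95, 500) == []

    def test_low_identity_filtered_and_empty_ok(self):
        assert merge_regions([self._hsp(0, 600, 90.0)], 95, 500) == []
        assert merge_regions([], 95, 500) == []

    def test_mixed_query_rejected(self):
        other = Hsp("q2", "s", 0, 600, 0, 600, 99, 600, "+", 600)
        with pytest.raises(ValueError):
            merge_regions([self._hsp(0, 600), other], 95, 500)


class TestAni:
    def test_self_ani_is_100_identical(self):
        g = gen_genome(3000, 0.5, 5, id="g")
        r = compute_ani(g, g, CFG)
        assert r.ani == 100.0 and r.novelty_class == "identical"

    def test_mosaic_lands_in_partial_band(self):
        donor = gen_genome(8000, 0.5, 1, id="d")
        mz = make_mosaic(donor, gen_genome(8000, 0.5, 2), 0.75, 3, id="m")
        r = compute_ani(mz, donor, CFG)
        assert 70 <= r.ani < 95 and r.novelty_class == "partial"

    def test_unrelated_pair_novel(self):
        a, b = gen_genome(3000, 0.5, 7, id="a"), gen_genome(3000, 0.5, 8, id="b")
        r = compute_ani(a, b, CFG)
        assert r.ani < 5 and r.novelty_class == "novel"

    @pytest.mark.parametrize("ani,expected", [
        (95.0, "identical"), (94.999, "partial"), (70.0, "partial"),
        (69.999, "novel"), (0.0, "novel"), (100.0, "identical")])
    def test_class_boundaries_exact(self, ani, expected):
        assert classify_novelty(ani, CFG) == expected

    def test_removing_an_hsp_never_increases_ani(self):
        donor = gen_genome(6000, 0.5, 1, id="d")
        mz = make_mosaic(donor, gen_genome(6000, 0.5, 2), 0.6, 3, id="m")
        hsps = find_hsps(mz, donor, CFG.novelty_hsp_identity,
                         CFG.novelty_hsp_minlen)
        full = sum(b - a for a, b in merge_regions(
            hsps, CFG.novelty_hsp_identity, CFG.novelty_hsp_minlen))
        for drop in range(len(hsps)):
            subset = hsps[:drop] + hsps[drop + 1:]
            part = sum(b - a for a, b in merge_regions(
                subset, CFG.novelty_hsp_identity, CFG.novelty_hsp_minlen))
            assert part <= full


class TestNoveltyVsCatalogues:
    def test_best_reference_decides_class(self):
        votu = gen_genome(6000, 0.5, 1, id="v")
        refs = {"cat": [
            Contig("r_novel", gen_genome(6000, 0.5, 2).sequence),
            Contig("r_partial", make_mosaic(votu, gen_genome(6000, 0.5, 3),
                                            0.72, 4).sequence)]}
        df = novelty_vs_catalogues([votu], refs, CFG)
        assert df.iloc[0]["class"] == "partial"
        assert df.iloc[0]["best_reference"] == "r_partial"

    def test_verbatim_copy_identical(self):
        votu = gen_genome(4000, 0.5, 9, id="v")
        df = novelty_vs_catalogues(
            [votu], {"cat": [Contig("copy", votu.sequence)]}, CFG)
        assert df.iloc[0]["class"] == "identical"

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            novelty_vs_catalogues([gen_genome(1000, 0.5, 1)], {}, CFG)


class TestDereplication:
    def test_two_percent_mutant_joins_cluster_with_edlib_crosscheck(self):
        g = gen_genome(8000, 0.5, 1, id="g")
        m = mutate(g, 0.02, 2, id="g_m")
        ours = global_identity(g, m)
        import edlib
        dist = edlib.align(g.sequence, m.sequence, task="distance")["editDistance"]
        independent = 1 - dist / g.length
        assert abs(ours - independent) < 0.005
        clusters = dereplicate([g, m], CFG)
        assert len(clusters) == 1
        assert clusters[0].representative_id in ("g", "g_m")

    def test_fifteen_percent_mutant_separates(self):
        g = gen_genome(8000, 0.5, 3, id="g")
        m = mutate(g, 0.15, 4, id="g_m")
        assert len(dereplicate([g, m], CFG)) == 2

    def test_single_genome_is_its_own_representative(self):
        g = gen_genome(6000, 0.5, 5, id="solo")
        [cl] = dereplicate([g], CFG)
        assert cl.representative_id == "solo" and cl.member_ids == ["solo"]

    def test_longest_member_is_representative(self):
        g = gen_genome(8000, 0.5, 6, id="zzz_long")
        m = mutate(g, 0.02, 7, id="aaa_short")
        m = Contig(m.id, m.sequence[:7000])
        [cl] = dereplicate([g, m], CFG)
        assert cl.representative_id == "zzz_long"


class TestSourceGroup:
    def _mk(self, id, seed, source, length=7000):
        c = gen_genome(length, 0.5, seed, id=id)
        c.assembly_source = source
        return c

    def test_hybrid_without_short_match_is_long_read(self):
        rep = self._mk("rep", 1, "hybrid")
        other = self._mk("other", 2, "short")
        assert assign_source_group(rep, [rep, other], CFG) == "long_read"

    def test_long_with_short_read_twin_is_both(self):
        rep = self._mk("rep", 3, "long")
        twin = mutate(rep, 0.02, 4, id="twin")
        twin.assembly_source = "short"
        assert assign_source_group(rep, [rep, twin], CFG) == "both"

    def test_short_without_long_data_is_short_read(self):
        rep = self._mk("rep", 5, "short")
        assert assign_source_group(rep, [rep], CFG) == "short_read"

    def test_unknown_source_rejected(self):
        rep = self._mk("rep", 6, "nanopore")
        with pytest.raises(ValueError):
            assign_source_group(rep, [rep], CFG)
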