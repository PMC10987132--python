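"""Closed-form checks for presence, abundance, diversity and rarefaction."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.stats import entropy as scipy_entropy

from virocat.config import PipelineConfig
from virocat.quantify import (CoverageSummary, abundance_tables, bray_curtis,
                              is_present, prevalence, rarefaction,
                              relative_abundance, rpkm, shannon,
                              summarize_coverage, vc_abundance)

CFG = PipelineConfig()


def cs(breadth, depth, sample="s1", contig="c1", reads=10):
    return CoverageSummary(sample, contig, breadth, depth, reads)


def placements(rows):
    return pd.DataFrame(rows, columns=["sample_id", "read_id", "contig_id",
                                       "start", "end", "strand"])


class TestCoverage:
    def test_half_genome_single_read(self):
        pl = placements([("s1", "r1", "c1", 0, 500, "+")])
        [out] = summarize_coverage(pl, {"c1": 1000})
        assert out.breadth == 0.5 and out.mean_depth == 0.5
        assert out.mapped_reads == 1

    def test_no_reads_all_zero(self):
        assert summarize_coverage(placements([]), {"c1": 1000}) == []

    def test_two_stacked_full_reads(self):
        pl = placements([("s1", "r1", "c1", 0, 1000, "+"),
                         ("s1", "r2", "c1", 0, 1000, "+")])
        [out] = summarize_coverage(pl, {"c1": 1000})
        assert out.breadth == 1.0 and out.mean_depth == 2.0

    def test_out_of_bounds_placement_rejected(self):
        pl = placements([("s1", "r1", "c1", 500, 1500, "+")])
        with pytest.raises(ValueError):
            summarize_coverage(pl, {"c1": 1000})


class TestPresence:
    @pytest.mark.parametrize("breadth,depth,expected", [
        (0.6, 5.0, True),     # both pass
        (0.9, 3.9, False),    # depth fails
        (0.4, 100.0, False),  # breadth fails
        (0.5, 5.0, False),    # breadth boundary is strict
        (0.6, 4.0, False),    # depth boundary is strict
    ])
    def test_threshold_quadrants(self, breadth, depth, expected):
        assert is_present(cs(breadth, depth), CFG) is expected


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(1000, 10_000, 1_000_000) == pytest.approx(100.0, abs=1e-9)

    def test_zero_reads(self):
        assert rpkm(0, 10_000, 1_000_000) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)

    def test_relative_abundance_scale_invariant(self):
        r1 = pd.DataFrame([[100.0, 300.0]], index=["s"], columns=["a", "b"])
        pres = pd.DataFrame([[True, True]], index=["s"], columns=["a", "b"])
        doubled = relative_abundance(2 * r1, pres)
        pd.testing.assert_frame_equal(relative_abundance(r1, pres), doubled)


class TestRelativeAbundance:
    def test_two_present_votus(self):
        r = pd.DataFrame([[100.0, 300.0]], index=["s"], columns=["a", "b"])
        pres = pd.DataFrame([[True, True]], index=["s"], columns=["a", "b"])
        rel = relative_abundance(r, pres)
        assert rel.loc["s", "a"] == pytest.approx(0.25, abs=1e-12)
        assert rel.loc["s", "b"] == pytest.approx(0.75, abs=1e-12)

    def test_absent_votu_zeroed_before_normalisation(self):
        r = pd.DataFrame([[900.0, 100.0]], index=["s"], columns=["a", "b"])
        pres = pd.DataFrame([[False, True]], index=["s"], columns=["a", "b"])
        rel = relative_abundance(r, pres)
        assert rel.loc["s", "a"] == 0.0
        assert rel.loc["s", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_no_present_votus_zero_row(self):
        r = pd.DataFrame([[5.0, 3.0]], index=["s"], columns=["a", "b"])
        pres = pd.DataFrame([[False, False]], index=["s"], columns=["a", "b"])
        assert relative_abundance(r, pres).sum(axis=1).iloc[0] == 0.0

    def test_rows_sum_to_one_within_tolerance(self):
        rng = np.random.default_rng(3)
        r = pd.DataFrame(rng.uniform(0, 10, (4, 6)),
                         columns=[f"c{i}" for i in range(6)])
        pres = pd.DataFrame(rng.random((4, 6)) > 0.3, columns=r.columns)
        rel = relative_abundance(r, pres)
        sums = rel.sum(axis=1)
        for i in range(4):
            if pres.iloc[i].any() and r.where(pres).iloc[i].sum() > 0:
                assert sums.iloc[i] == pytest.approx(1.0, abs=1e-12)


class TestVcAbundance:
    def test_member_sum_and_conservation(self):
        rel = pd.DataFrame([[0.2, 0.3, 0.5]], index=["s"],
                           columns=["a", "b", "c"])
        pres = pd.DataFrame([[True, True, True]], index=["s"],
                            columns=["a", "b", "c"])
        vc_rel, vc_pres = vc_abundance(rel, pres, {"VC_1": ["a", "b"],
                                                   "VC_2": ["c"]})
        assert vc_rel.loc["s", "VC_1"] == pytest.approx(0.5, abs=1e-12)
        assert vc_rel.loc["s"].sum() == pytest.approx(rel.loc["s"].sum(),
                                                      abs=1e-12)
        assert vc_pres.loc["s", "VC_2"]


class TestPrevalence:
    def test_fraction_of_samples(self):
        pres = pd.DataFrame({"v": [True] * 27 + [False] * 108})
        assert prevalence(pres)["v"] == pytest.approx(0.2, abs=1e-12)

    def test_extremes(self):
        pres = pd.DataFrame({"a": [False, False], "b": [True, True]})
        p = prevalence(pres)
        assert p["a"] == 0.0 and p["b"] == 1.0


class TestDiversity:
    def test_shannon_uniform_four(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4), abs=1e-9)

    def test_shannon_single_taxon_zero(self):
        assert shannon([1.0, 0.0]) == 0.0

    def test_shannon_vs_scipy_and_max_entropy_bound(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            row = rng.uniform(0, 1, 12)
            row[rng.random(12) < 0.3] = 0.0
            if (row > 0).sum() <= 1:
                continue
            ours = shannon(row)
            assert ours == pytest.approx(scipy_entropy(row[row > 0]), abs=1e-9)
            assert ours <= np.log((row > 0).sum()) + 1e-12

    @pytest.mark.parametrize("a,b,expected", [
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([1.0, 0.0], [0.0, 1.0], 1.0),
        ([1.0, 0.0], [0.5, 0.5], 0.5),
    ])
    def test_bray_curtis_closed_forms(self, a, b, expected):
        assert bray_curtis(a, b) == pytest.approx(expected, abs=1e-12)

    def test_bray_curtis_vs_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
            assert bray_curtis(a, b) == pytest.approx(scipy_bc(a, b), abs=1e-9)

    def test_bray_curtis_both_zero_undefined(self):
        with pytest.raises(ValueError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])


class TestRarefaction:
    def test_disjoint_sets_linear_curve(self):
        sets = {f"s{i}": {f"v{i}_{j}" for j in range(5)} for i in range(4)}
        df = rarefaction(sets, seed=1)
        assert df["mean_unique"].tolist() == [5.0, 10.0, 15.0, 20.0]

    def test_identical_sets_flat_curve(self):
        sets = {f"s{i}": {"a", "b", "c"} for i in range(4)}
        df = rarefaction(sets, seed=1)
        assert df["mean_unique"].tolist() == [3.0] * 4

    def test_curve_non_decreasing_and_deterministic(self):
        rng = np.random.default_rng(2)
        sets = {f"s{i}": {f"v{j}" for j in rng.choice(30, 10, replace=False)}
                for i in range(6)}
        a = rarefaction(sets, seed=7)
        b = rarefaction(sets, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert (np.diff(a["mean_unique"]) >= -1e-12).all()
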