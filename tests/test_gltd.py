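import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gltdseq.gltd import (
    GeneLengthTrendModel,
    bin_by_length,
    bin_direction_ratio,
    cohort_interaction_regression,
    deg_length_shift_test,
    length_ratio_regression,
)
from gltdseq.pipeline import analyze_simulated_cohort
from gltdseq.simulate import SimulationConfig


def lengths_series(values, ids=None):
    ids = ids or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=pd.Index(ids, name="gene_id"), name="length_bp")


def de_from_lfc(gene_ids, lfc, padj=None):
    lfc = np.asarray(lfc, dtype=float)
    padj = np.ones_like(lfc) if padj is None else np.asarray(padj, dtype=float)
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": lfc, "pvalue": padj, "padj": padj,
         "significant": padj < 0.05}
    )


class TestBinning:
    def test_exact_division(self):
        rng = np.random.default_rng(0)
        bins = bin_by_length(lengths_series(rng.integers(100, 10**6, 1000)), 500)
        assert bins.n_bins == 2
        assert bins.discarded == []

    def test_remainder_rule_discards_shortest(self):
        rng = np.random.default_rng(1)
        vals = rng.choice(10**6, size=1234, replace=False) + 100
        lengths = lengths_series(vals)
        bins = bin_by_length(lengths, 500)
        assert bins.n_bins == 2
        assert len(bins.discarded) == 234
        # discarded are exactly the shortest 234
        cut = np.sort(vals)[233]
        assert max(lengths[bins.discarded]) <= cut
        # bin 0 holds the longest genes
        assert bins.table["mean_length_bp"].is_monotonic_decreasing

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(n=st.integers(30, 400), bin_size=st.integers(5, 60), seed=st.integers(0, 99))
    def test_partition_matches_brute_force_oracle(self, n, bin_size, seed):
        if n < bin_size:
            return
        rng = np.random.default_rng(seed)
        vals = rng.integers(100, 10000, size=n)  # deliberately with ties
        lengths = lengths_series(vals)
        bins = bin_by_length(lengths, bin_size)
        # brute-force: sort by (-length, gene_id), slice consecutive chunks
        order = sorted(lengths.index, key=lambda g: (-lengths[g], g))
        n_bins = n // bin_size
        for b in range(n_bins):
            expected = order[b * bin_size : (b + 1) * bin_size]
            assert sorted(bins.members(b)) == sorted(expected)
        assert sorted(bins.discarded) == sorted(order[n_bins * bin_size :])
        # every retained gene in exactly one bin
        assert bins.assignments.index.is_unique
        assert len(bins.assignments) + len(bins.discarded) == n

    def test_universe_smaller_than_bin_rejected(self):
        with pytest.raises(ValueError, match="smaller than one bin"):
            bin_by_length(lengths_series([10, 20]), 500)


class TestDirectionRatio:
    def test_ratio_definition(self):
        vals = np.arange(100, 150)[::-1]
        lengths = lengths_series(vals)
        bins = bin_by_length(lengths, 50)
        lfc = np.array([1.0] * 30 + [-1.0] * 20)
        out = bin_direction_ratio(bins, de_from_lfc(lengths.index, lfc))
        row = out.table.iloc[0]
        assert (row["n_up"], row["n_down"]) == (30, 20)
        assert row["up_ratio"] == pytest.approx(0.6)

    def test_zero_lfc_counted_in_neither(self):
        lengths = lengths_series(np.arange(10, 20))
        bins = bin_by_length(lengths, 10)
        lfc = np.array([1.0] * 3 + [0.0] * 4 + [-1.0] * 3)
        out = bin_direction_ratio(bins, de_from_lfc(lengths.index, lfc))
        assert out.table.iloc[0]["n_up"] + out.table.iloc[0]["n_down"] == 6

    def test_deg_only_empty_bin_is_undefined(self):
        lengths = lengths_series(np.arange(100, 120))
        bins = bin_by_length(lengths, 10)
        de = de_from_lfc(lengths.index, np.ones(20), padj=np.ones(20))
        out = bin_direction_ratio(bins, de, mode="deg_only")
        assert out.table["up_ratio"].isna().all()

    def test_missing_gene_rejected(self):
        lengths = lengths_series(np.arange(100, 120))
        bins = bin_by_length(lengths, 10)
        de = de_from_lfc(lengths.index[:-1], np.ones(19))
        with pytest.raises(ValueError, match="missing from the DE table"):
            bin_direction_ratio(bins, de)

    def test_odds_variant(self):
        lengths = lengths_series(np.arange(100, 150))
        bins = bin_by_length(lengths, 50)
        lfc = np.array([1.0] * 30 + [-1.0] * 20)
        out = bin_direction_ratio(bins, de_from_lfc(lengths.index, lfc), ratio="odds")
        assert out.table.iloc[0]["up_ratio"] == pytest.approx(1.5)


class TestRegression:
    def _bins_with_ratios(self, log10_lengths, ratios):
        table = pd.DataFrame(
            {
                "bin_index": np.arange(len(ratios)),
                "mean_length_bp": 10.0 ** np.asarray(log10_lengths),
                "n_total": 500,
                "n_up": 1,
                "n_down": 1,
                "up_ratio": ratios,
            }
        )
        from gltdseq.gltd import LengthBinTable

        return LengthBinTable(table, pd.Series(dtype=int), [], 500)

    def test_perfect_linear_fit(self):
        x = np.array([3.0, 3.5, 4.0, 4.5, 5.0])
        bins = self._bins_with_ratios(x, 0.9 - 0.1 * x)
        fit = length_ratio_regression(bins)
        assert fit.slope == pytest.approx(-0.1, abs=1e-12)
        assert fit.pearson_r == pytest.approx(-1.0)
        assert fit.pvalue < 1e-10
        assert fit.df == 3

    def test_constant_ratios_rejected(self):
        bins = self._bins_with_ratios([3.0, 4.0, 5.0], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="zero variance"):
            length_ratio_regression(bins)

    def test_too_few_bins_rejected(self):
        bins = self._bins_with_ratios([3.0, 4.0], [0.4, 0.6])
        with pytest.raises(ValueError, match=">= 3"):
            length_ratio_regression(bins)

    def test_length_units_shift_intercept_only(self):
        x = np.array([3.0, 3.7, 4.1, 4.9, 5.3])
        rng = np.random.default_rng(2)
        y = 0.8 - 0.08 * x + rng.normal(0, 0.01, 5)
        bp = self._bins_with_ratios(x, y)
        kb = self._bins_with_ratios(x - 3, y)  # lengths in kb
        fit_bp, fit_kb = length_ratio_regression(bp), length_ratio_regression(kb)
        assert fit_bp.slope == pytest.approx(fit_kb.slope, rel=1e-9)
        assert fit_bp.pearson_r == pytest.approx(fit_kb.pearson_r, rel=1e-9)
        assert fit_bp.intercept != pytest.approx(fit_kb.intercept)

    def test_r_and_slope_share_sign(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.uniform(3, 6, 8)
            y = rng.uniform(0.2, 0.8, 8)
            try:
                fit = length_ratio_regression(self._bins_with_ratios(x, y))
            except ValueError:
                continue
            assert np.sign(fit.slope) == np.sign(fit.pearson_r)

    def test_model_results_summary(self):
        res = analyze_simulated_cohort(SimulationConfig(n_genes=4000, seed=43),
                                       bin_size=250)["gltd"]
        text = res.summary()
        assert "Pearson r" in text
        assert res.fit.df == res.fit.n_bins - 2


class TestCohortComparison:
    def _simulated_bins(self, slope, seed, n_bins=20):
        rng = np.random.default_rng(seed)
        x = np.linspace(3.2, 5.6, n_bins)
        y = 0.5 + slope * (x - x.mean()) + rng.normal(0, 0.02, n_bins)
        return TestRegression()._bins_with_ratios(x, y)

    def test_identical_cohorts_show_no_interaction(self):
        bins = self._simulated_bins(-0.3, 0)
        comp = cohort_interaction_regression(bins, bins)
        assert comp.f_stat == pytest.approx(0.0, abs=1e-9)
        assert comp.pvalue > 0.99

    def test_opposite_slopes_detected(self):
        a = self._simulated_bins(-0.4, 1)
        b = self._simulated_bins(+0.4, 2)
        comp = cohort_interaction_regression(a, b)
        assert comp.pvalue < 0.01
        assert comp.df_num == 1
        assert comp.df_den == 2 * 20 - 4

    def test_pooled_slope_reported(self):
        a = self._simulated_bins(-0.3, 3)
        b = self._simulated_bins(-0.3, 4)
        comp = cohort_interaction_regression(a, b)
        assert comp.pooled_slope == pytest.approx(-0.3, abs=0.05)
        assert comp.pooled_slope_p < 1e-6


class TestLengthShift:
    def test_exact_enumeration_fixture(self):
        de = de_from_lfc(
            [f"g{i}" for i in range(6)],
            [1, 1, 1, -1, -1, -1],
            padj=np.zeros(6),
        )
        lengths = lengths_series([1, 2, 3, 4, 5, 6])
        out = deg_length_shift_test(de, lengths)
        assert out["U"] == 0
        assert out["pvalue"] == pytest.approx(0.1)
        assert out["method"] == "exact"

    def test_identical_groups_give_p_one(self):
        de = de_from_lfc(
            [f"g{i}" for i in range(6)], [1, 1, 1, -1, -1, -1], padj=np.zeros(6)
        )
        lengths = lengths_series([5, 7, 9, 5, 7, 9])
        assert deg_length_shift_test(de, lengths)["pvalue"] == pytest.approx(1.0)

    def test_asymptotic_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(4)
        n = 8
        de = de_from_lfc(
            [f"g{i}" for i in range(2 * n)], [1] * n + [-1] * n, padj=np.zeros(2 * n)
        )
        lengths = lengths_series(rng.choice(10000, size=2 * n, replace=False))
        from scipy import stats

        up = lengths.iloc[:n].to_numpy(float)
        down = lengths.iloc[n:].to_numpy(float)
        exact = deg_length_shift_test(de, lengths)["pvalue"]
        approx = stats.mannwhitneyu(up, down, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert approx == pytest.approx(exact, rel=0.10)

    def test_empty_direction_rejected(self):
        de = de_from_lfc(["g0", "g1"], [1, 1], padj=np.zeros(2))
        with pytest.raises(ValueError, match="undefined"):
            deg_length_shift_test(de, lengths_series([10, 20], ["g0", "g1"]))


class TestEndToEndPattern:
    def test_strong_bias_flips_ratio_across_length(self):
        res = analyze_simulated_cohort(SimulationConfig(gltd_slope=1.5, seed=42))
        bins = res["gltd"].bins.dropna(subset=["up_ratio"])
        longest, shortest = bins.iloc[0], bins.iloc[-1]
        assert shortest["up_ratio"] > 0.5
        assert longest["up_ratio"] < 0.5
        assert res["gltd"].slope < 0

    def test_bin_means_strictly_decreasing_on_simulated_universe(self):
        res = analyze_simulated_cohort(SimulationConfig(seed=44))
        means = res["gltd"].bins["mean_length_bp"].to_numpy()
        assert np.all(np.diff(means) < 0)
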