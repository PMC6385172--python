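"""Purity-confounding analyses: rank-correlation machinery, gene
classification, signature filtering, rates and the 2x2 chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purityconn.purity import (
    AnalysisError,
    classify_gene_purity_sensitivity,
    compare_rates_chisq,
    correlate_connectivity_purity,
    filter_signature_purity,
    negative_enrichment_rate,
    purity_tertile,
    purity_tertile_comparison,
    spearman_test,
    wilcoxon_ranksum,
)
from purityconn.signatures import TumourSignature


def results_frame(scores, perm_p=None, drug="d", samples=None):
    samples = samples or [f"s{i}" for i in range(len(scores))]
    return pd.DataFrame({
        "sample_id": samples, "drug_id": drug, "score": scores,
        "perm_p": perm_p if perm_p is not None else [np.nan] * len(scores),
    })


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_test([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)   # two orderings out of 5!

    def test_small_sample_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman_test(x, y)
        # oracle: enumerate all permutations with plain python
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        def pearson(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            a -= a.mean(); b -= b.mean()
            return float(a @ b / np.sqrt((a @ a) * (b @ b)))
        rho_oracle = pearson(rx, ry)
        null = [pearson(rx, perm) for perm in itertools.permutations(ry)]
        p_oracle = np.mean([abs(r) >= abs(rho_oracle) - 1e-12 for r in null])
        assert rho == pytest.approx(rho_oracle)
        assert p == pytest.approx(p_oracle)

    def test_constant_input_undefined(self):
        rho, p = spearman_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)


class TestPurityAssociation:
    def test_scores_equal_purity_gives_rho_one(self):
        purity = pd.Series([50.0, 60, 70, 80, 90], index=[f"s{i}" for i in range(5)])
        res = results_frame(list(purity.values))
        a = correlate_connectivity_purity(res, purity)
        assert a.spearman_rho == pytest.approx(1.0)
        assert a.n == 5

    def test_null_p_uniformly_distributed(self):
        """Permuting scores against purity yields uniform Spearman p."""
        rng = np.random.default_rng(8)
        purity = pd.Series(rng.uniform(40, 95, 30), index=[f"s{i}" for i in range(30)])
        ps = []
        for _ in range(200):
            scores = rng.permutation(purity.values)
            a = correlate_connectivity_purity(results_frame(list(scores)), purity)
            ps.append(a.spearman_p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_identical_scores_reported_undefined(self):
        purity = pd.Series([50.0, 60, 70, 80], index=[f"s{i}" for i in range(4)])
        a = correlate_connectivity_purity(results_frame([0.1] * 4), purity)
        assert a.spearman_rho is None

    def test_split_assigns_boundary_to_low_group(self):
        purity = pd.Series([70.0, 80.0, 90.0, 95.0, 60.0],
                           index=[f"s{i}" for i in range(5)])
        res = results_frame([0.0, 0.0, 1.0, 1.0, 0.0])
        a = correlate_connectivity_purity(res, purity)
        # 80 goes to the low group: high = {90, 95} scores {1,1}, low = {0,0,0}
        assert a.wilcoxon_split_p == pytest.approx(
            wilcoxon_ranksum([1.0, 1.0], [0.0, 0.0, 0.0]))

    def test_undefined_scores_excluded(self):
        purity = pd.Series([50.0, 60, 70, 80], index=[f"s{i}" for i in range(4)])
        res = results_frame([0.1, np.nan, 0.3, 0.2])
        assert correlate_connectivity_purity(res, purity).n == 3


class TestGeneClassification:
    def _series(self, values):
        idx = [f"s{i}" for i in range(len(values))]
        return pd.Series(values, index=idx, name="g")

    def test_up_gene_tracking_purity_is_more_de(self):
        purity = self._series(np.linspace(40, 95, 20))
        expr = self._series(np.linspace(1, 6, 20))
        c = classify_gene_purity_sensitivity(expr, purity, "up")
        assert c.label == "more_de" and c.rho > 0

    def test_up_gene_opposing_purity_is_less_de(self):
        purity = self._series(np.linspace(40, 95, 20))
        expr = self._series(np.linspace(6, 1, 20))
        assert classify_gene_purity_sensitivity(expr, purity, "up").label == "less_de"

    def test_down_gene_with_negative_correlation_is_more_de(self):
        purity = self._series(np.linspace(40, 95, 20))
        expr = self._series(np.linspace(6, 1, 20))
        assert classify_gene_purity_sensitivity(expr, purity, "down").label == "more_de"

    def test_uncorrelated_gene_is_insensitive(self):
        rng = np.random.default_rng(4)
        purity = self._series(np.linspace(40, 95, 40))
        expr = self._series(rng.normal(size=40))
        assert classify_gene_purity_sensitivity(expr, purity, "up").label == "insensitive"

    @settings(derandomize=True, max_examples=25)
    @given(st.sampled_from(["up", "down"]),
           st.floats(0.1, 3.0), st.floats(-2.0, 2.0))
    def test_invariant_under_monotone_transforms(self, direction, scale, shift):
        rng = np.random.default_rng(11)
        purity = self._series(rng.uniform(40, 95, 25))
        expr = self._series(purity.values * 0.05 + rng.normal(0, 0.5, 25))
        c0 = classify_gene_purity_sensitivity(expr, purity, direction)
        transformed = self._series(np.exp(scale * expr.values + shift))
        c1 = classify_gene_purity_sensitivity(transformed, purity, direction)
        assert c0.label == c1.label
        assert c0.p == pytest.approx(c1.p)


class TestSignatureFiltering:
    def _classes(self, labels):
        from purityconn.purity import PurityGeneClass
        return {
            (g, d): PurityGeneClass(g, d, lab, 0.0, 1.0)
            for (g, d), lab in labels.items()
        }

    def test_identity_when_nothing_less_de(self):
        sig = TumourSignature("s", ["a", "b"], ["c"], pd.DataFrame())
        classes = self._classes({("a", "up"): "more_de", ("b", "up"): "insensitive",
                                 ("c", "down"): "more_de"})
        out = filter_signature_purity(sig, classes)
        assert out.up_genes == ["a", "b"] and out.down_genes == ["c"]

    def test_all_less_de_empties_signature(self):
        sig = TumourSignature("s", ["a"], ["b"], pd.DataFrame())
        classes = self._classes({("a", "up"): "less_de", ("b", "down"): "less_de"})
        out = filter_signature_purity(sig, classes)
        assert out.size == 0

    def test_mixed_labels_keep_exact_complement(self):
        up = [f"u{i}" for i in range(10)]
        down = [f"d{i}" for i in range(10)]
        labels = {}
        for i, g in enumerate(up):
            labels[(g, "up")] = "less_de" if i % 3 == 0 else "insensitive"
        for i, g in enumerate(down):
            labels[(g, "down")] = "less_de" if i % 4 == 0 else "more_de"
        sig = TumourSignature("s", up, down, pd.DataFrame())
        out = filter_signature_purity(sig, self._classes(labels))
        assert out.up_genes == [g for i, g in enumerate(up) if i % 3 != 0]
        assert out.down_genes == [g for i, g in enumerate(down) if i % 4 != 0]
        assert out.size <= sig.size

    def test_missing_class_is_error(self):
        sig = TumourSignature("s", ["a"], [], pd.DataFrame())
        with pytest.raises(AnalysisError, match="no purity class"):
            filter_signature_purity(sig, {})


class TestRates:
    def test_all_positive_scores_rate_zero(self):
        res = results_frame([0.1, 0.5, 0.2], perm_p=[0.01, 0.01, 0.01])
        assert negative_enrichment_rate(res) == 0.0

    def test_counting(self):
        scores = [-0.5, -0.4, -0.3, 0.1, 0.2, -0.1, 0.3, 0.4, 0.5, 0.6]
        pvals = [0.01, 0.02, 0.2, 0.01, 0.9, 0.04, 0.5, 0.5, 0.5, 0.5]
        res = results_frame(scores, perm_p=pvals)
        assert negative_enrichment_rate(res) == pytest.approx(0.3)

    def test_brute_force_count_on_synthetic_table(self):
        rng = np.random.default_rng(10)
        scores = rng.uniform(-1, 1, 50)
        pvals = rng.uniform(0, 1, 50)
        res = results_frame(list(scores), perm_p=list(pvals))
        manual = sum(1 for s, p in zip(scores, pvals) if s < 0 and p < 0.05) / 50
        assert negative_enrichment_rate(res) == pytest.approx(manual)

    def test_undefined_scores_out_of_denominator(self):
        res = results_frame([-0.5, np.nan], perm_p=[0.01, np.nan])
        assert negative_enrichment_rate(res) == 1.0

    def test_empty_is_error(self):
        with pytest.raises(AnalysisError):
            negative_enrichment_rate(results_frame([np.nan], perm_p=[np.nan]))


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        stat, p = compare_rates_chisq((30, 70), (30, 70))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a, b, c, d = 90, 10, 10, 90
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = compare_rates_chisq((a, b), (c, d))
        assert stat == pytest.approx(expected)

    def test_statistic_linear_in_counts_at_fixed_proportions(self):
        s1, _ = compare_rates_chisq((20, 30), (35, 15))
        s2, _ = compare_rates_chisq((40, 60), (70, 30))
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin_is_error(self):
        with pytest.raises(AnalysisError, match="margin"):
            compare_rates_chisq((0, 10), (0, 20))


class TestTertiles:
    def test_binning(self):
        assert [purity_tertile(p) for p in (50.0, 65.0, 80.0)] == ["low", "mid", "high"]

    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(3)
        purity = pd.Series(
            np.r_[rng.uniform(40, 59, 20), rng.uniform(60, 72, 20), rng.uniform(73, 95, 20)],
            index=[f"s{i}" for i in range(60)])
        scores = list(np.tile(rng.normal(size=20), 3))
        res = results_frame(scores, samples=list(purity.index))
        table = purity_tertile_comparison(res, purity)
        assert (table["p"] > 0.3).all()

    def test_shifted_mid_tertile_detected(self):
        rng = np.random.default_rng(6)
        purity = pd.Series(
            np.r_[rng.uniform(40, 59, 30), rng.uniform(60, 72, 30), rng.uniform(73, 95, 30)],
            index=[f"s{i}" for i in range(90)])
        scores = np.r_[rng.normal(0, 0.1, 30), rng.normal(-0.6, 0.1, 30),
                       rng.normal(0, 0.1, 30)]
        res = results_frame(list(scores), samples=list(purity.index))
        table = purity_tertile_comparison(res, purity).set_index("comparison")
        from scipy.stats import mannwhitneyu
        oracle = mannwhitneyu(scores[:30], scores[30:60], alternative="two-sided",
                              use_continuity=False, method="asymptotic").pvalue
        assert table.loc["low_vs_mid", "p"] == pytest.approx(oracle)
        assert table.loc["low_vs_mid", "p"] < 0.05
        assert table.loc["mid_vs_high", "p"] < 0.05

    def test_empty_tertile_is_error(self):
        purity = pd.Series([40.0, 45.0, 85.0], index=["s0", "s1", "s2"])
        res = results_frame([0.1, 0.2, 0.3], samples=["s0", "s1", "s2"])
        with pytest.raises(AnalysisError, match="empty"):
            purity_tertile_comparison(res, purity)
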