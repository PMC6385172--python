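"""Covariate models: univariate screen, mixed/OLS fits, backward
elimination, bootstrap stability and p-values, repeated k-fold CV."""

import numpy as np
import pandas as pd
import pytest

from purityconn.models import (
    ModelError,
    backward_eliminate,
    bootstrap_pvalues,
    bootstrap_stability,
    fit_lmm,
    p53_group,
    repeated_kfold_cv,
    signature_size_vs_p53,
    univariate_screen,
)


def linear_data(n=300, seed=0, betas=(1.5, 0.0, -2.0), noise=1.0, n_groups=6):
    """y = b0*x0 + b1*x1 + b2*1[cat=b] + group effect + noise."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=n)
    x1 = rng.normal(size=n)
    cat = rng.choice(["a", "b"], n)
    grp = rng.choice([f"g{i}" for i in range(n_groups)], n)
    grp_eff = {f"g{i}": rng.normal(0, 0.5) for i in range(n_groups)}
    y = (betas[0] * x0 + betas[1] * x1 + betas[2] * (cat == "b")
         + np.array([grp_eff[g] for g in grp]) + rng.normal(0, noise, n))
    return pd.DataFrame({"y": y, "x0": x0, "x1": x1, "cat": cat, "grp": grp})


class TestUnivariateScreen:
    def test_test_selection_by_arity_and_bonferroni(self):
        rng = np.random.default_rng(1)
        n = 200
        data = pd.DataFrame({
            "y": rng.normal(size=n),
            "binary": rng.choice(["u", "v"], n),
            "multi": rng.choice(["a", "b", "c"], n),
            "cont": rng.normal(size=n),
        })
        out = univariate_screen(data, "y", ["binary", "multi", "cont"]).set_index("variable")
        assert out.loc["binary", "test"] == "wilcoxon"
        assert out.loc["multi", "test"] == "kruskal"
        assert out.loc["cont", "test"] == "spearman"
        assert np.allclose(out["bonferroni_p"],
                           np.minimum(out["raw_p"] * 3, 1.0))

    def test_null_binary_p_near_one_for_identical_groups(self):
        data = pd.DataFrame({"y": [1.0, 2, 3, 4] * 4,
                             "g": ["a"] * 8 + ["b"] * 8})
        out = univariate_screen(data, "y", ["g"]).set_index("variable")
        assert out.loc["g", "raw_p"] > 0.9

    def test_single_level_variable_skipped(self):
        data = pd.DataFrame({"y": [1.0, 2, 3], "g": ["a", "a", "a"]})
        out = univariate_screen(data, "y", ["g"]).set_index("variable")
        assert out.loc["g", "test"] == "skipped"

    def test_simulated_effect_detected(self):
        rng = np.random.default_rng(2)
        n = 300
        g = rng.choice(["no", "yes"], n)
        y = rng.normal(size=n) - 0.8 * (g == "yes")
        out = univariate_screen(pd.DataFrame({"y": y, "g": g}), "y", ["g"])
        assert out["bonferroni_p"].iloc[0] < 0.001


class TestFitLMM:
    def test_ols_estimates_recover_truth(self):
        data = linear_data(n=500, seed=3)
        fit = fit_lmm(data, "y", ["x0", "x1", "cat"])
        assert fit.coef["x0"] == pytest.approx(1.5, abs=3 * fit.se["x0"])
        assert fit.coef["cat[b]"] == pytest.approx(-2.0, abs=3 * fit.se["cat[b]"])
        assert 0 <= fit.r_squared <= 1

    def test_lmm_reduces_to_ols_when_group_variance_zero(self):
        rng = np.random.default_rng(4)
        n = 300
        data = pd.DataFrame({
            "x": rng.normal(size=n),
            "grp": rng.choice([f"g{i}" for i in range(15)], n),
        })
        data["y"] = 2.0 * data["x"] + rng.normal(0, 1, n)  # no group effect
        ols = fit_lmm(data, "y", ["x"])
        lmm = fit_lmm(data, "y", ["x"], random_terms=["grp"])
        assert lmm.coef["x"] == pytest.approx(ols.coef["x"], abs=0.02)
        assert lmm.random_var["grp"] == pytest.approx(0.0, abs=0.05)

    def test_lmm_matches_lme4_reference(self, tmp_path):
        """Variance component and fixed effects agree with an independent
        REML fit (lme4 via Rscript) on the same data."""
        import subprocess

        rng = np.random.default_rng(44)
        n = 200
        grp = rng.choice([f"g{i}" for i in range(12)], n)
        grp_eff = {f"g{i}": rng.normal(0, 0.6) for i in range(12)}
        data = pd.DataFrame({"x": rng.normal(size=n), "grp": grp})
        data["y"] = (1.7 * data["x"] + np.array([grp_eff[g] for g in grp])
                     + rng.normal(0, 1, n))
        fit = fit_lmm(data, "y", ["x"], random_terms=["grp"])
        csv = tmp_path / "lmm.csv"
        data.to_csv(csv, index=False)
        script = (
            f'd <- read.csv("{csv}"); '
            'm <- lme4::lmer(y ~ x + (1|grp), data=d, REML=TRUE); '
            'v <- as.data.frame(lme4::VarCorr(m)); '
            'cat(lme4::fixef(m)[["x"]], v$vcov[1], sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        slope_r, vc_r = map(float, out.stdout.strip().splitlines()[-2:])
        assert fit.coef["x"] == pytest.approx(slope_r, abs=1e-4)
        assert fit.random_var["grp"] == pytest.approx(vc_r, rel=1e-3, abs=1e-5)

    def test_lmm_recovers_fixed_effects_with_batch_structure(self):
        data = linear_data(n=500, seed=5)
        fit = fit_lmm(data, "y", ["x0", "cat"], random_terms=["grp"])
        assert fit.coef["x0"] == pytest.approx(1.5, abs=0.15)
        assert fit.random_var["grp"] > 0.05

    def test_parameter_recovery_across_replicates(self):
        """Estimates fall within 2 SEs of truth in roughly 95% of fits."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            data = linear_data(n=200, seed=1000 + rep, n_groups=2)
            fit = fit_lmm(data, "y", ["x0", "x1", "cat"])
            if abs(fit.coef["x0"] - 1.5) <= 2 * fit.se["x0"]:
                hits += 1
        assert hits >= 88   # binomial(100, .95) lower tail

    def test_outcome_cannot_predict_itself(self):
        data = linear_data(n=50, seed=6).rename(columns={"y": "purity_pct"})
        with pytest.raises(ModelError, match="predict itself"):
            fit_lmm(data, "purity_pct", ["purity_pct", "x0"])


class TestBackwardElimination:
    def test_all_significant_model_unchanged(self):
        data = linear_data(n=400, seed=7, betas=(2.0, 0.0, -3.0))
        fit = backward_eliminate(data, "y", ["x0", "cat"])
        assert set(fit.fixed_terms) == {"x0", "cat"}

    def test_only_true_predictor_survives(self):
        rng = np.random.default_rng(8)
        n = 200
        data = pd.DataFrame({
            "x0": rng.normal(size=n), "weak": rng.normal(size=n),
            "weaker": rng.normal(size=n),
        })
        data["y"] = 2 * data["x0"] + rng.normal(size=n)
        full = fit_lmm(data, "y", ["x0", "weak", "weaker"])
        assert full.term_p.idxmax() != "x0"   # a noise term is worst
        reduced = backward_eliminate(data, "y", ["x0", "weak", "weaker"])
        assert reduced.fixed_terms == ["x0"]

    def test_intercept_only_when_nothing_significant(self):
        rng = np.random.default_rng(21)
        n = 100
        data = pd.DataFrame({"x0": rng.normal(size=n), "x1": rng.normal(size=n)})
        data["y"] = rng.normal(size=n)
        fit = backward_eliminate(data, "y", ["x0", "x1"], alpha=1e-9)
        assert fit.fixed_terms == []
        assert fit.coef["intercept"] == pytest.approx(data["y"].mean())

    def test_noise_term_eliminated_in_most_replicates(self):
        eliminated = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            n = 150
            data = pd.DataFrame({"x0": rng.normal(size=n), "noise": rng.normal(size=n)})
            data["y"] = 1.5 * data["x0"] + rng.normal(size=n)
            fit = backward_eliminate(data, "y", ["x0", "noise"])
            if "noise" not in fit.fixed_terms and "x0" in fit.fixed_terms:
                eliminated += 1
        assert eliminated >= 0.95 * n_rep

    def test_output_terms_all_below_alpha(self):
        data = linear_data(n=300, seed=9)
        fit = backward_eliminate(data, "y", ["x0", "x1", "cat"], alpha=0.05)
        assert (fit.term_p < 0.05).all()


class TestBootstrapStability:
    def test_strong_predictor_always_selected(self):
        data = linear_data(n=300, seed=10, betas=(5.0, 0.0, 0.0), noise=0.5)
        rep = bootstrap_stability(data, "y", ["x0", "x1"], B=100, seed=1)
        assert rep.frequency["x0"] == 1.0
        assert bool(rep.kept["x0"])

    def test_noise_predictor_below_half(self):
        data = linear_data(n=300, seed=11, betas=(2.0, 0.0, -1.0))
        rep = bootstrap_stability(data, "y", ["x0", "x1", "cat"], B=200, seed=2)
        assert rep.frequency["x1"] < 0.5
        assert not bool(rep.kept["x1"])

    def test_seed_determinism(self):
        data = linear_data(n=150, seed=12)
        r1 = bootstrap_stability(data, "y", ["x0", "cat"], B=50, seed=3)
        r2 = bootstrap_stability(data, "y", ["x0", "cat"], B=50, seed=3)
        pd.testing.assert_series_equal(r1.frequency, r2.frequency)


class TestBootstrapPValues:
    def test_huge_effect_reports_floor(self):
        data = linear_data(n=300, seed=13, betas=(5.0, 0.0, 0.0), noise=0.2)
        out = bootstrap_pvalues(data, "y", ["x0"], B=1000, seed=4)
        assert out.loc["x0", "display"] == "<0.001"
        assert out.loc["x0", "bootstrap_p"] == pytest.approx(1 / 1000)

    def test_null_coefficient_p_calibrated(self):
        ps = []
        for rep in range(40):
            rng = np.random.default_rng(7000 + rep)
            n = 100
            data = pd.DataFrame({"x0": rng.normal(size=n)})
            data["y"] = rng.normal(size=n)
            out = bootstrap_pvalues(data, "y", ["x0"], B=200, seed=rep)
            ps.append(out.loc["x0", "bootstrap_p"])
        # roughly uniform: mean near 0.5, a spread across the unit interval
        assert 0.3 < np.mean(ps) < 0.7
        assert min(ps) < 0.2 and max(ps) > 0.8

    def test_seed_determinism(self):
        data = linear_data(n=100, seed=14)
        o1 = bootstrap_pvalues(data, "y", ["x0"], B=100, seed=5)
        o2 = bootstrap_pvalues(data, "y", ["x0"], B=100, seed=5)
        pd.testing.assert_frame_equal(o1, o2)


class TestRepeatedCV:
    def test_noiseless_linear_data_perfect_oof(self):
        rng = np.random.default_rng(15)
        n = 100
        data = pd.DataFrame({"x0": rng.normal(size=n)})
        data["y"] = 3.0 * data["x0"] + 1.0
        cv = repeated_kfold_cv(data, "y", ["x0"], k=5, repeats=5, seed=6)
        assert np.allclose(cv.oof_r2, 1.0)
        assert cv.in_sample_r2 == pytest.approx(1.0)

    def test_pure_noise_outcome_does_not_generalize(self):
        rng = np.random.default_rng(16)
        n = 120
        data = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(5)})
        data["y"] = rng.normal(size=n)
        cv = repeated_kfold_cv(data, "y", [f"x{i}" for i in range(5)],
                               k=10, repeats=20, seed=7)
        assert cv.oof_r2.mean() <= 0.0

    def test_overfitting_gap_grows_with_noise_predictors(self):
        rng = np.random.default_rng(17)
        n = 80
        base = pd.DataFrame({"x0": rng.normal(size=n)})
        base["y"] = base["x0"] + rng.normal(size=n)
        for i in range(15):
            base[f"junk{i}"] = rng.normal(size=n)
        small = repeated_kfold_cv(base, "y", ["x0"], k=10, repeats=10, seed=8)
        big = repeated_kfold_cv(base, "y", ["x0"] + [f"junk{i}" for i in range(15)],
                                k=10, repeats=10, seed=8)
        gap_small = small.in_sample_r2 - small.oof_r2.mean()
        gap_big = big.in_sample_r2 - big.oof_r2.mean()
        assert gap_big > gap_small

    def test_requires_enough_rows(self):
        data = linear_data(n=15, seed=18)
        with pytest.raises(ModelError, match="10-fold"):
            repeated_kfold_cv(data, "y", ["x0"], k=10, repeats=2, seed=9)


class TestSignatureSizeVsP53:
    def test_group_binning(self):
        assert [p53_group(c) for c in (0, 2, 5)] == ["0", "1-3", "4-15"]

    def test_constant_sizes_give_large_p(self):
        sizes = pd.Series([50.0] * 30, index=[f"s{i}" for i in range(30)])
        counts = pd.Series([0] * 10 + [2] * 10 + [8] * 10,
                           index=[f"s{i}" for i in range(30)])
        out = signature_size_vs_p53(sizes, counts)
        assert (out["p"] > 0.9).all()

    def test_increasing_sizes_detected(self):
        rng = np.random.default_rng(19)
        counts = pd.Series([0] * 30 + [2] * 30 + [8] * 30,
                           index=[f"s{i}" for i in range(90)])
        sizes = pd.Series(
            np.r_[rng.normal(20, 3, 30), rng.normal(40, 3, 30), rng.normal(70, 3, 30)],
            index=counts.index)
        out = signature_size_vs_p53(sizes, counts).set_index("comparison")
        assert (out["p"] < 0.001).all()
        assert out.loc["0_vs_1-3", "median_a"] < out.loc["0_vs_1-3", "median_b"]

    def test_empty_group_is_error(self):
        sizes = pd.Series([10.0, 20.0], index=["a", "b"])
        counts = pd.Series([0, 1], index=["a", "b"])
        with pytest.raises(ModelError, match="empty"):
            signature_size_vs_p53(sizes, counts)
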