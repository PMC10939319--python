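"""Normalization, the weighted linear model and empirical-Bayes testing."""

import numpy as np
import pandas as pd
import pytest

from thermorev import diffexp
from thermorev.diffexp import (GeneExpressionLM, build_design, cpm,
                               estimate_precision_weights, fit_weighted_lm,
                               moderate_and_test)
from thermorev.exceptions import ValidationError


def _frame(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestCPM:
    def test_single_gene_is_million(self):
        out = cpm(_frame([[10]]))
        assert out.values.iloc[0, 0] == pytest.approx(1e6)

    def test_proportionality(self):
        out = cpm(_frame([[25], [75]]))
        assert out.values["s0"].tolist() == pytest.approx([250000.0, 750000.0])

    def test_column_sums_are_million(self, small_sim):
        counts = small_sim[1]
        out = cpm(counts)
        assert out.values.sum(axis=0).to_numpy() == pytest.approx(
            np.full(counts.shape[1], 1e6), rel=1e-9)

    def test_logged_zero_count_formula(self):
        # one gene at 0 with external library size 1e6, prior 0.5
        counts = _frame([[0]])
        out = cpm(counts, log=True, prior_count=0.5,
                  libsizes=pd.Series({"s0": 1e6}))
        assert out.values.iloc[0, 0] == pytest.approx(
            np.log2(0.5 / (1e6 + 1.0) * 1e6), abs=1e-9)
        assert out.values.iloc[0, 0] == pytest.approx(-1.0, abs=1e-5)

    def test_zero_library_names_sample(self):
        with pytest.raises(ValidationError, match="s0"):
            cpm(_frame([[0], [0]]))


class TestLinearModel:
    def test_unit_weights_equal_ols(self, rng):
        y = _frame(rng.normal(size=(30, 8)))
        x = pd.DataFrame({"intercept": np.ones(8),
                          "slope": np.arange(8.0)}, index=y.columns)
        fit = fit_weighted_lm(y, x)
        ref = np.linalg.lstsq(x.to_numpy(), y.to_numpy().T, rcond=None)[0].T
        assert fit.coefficients.to_numpy() == pytest.approx(ref, abs=1e-10)

    def test_noiseless_exact_recovery(self):
        x = pd.DataFrame({"intercept": np.ones(6), "t": [0, 1, 0, 1, 0, 1]},
                         index=[f"s{j}" for j in range(6)])
        beta = np.array([[2.0, -1.5], [0.3, 0.8]])
        y = _frame(beta @ x.to_numpy().T, samples=list(x.index))
        fit = fit_weighted_lm(y, x)
        assert fit.coefficients.to_numpy() == pytest.approx(beta, abs=1e-12)
        assert fit.sigma.to_numpy() == pytest.approx(np.zeros(2), abs=1e-10)

    def test_weighted_matches_normal_equations_oracle(self, rng):
        y = _frame(rng.normal(size=(10, 7)))
        x = pd.DataFrame({"a": np.ones(7), "b": rng.normal(size=7)}, index=y.columns)
        w = _frame(rng.uniform(0.2, 3.0, size=(10, 7)), samples=list(y.columns))
        fit = fit_weighted_lm(y, x, w)
        for i, g in enumerate(y.index):
            wd = np.diag(w.iloc[i].to_numpy())
            xm = x.to_numpy()
            beta = np.linalg.solve(xm.T @ wd @ xm, xm.T @ wd @ y.iloc[i].to_numpy())
            assert fit.coefficients.iloc[i].to_numpy() == pytest.approx(beta, abs=1e-10)

    def test_rank_deficient_names_aliased(self):
        x = pd.DataFrame({"a": np.ones(5), "b": np.ones(5)},
                         index=[f"s{j}" for j in range(5)])
        y = _frame(np.zeros((3, 5)), samples=list(x.index))
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_weighted_lm(y, x)


class TestPrecisionWeights:
    def test_homoscedastic_weights_nearly_constant(self, rng):
        # equal-mean genes: the trend is flat, weights within 20% of constant
        counts = _frame(rng.poisson(500, size=(300, 12)))
        design = pd.DataFrame({"intercept": np.ones(12)}, index=counts.columns)
        w, trend = estimate_precision_weights(counts, design)
        vals = w.to_numpy()
        assert (vals.max() - vals.min()) / vals.mean() < 0.2
        assert np.isfinite(trend["sqrt_sd"].to_numpy()).all()
        assert (trend["sqrt_sd"].to_numpy() > 0).all()

    def test_library_scaling_preserves_weight_order(self, small_sim):
        _, gene_counts, _, sheet, _ = small_sim
        sub = sheet[(sheet.tissue == "gonad") & (sheet.stage_dpf == 15)]
        counts = gene_counts[sub["sample_id"].to_numpy()]
        design = build_design(sub)
        w1, _ = estimate_precision_weights(counts, design)
        w2, _ = estimate_precision_weights(counts * 2, design)
        from scipy import stats
        rho = stats.spearmanr(w1.to_numpy().ravel(), w2.to_numpy().ravel())[0]
        # monotone transform: the weight ordering is essentially preserved
        # (the refitted lowess trend allows tiny local reshuffles)
        assert rho > 0.99

    def test_few_genes_fall_back_to_unit(self):
        counts = _frame(np.full((10, 4), 100))
        design = pd.DataFrame({"intercept": np.ones(4)}, index=counts.columns)
        with pytest.warns(UserWarning, match="unit weights"):
            w, _ = estimate_precision_weights(counts, design)
        assert (w.to_numpy() == 1.0).all()


class TestModeratedTest:
    def _paired_fit(self, rng, n_genes=80, effect=None):
        samples = [f"s{j}" for j in range(8)]
        design = pd.DataFrame(
            {"intercept": np.ones(8), "treatment": [0, 1] * 4,
             "family[f2]": [0, 0, 1, 1, 0, 0, 0, 0],
             "family[f3]": [0, 0, 0, 0, 1, 1, 0, 0],
             "family[f4]": [0, 0, 0, 0, 0, 0, 1, 1]},
            index=samples)
        y = rng.normal(size=(n_genes, 8))
        if effect is not None:
            y[0] += effect * design["treatment"].to_numpy()
        return fit_weighted_lm(_frame(y, samples=samples), design)

    def test_identical_arms_give_null_result(self):
        samples = [f"s{j}" for j in range(6)]
        design = pd.DataFrame({"intercept": np.ones(6), "treatment": [0, 1] * 3},
                              index=samples)
        base = np.random.default_rng(0).normal(size=(40, 3))
        y = np.repeat(base, 2, axis=1)  # treated value == control value
        fit = fit_weighted_lm(_frame(y, samples=samples), design)
        res = fit.ebayes("treatment")
        assert res.table["logFC"].to_numpy() == pytest.approx(np.zeros(40), abs=1e-12)
        assert res.table["t"].to_numpy() == pytest.approx(np.zeros(40), abs=1e-10)
        assert res.table["p"].to_numpy() == pytest.approx(np.ones(40))

    def test_d0_zero_recovers_ordinary_t(self, rng):
        from scipy import stats
        fit = self._paired_fit(rng)
        res = moderate_and_test(fit, "treatment", d0_override=0.0)
        beta = fit.coefficients["treatment"].to_numpy()
        se = fit.stdev_unscaled["treatment"].to_numpy() * fit.sigma.to_numpy()
        t_ref = beta / se
        assert res.table["t"].to_numpy() == pytest.approx(t_ref, rel=1e-10)
        p_ref = 2 * stats.t.sf(np.abs(t_ref), fit.df_resid)
        assert res.table["p"].to_numpy() == pytest.approx(p_ref, rel=1e-9)

    def test_posterior_variance_convexity(self, rng):
        fit = self._paired_fit(rng, n_genes=200)
        res = fit.ebayes("treatment")
        s2 = fit.sigma.to_numpy() ** 2
        lo = np.minimum(s2, res.s0sq) - 1e-12
        hi = np.maximum(s2, res.s0sq) + 1e-12
        post = res.s2_post.to_numpy()
        assert ((post >= lo) & (post <= hi)).all()

    def test_direction_consistent_with_sign(self, rng):
        fit = self._paired_fit(rng, effect=5.0)
        res = fit.ebayes("treatment", use_adjusted=False)
        t = res.table
        sig = t[t["direction"] != "none"]
        assert ((sig["direction"] == "up") == (sig["logFC"] > 0)).all()
        assert (t["adj_p"] >= t["p"] - 1e-15).all()

    def test_summary_mentions_counts(self, rng):
        fit = self._paired_fit(rng)
        text = fit.ebayes("treatment").summary()
        assert "genes tested: 80" in text and "prior df" in text


class TestDEPipeline:
    def test_recovers_planted_effects(self, small_sim):
        _, gene_counts, _, sheet, truth = small_sim
        res = diffexp.de_pipeline(gene_counts, sheet, "gonad", 40)
        degs = set(res.degs)
        true_de = set(truth.de_genes) & set(res.table.index)
        assert len(degs & true_de) / len(true_de) >= 0.8

    def test_missing_stratum_errors(self, small_sim):
        _, gene_counts, _, sheet, _ = small_sim
        with pytest.raises(ValidationError):
            diffexp.de_pipeline(gene_counts, sheet[sheet.tissue == "gonad"], "brain", 40)
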