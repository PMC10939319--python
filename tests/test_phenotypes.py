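"""Reversal-rate statistics, exact tests and group comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from thermorev.exceptions import UndefinedStatisticError, ValidationError
from thermorev.phenotypes import (BatchRecord, binomial_sexratio_test,
                                  compare_groups_logistic, fisher_exact_2x2,
                                  inversion_rate, pair_families,
                                  family_pair_table,
                                  relative_survival_rate, spearman_correlation,
                                  summarize_population)


class TestReversalRate:
    @pytest.mark.parametrize(
        "sr_t, sr_c, expected",
        [
            (1.00, 0.50, 100.0),          # all-male treated batch -> full reversal
            (0.30, 0.30, 0.0),            # no treatment effect
            (0.88, 0.65, 100 * 0.23 / 0.35),  # hand arithmetic: 65.714...
            (0.40, 0.60, -50.0),          # reversal can be negative
        ],
    )
    def test_ir_values(self, sr_t, sr_c, expected):
        assert inversion_rate(sr_t, sr_c) == pytest.approx(expected, abs=1e-9)

    def test_all_male_treated_gives_100_for_any_control(self):
        for sr_c in (0.0, 0.25, 0.5, 0.77, 0.999):
            assert inversion_rate(1.0, sr_c) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "s_t, s_c, expected",
        [(0.5, 0.5, 0.0), (1.0, 0.3, 100.0), (0.95, 0.81, 100 * 0.14 / 0.19)],
    )
    def test_rsr_values(self, s_t, s_c, expected):
        assert relative_survival_rate(s_t, s_c) == pytest.approx(expected, abs=1e-9)

    def test_undefined_at_full_control(self):
        with pytest.raises(UndefinedStatisticError):
            inversion_rate(1.0, 1.0)
        with pytest.raises(UndefinedStatisticError):
            relative_survival_rate(0.9, 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            inversion_rate(1.2, 0.5)

    @given(st.floats(0, 0.99), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_treated_and_bounded(self, sr_c, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert inversion_rate(hi, sr_c) > inversion_rate(lo, sr_c)
        assert inversion_rate(hi, sr_c) <= 100.0 + 1e-9


def _fisher_oracle(a, b, c, d):
    """Literal enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(n, c1, exact=True)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((10, 0, 0, 10), 2 / comb(20, 10, exact=True)),
            ((3, 1, 1, 3), 34 / 70),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-7)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) and (c + d) and (a + c) and (b + d):
                assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                    _fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 3, 4)


class TestBinomial:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(10, 20, 1.0), (20, 20, 2 * 0.5**20), (15, 20, 2 * 21700 / 2**20)],
    )
    def test_known_values(self, k, n, expected):
        assert binomial_sexratio_test(k, n) == pytest.approx(expected, rel=1e-9)

    def test_symmetry(self):
        for n in (7, 12, 31):
            for k in range(n + 1):
                assert binomial_sexratio_test(k, n) == pytest.approx(
                    binomial_sexratio_test(n - k, n), rel=1e-12)

    def test_matches_tail_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p_obs = comb(n, k, exact=True) * 0.5**n
            oracle = sum(comb(n, j, exact=True) * 0.5**n for j in range(n + 1)
                         if comb(n, j, exact=True) * 0.5**n <= p_obs * (1 + 1e-12))
            assert binomial_sexratio_test(k, n) == pytest.approx(oracle, rel=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            binomial_sexratio_test(5, 4)


class TestSpearman:
    def test_perfect_and_reversed(self):
        assert spearman_correlation([1, 2, 3, 4], [1, 2, 3, 4]).rho == pytest.approx(1.0)
        res = spearman_correlation([10, 20, 30, 40], [9, 7, 5, 2])
        assert res.rho == pytest.approx(-1.0)

    def test_known_rho(self):
        res = spearman_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)  # 1 - 6*4/(4*15)

    def test_exact_p_equals_permutation_enumeration(self, rng):
        for n in (4, 5, 6):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = spearman_correlation(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            obs = abs(np.corrcoef(rx, ry)[0, 1])
            hits = sum(
                abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
                for perm in itertools.permutations(ry)
            )
            assert res.p == pytest.approx(hits / math.factorial(n), rel=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            res = spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined and math.isnan(res.rho)

    def test_large_n_uses_t_approximation(self, rng):
        x = np.arange(20.0)
        y = x + rng.normal(0, 5, size=20)
        res = spearman_correlation(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref_rho)
        assert res.p == pytest.approx(ref_p, rel=1e-6)


class TestGroupComparison:
    def test_identical_groups_share_letter(self):
        batches = [
            BatchRecord("A", "A_F1", "control", 100, 90, 80, 40),
            BatchRecord("B", "B_F1", "control", 100, 90, 80, 40),
        ]
        table, letters = compare_groups_logistic(batches, grouping="population")
        assert letters["A"] == letters["B"]

    def test_overwhelming_difference_disjoint_letters(self):
        batches = [
            BatchRecord("A", "A_F1", "control", 200, 200, 200, 10),
            BatchRecord("B", "B_F1", "control", 200, 200, 200, 190),
        ]
        _, letters = compare_groups_logistic(batches, grouping="population")
        assert not set(letters["A"]) & set(letters["B"])

    def test_two_group_decisions_agree_with_fisher(self, rng):
        """Cross-method concordance: logit LRT vs Fisher exact at alpha=0.05."""
        agree = 0
        total = 0
        for _ in range(100):
            n1, n2 = rng.integers(30, 120, size=2)
            k1 = int(rng.integers(1, n1))
            k2 = int(rng.integers(1, n2))
            batches = [
                BatchRecord("A", "A_F1", "control", int(n1), int(n1), int(n1), k1),
                BatchRecord("B", "B_F1", "control", int(n2), int(n2), int(n2), k2),
            ]
            table, _ = compare_groups_logistic(batches, grouping="population")
            p_f = fisher_exact_2x2(k1, int(n1) - k1, k2, int(n2) - k2)
            total += 1
            if (table["p"].iloc[0] <= 0.05) == (p_f <= 0.05):
                agree += 1
        assert agree / total >= 0.95  # asymptotic vs exact may differ at the margin

    def test_separation_falls_back_to_fisher(self):
        batches = [
            BatchRecord("A", "A_F1", "control", 50, 50, 50, 0),
            BatchRecord("B", "B_F1", "control", 50, 50, 50, 25),
        ]
        table, _ = compare_groups_logistic(batches, grouping="population")
        assert (table["method"] == "fisher").all()

    def test_letters_consistent_with_pairwise_decisions(self, example_batches):
        table, letters = compare_groups_logistic(
            example_batches, grouping=lambda b: f"{b.population}|{b.treatment}")
        for row in table.itertuples():
            share = bool(set(letters[row.group1]) & set(letters[row.group2]))
            assert share != (row.adj_p <= 0.05)


class TestSummaries:
    def test_single_family_degenerate(self):
        batches = [
            BatchRecord("GB", "GB_F1", "control", 100, 90, 80, 40),
            BatchRecord("GB", "GB_F1", "ltherm", 100, 85, 75, 60),
            BatchRecord("GO", "GO_F1", "control", 100, 90, 80, 42),
            BatchRecord("GO", "GO_F1", "ltherm", 100, 85, 75, 70),
        ]
        summary = summarize_population(pair_families(batches))
        row = summary[(summary.population == "GB") & (summary.treatment == "control")].iloc[0]
        assert row["mean"] == pytest.approx(row["median"]) == pytest.approx(50.0)
        assert row["sd"] == 0.0

    def test_quartiles_linear_interpolation(self, example_batches):
        vals = [64.0, 79.0, 91.0, 33.0]
        assert np.median(vals) == pytest.approx(np.percentile(vals, 50))

    def test_permutation_invariance(self, example_batches):
        pairs = pair_families(example_batches)
        s1 = summarize_population(pairs)
        s2 = summarize_population(list(reversed(pairs)))
        for col in ("mean", "sd", "median", "p25", "p75", "mean_ir"):
            assert np.allclose(s1[col].to_numpy(), s2[col].to_numpy())

    def test_family_pair_table_columns(self, example_batches):
        t = family_pair_table(pair_families(example_batches))
        assert {"ir", "rsr", "fisher_p_sex", "binomial_p_control_50_50"} <= set(t.columns)
        assert len(t) == 4


class TestBatchValidation:
    def test_males_exceed_sexed(self):
        with pytest.raises(ValidationError):
            BatchRecord("A", "F", "control", 10, 10, 5, 6)

    def test_bad_treatment(self):
        with pytest.raises(ValidationError):
            BatchRecord("A", "F", "heated", 10, 10, 5, 2)

    def test_duplicate_arm_rejected(self):
        b = BatchRecord("A", "F", "control", 10, 10, 5, 2)
        with pytest.raises(ValidationError):
            pair_families([b, b])
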