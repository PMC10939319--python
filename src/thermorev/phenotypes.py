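"""Sex-ratio and survival statistics for paired control / high-temperature batches.

A full-sib family is split at 9-10 dpf into a control batch reared at ~30 degC
and a treated ("Ltherm") batch held at a masculinizing 36.5 degC from 10 to
30 dpf.  Sexing at 90 dpf gives the male proportion in each batch; counting at
31 dpf gives survival.  Two derived statistics summarize the treatment effect
per family:

* reversal rate  IR  (%) = 100 * (SR_t - SR_c) / (1 - SR_c), the fraction of
  presumptive females masculinized by the treatment, where SR is the male
  proportion;
* relative survival  RSR (%) = same transform applied to 31-dpf survival
  proportions.

Both may be negative (treatment can depress the numerator) and are undefined
when the control proportion is exactly 1 (no females left to reverse).

The module also carries the supporting tests: exact Fisher 2x2 comparison of
treated vs control counts, exact binomial test of a control sex ratio against
the theoretical 50:50, Spearman rank correlation (exact permutation null for
n <= 7), a binomial-logit group comparison with a compact letter display, and
Table-style population summaries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._stats import bh_adjust, compact_letters
from .exceptions import UndefinedStatisticError, ValidationError

__all__ = [
    "BatchRecord",
    "FamilyPair",
    "SpearmanResult",
    "inversion_rate",
    "relative_survival_rate",
    "fisher_exact_2x2",
    "binomial_sexratio_test",
    "spearman_correlation",
    "compare_groups_logistic",
    "pair_families",
    "family_pair_table",
    "summarize_population",
]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatchRecord:
    """Counts for one rearing batch (one family under one treatment)."""

    population: str
    family: str
    treatment: str  # "control" | "ltherm"
    n_stocked: int
    n_alive_31dpf: int
    n_sexed: int
    n_males: int

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "ltherm"):
            raise ValidationError(
                f"treatment must be 'control' or 'ltherm', got {self.treatment!r}"
            )
        for name in ("n_stocked", "n_alive_31dpf", "n_sexed", "n_males"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_males > self.n_sexed:
            raise ValidationError(
                f"family {self.family}: n_males ({self.n_males}) > n_sexed ({self.n_sexed})"
            )
        if self.n_alive_31dpf > self.n_stocked:
            raise ValidationError(
                f"family {self.family}: n_alive_31dpf ({self.n_alive_31dpf}) > "
                f"n_stocked ({self.n_stocked})"
            )

    @property
    def male_ratio(self) -> float:
        if self.n_sexed == 0:
            raise UndefinedStatisticError(f"family {self.family}: no sexed fish")
        return self.n_males / self.n_sexed

    @property
    def survival_rate(self) -> float:
        if self.n_stocked == 0:
            raise UndefinedStatisticError(f"family {self.family}: no stocked fish")
        return self.n_alive_31dpf / self.n_stocked


@dataclass(frozen=True)
class FamilyPair:
    """A family's control and treated batches with the derived IR / RSR."""

    family: str
    control: BatchRecord
    treated: BatchRecord

    @property
    def population(self) -> str:
        return self.control.population

    @property
    def ir(self) -> float:
        return inversion_rate(self.treated.male_ratio, self.control.male_ratio)

    @property
    def rsr(self) -> float:
        return relative_survival_rate(self.treated.survival_rate, self.control.survival_rate)


# ---------------------------------------------------------------------------
# the two display statistics
# ---------------------------------------------------------------------------

def _excess_over_control(p_treated: float, p_control: float, what: str) -> float:
    for name, v in (("treated", p_treated), ("control", p_control)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} {what} proportion must be in [0, 1], got {v}")
    if p_control == 1.0:
        raise UndefinedStatisticError(
            f"{what} statistic undefined: control proportion is 1 (nothing left to shift)"
        )
    return 100.0 * (p_treated - p_control) / (1.0 - p_control)


def inversion_rate(sr_treated: float, sr_control: float) -> float:
    """Reversal rate IR (%) from treated and control male proportions.

    IR = 100 * (SR_treated - SR_control) / (1 - SR_control).  An all-male
    treated batch yields IR = 100 for any control ratio below 1; equal
    proportions yield 0; values may be negative.
    """
    return _excess_over_control(sr_treated, sr_control, "male-ratio")


def relative_survival_rate(s_treated: float, s_control: float) -> float:
    """Relative survival RSR (%) from treated and control 31-dpf survival."""
    return _excess_over_control(s_treated, s_control, "survival")


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided by the point-probability rule: sum hypergeometric probabilities
    of all tables with the observed margins whose probability does not exceed
    that of the observed table (the R fisher.test convention).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError("cell counts must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValidationError("Fisher test needs positive row and column totals")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def binomial_sexratio_test(n_males: int, n_sexed: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of an observed sex ratio against ``p0``.

    Two-sided by summing probabilities of outcomes no more likely than the
    observed count (the R binom.test convention).
    """
    if n_sexed < 1:
        raise ValidationError("binomial test needs n_sexed >= 1")
    if n_males < 0 or n_males > n_sexed:
        raise ValidationError("n_males must lie in [0, n_sexed]")
    return float(stats.binomtest(n_males, n_sexed, p0, alternative="two-sided").pvalue)


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    undefined: bool = False


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the Pearson correlation of average (mid) ranks.  For n <= 7 the
    p-value enumerates all n! permutations of one rank vector (two-sided:
    fraction of permutations with |rho| >= |rho_obs|); larger n uses the usual
    t approximation on n - 2 degrees of freedom.

    A constant input has zero rank variance; the result is flagged
    ``undefined`` (rho and p are NaN) and a warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation needs at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), True)

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= 7:
        target = abs(rho) - 1e-12
        hits = sum(
            abs(_rho(rx, np.asarray(perm, dtype=float))) >= target
            for perm in itertools.permutations(ry)
        )
        return SpearmanResult(rho, hits / math.factorial(n), False)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, False)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, float(min(1.0, p)), False)


# ---------------------------------------------------------------------------
# group comparison with compact letter display
# ---------------------------------------------------------------------------

def _group_counts(batches: Iterable[BatchRecord], response: str) -> tuple[list[int], list[int]]:
    succ, tot = [], []
    for b in batches:
        if response == "male_ratio":
            succ.append(b.n_males)
            tot.append(b.n_sexed)
        elif response == "survival":
            succ.append(b.n_alive_31dpf)
            tot.append(b.n_stocked)
        else:
            raise ValidationError(f"unknown response {response!r}")
    return succ, tot


def _pair_lrt(s1, t1, s2, t2) -> float:
    """Likelihood-ratio p for equality of two binomial-logit group proportions.

    Each batch contributes a (successes, failures) row; the alternative model
    has an intercept plus a group indicator, the null an intercept only.
    """
    endog = np.array(
        [[s, t - s] for s, t in zip(s1, t1)] + [[s, t - s] for s, t in zip(s2, t2)],
        dtype=float,
    )
    group = np.array([0] * len(s1) + [1] * len(s2), dtype=float)
    x_alt = sm.add_constant(group)
    x_null = np.ones((len(group), 1))
    fam = sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        llf_alt = sm.GLM(endog, x_alt, family=fam).fit().llf
        llf_null = sm.GLM(endog, x_null, family=fam).fit().llf
    lr = max(0.0, 2.0 * (llf_alt - llf_null))
    return float(stats.chi2.sf(lr, 1))


def compare_groups_logistic(
    batches: Sequence[BatchRecord],
    grouping: str | Callable[[BatchRecord], str] = "population",
    response: str = "male_ratio",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise binomial-logit comparison of batch proportions with letters.

    Groups batches by ``grouping`` (an attribute name or a callable), tests
    every pair by a likelihood-ratio test on a logistic model of per-batch
    successes/failures, BH-adjusts the pairwise p-values, and summarizes with a
    compact letter display: two groups share a letter iff their adjusted
    p > alpha.

    When either group of a pair sits at 0 or 1 (complete separation, where the
    logit likelihood degenerates) the pair falls back to an exact Fisher test
    on pooled counts; the ``method`` column records which route was used.

    Returns
    -------
    (pairwise table, letters) where the table has columns
    group1, group2, p, adj_p, method and letters maps group -> letter string.
    """
    key = grouping if callable(grouping) else (lambda b: getattr(b, grouping))
    groups: dict[str, list[BatchRecord]] = {}
    for b in batches:
        groups.setdefault(key(b), []).append(b)
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups to compare")
    counts = {g: _group_counts(groups[g], response) for g in names}
    for g, (succ, tot) in counts.items():
        if sum(tot) == 0:
            raise ValidationError(f"group {g!r} has no denominator counts")

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        s1, t1 = counts[g1]
        s2, t2 = counts[g2]
        sep = any(sum(s) in (0, sum(t)) for s, t in ((s1, t1), (s2, t2)))
        if sep:
            p = fisher_exact_2x2(sum(s1), sum(t1) - sum(s1), sum(s2), sum(t2) - sum(s2))
            method = "fisher"
        else:
            p = _pair_lrt(s1, t1, s2, t2)
            method = "logit-lrt"
        rows.append({"group1": g1, "group2": g2, "p": p, "method": method})
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    significant = {
        frozenset((r.group1, r.group2))
        for r in table.itertuples()
        if r.adj_p <= alpha
    }
    letters = compact_letters(names, significant)
    return table, letters


# ---------------------------------------------------------------------------
# pairing and summaries
# ---------------------------------------------------------------------------

def pair_families(batches: Iterable[BatchRecord]) -> list[FamilyPair]:
    """Match each family's control and treated batches into :class:`FamilyPair`.

    Families missing either arm are skipped with a warning; duplicate arms are
    an error.
    """
    arms: dict[str, dict[str, BatchRecord]] = {}
    for b in batches:
        slot = arms.setdefault(b.family, {})
        if b.treatment in slot:
            raise ValidationError(f"family {b.family}: duplicate {b.treatment} batch")
        slot[b.treatment] = b
    pairs = []
    for fam, slot in arms.items():
        if "control" in slot and "ltherm" in slot:
            pairs.append(FamilyPair(fam, slot["control"], slot["ltherm"]))
        else:
            warnings.warn(f"family {fam}: missing arm, excluded from pairing", stacklevel=2)
    return pairs


def family_pair_table(pairs: Sequence[FamilyPair]) -> pd.DataFrame:
    """Per-family statistics: male ratios, survival, IR, RSR, Fisher and binomial p."""
    rows = []
    for fp in pairs:
        c, t = fp.control, fp.treated
        rows.append(
            {
                "population": fp.population,
                "family": fp.family,
                "male_ratio_control": c.male_ratio,
                "male_ratio_ltherm": t.male_ratio,
                "survival_control": c.survival_rate,
                "survival_ltherm": t.survival_rate,
                "ir": fp.ir,
                "rsr": fp.rsr,
                "fisher_p_sex": fisher_exact_2x2(
                    t.n_males, t.n_sexed - t.n_males, c.n_males, c.n_sexed - c.n_males
                ),
                "binomial_p_control_50_50": binomial_sexratio_test(c.n_males, c.n_sexed),
            }
        )
    return pd.DataFrame(rows)


def summarize_population(pairs: Sequence[FamilyPair], alpha: float = 0.05) -> pd.DataFrame:
    """Population x treatment male-ratio summary with letters and mean IR / RSR.

    Mean and sample SD (ddof=1; a single family reports SD 0), median and
    quartiles by linear interpolation, letters from the pooled logistic
    comparison of all population x treatment groups.
    """
    if not pairs:
        raise ValidationError("no family pairs to summarize")
    batches = [b for fp in pairs for b in (fp.control, fp.treated)]
    _, letters = compare_groups_logistic(
        batches, grouping=lambda b: f"{b.population}|{b.treatment}", alpha=alpha
    )
    rows = []
    pops = sorted({fp.population for fp in pairs})
    for pop in pops:
        fam_pairs = [fp for fp in pairs if fp.population == pop]
        for treatment in ("control", "ltherm"):
            vals = np.array(
                [
                    100.0 * getattr(fp, "control" if treatment == "control" else "treated").male_ratio
                    for fp in fam_pairs
                ]
            )
            rows.append(
                {
                    "population": pop,
                    "treatment": treatment,
                    "n_families": len(fam_pairs),
                    "n_sexed": sum(
                        getattr(fp, "control" if treatment == "control" else "treated").n_sexed
                        for fp in fam_pairs
                    ),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "median": float(np.median(vals)),
                    "p25": float(np.percentile(vals, 25)),
                    "p75": float(np.percentile(vals, 75)),
                    "letters": letters[f"{pop}|{treatment}"],
                    "mean_ir": float(np.mean([fp.ir for fp in fam_pairs])),
                    "mean_rsr": float(np.mean([fp.rsr for fp in fam_pairs])),
                }
            )
    return pd.DataFrame(rows)
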