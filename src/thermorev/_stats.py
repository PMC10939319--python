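"""Shared statistical primitives: FDR control, p-value aggregation, variance moderation.

The empirical-Bayes machinery follows the classic hierarchical model for gene-wise
residual variances: s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g with a scaled
inverse-chi-square prior sigma2_g ~ s0^2 * d0 / chi2(d0).  The prior parameters
(d0, s0^2) are estimated by matching the first two moments of log s2_g to the
log-F distribution implied by the model (digamma/trigamma inversion), and the
posterior variance is the degrees-of-freedom-weighted combination of the prior
and the observed variance.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

__all__ = ["bh_adjust", "simes_p", "trigamma_inverse", "squeeze_var", "compact_letters"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    Parameters
    ----------
    p : array-like of p-values in [0, 1].

    Returns
    -------
    ndarray of the same shape with monotone step-up adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1] and be non-missing")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def simes_p(p: np.ndarray) -> float:
    """Simes combination of per-hypothesis p-values into one global p-value.

    p_simes = min_i ( n * p_(i) / i ) over the sorted p-values; valid under
    independence or positive dependence, and the standard gene-level aggregation
    of per-exon splicing tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("Simes aggregation needs at least one p-value")
    ps = np.sort(p)
    n = ps.size
    return float(min(1.0, np.min(ps * n / np.arange(1, n + 1))))


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/trigamma.

    Mirrors the standard monotone-convergent scheme: iterate
    y <- y + delta with delta = trigamma(y) * (1 - trigamma(y)/x) / trigamma'(y).
    Returns a large value (~1e6) when x is so small that y overflows usefulness.
    """
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Moderate gene-wise variances toward a common prior.

    Estimates the prior degrees of freedom d0 and prior variance s0^2 by moment
    matching on z_g = log s2_g, then returns the posterior variances

        s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g).

    Returns
    -------
    (s2_post, d0, s0sq).  d0 is capped at 1e6 and treated as effectively
    infinite (full pooling) when the trigamma inversion underflows.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if not np.any(ok):
        raise ValidationError("all residual variances are zero; moderation impossible")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    n = e.size
    if n < 2:
        evar = 0.0
    else:
        evar = float(np.var(e, ddof=1) - np.mean(polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        d0 = min(d0, 1e6)
        s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = 1e6
        s0sq = float(np.exp(emean))
    s2_post = np.where(ok, (d0 * s0sq + df * s2) / (d0 + df), s0sq)
    return s2_post, float(d0), s0sq


def compact_letters(groups: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two groups share at least one letter iff their pair is NOT in
    ``significant``.  Starts from a single all-group letter column; every
    significant pair splits each column containing both; columns that become
    subsets of others are absorbed.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb subset columns
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # stable letter order: sort columns by earliest member in input order
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, col in enumerate(columns):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in col:
            letters[g].append(letter)
    return {g: "".join(sorted(ls)) if ls else "" for g, ls in letters.items()}
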