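"""Gene-level differential expression between treated and control batches.

The design has no within-condition replicates: each tissue x stage stratum
holds one control and one treated library per family (12 libraries for six
families).  Treatment effects are therefore estimated from a family-paired
linear model on log2-CPM,

    y_gs = intercept + treatment_s * beta_g + family-block effects + e_gs,

leaving 5 residual degrees of freedom per gene at six families.  Because
log-counts are heteroscedastic (low counts are noisier), each observation is
precision-weighted from a lowess mean-variance trend fitted across all genes,
and the gene-wise residual variances are moderated toward a common prior by
empirical Bayes before the treatment coefficient is tested with a moderated
t-statistic on augmented degrees of freedom.

The model surface is statsmodels-like: :class:`GeneExpressionLM` is built from
a normalized matrix and a design, ``fit()`` returns an :class:`LMFit` with
coefficients and unscaled standard errors, and ``LMFit.ebayes()`` returns a
:class:`ModeratedDEResults` carrying fold changes, moderated t, p-values, BH
FDR and a ``summary()`` table.  Thin functional wrappers (``cpm``,
``fit_weighted_lm``, ``estimate_precision_weights``, ``moderate_and_test``)
expose the individual steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._stats import bh_adjust, squeeze_var
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix", "cpm", "build_design", "filter_low_expression",
    "GeneExpressionLM", "LMFit", "ModeratedDEResults",
    "fit_weighted_lm", "estimate_precision_weights", "moderate_and_test",
    "de_pipeline", "bh_adjust",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """CPM or log2-CPM values with the library sizes they were scaled by."""

    values: pd.DataFrame
    libsizes: pd.Series
    log: bool
    prior_count: float


def cpm(counts: pd.DataFrame, log: bool = False, prior_count: float = 0.5,
        libsizes: pd.Series | None = None) -> NormalizedMatrix:
    """Counts-per-million normalization by library size.

    Un-logged: count / libsize * 1e6.  Logged:
    log2((count + prior_s) / (libsize_s + 2 * prior_s) * 1e6) where the prior
    count is scaled proportionally to each sample's library size
    (prior_s = prior_count * libsize_s / mean libsize), keeping zero counts
    finite and fold changes library-size-balanced.
    """
    if libsizes is None:
        libsizes = counts.sum(axis=0).astype(float)
    else:
        libsizes = libsizes.reindex(counts.columns).astype(float)
    if (libsizes <= 0).any():
        bad = libsizes.index[libsizes <= 0][0]
        raise ValidationError(f"sample {bad!r} has non-positive library size")
    mat = counts.to_numpy(dtype=float)
    lib = libsizes.to_numpy()
    if log:
        prior = prior_count * lib / lib.mean()
        vals = np.log2((mat + prior) / (lib + 2.0 * prior) * 1e6)
    else:
        vals = mat / lib * 1e6
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return NormalizedMatrix(out, libsizes, log, prior_count if log else 0.0)


def filter_low_expression(counts: pd.DataFrame, min_cpm: float = 1.0,
                          min_samples: int | None = None) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in at least min_samples samples
    (default: half the samples, rounded up)."""
    if min_samples is None:
        min_samples = (counts.shape[1] + 1) // 2
    c = cpm(counts).values
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def build_design(sheet: pd.DataFrame) -> pd.DataFrame:
    """Family-paired design for one stratum: intercept + treatment + family blocks.

    Rows are ordered as the sheet; the treatment column codes ltherm = 1.
    """
    fams = sorted(sheet["family"].unique())
    cols = {"intercept": np.ones(len(sheet)),
            "treatment": (sheet["treatment"] == "ltherm").astype(float).to_numpy()}
    for fam in fams[1:]:
        cols[f"family[{fam}]"] = (sheet["family"] == fam).astype(float).to_numpy()
    return pd.DataFrame(cols, index=sheet["sample_id"].to_numpy())


# ---------------------------------------------------------------------------
# the linear model
# ---------------------------------------------------------------------------

@dataclass
class LMFit:
    """Per-gene weighted least-squares fit.

    coefficients and stdev_unscaled are genes x coefficients; ``sigma`` is the
    residual standard deviation s_g on ``df_resid`` degrees of freedom;
    ``amean`` the mean log2 abundance per gene.  The unscaled standard error
    times s_g is the ordinary standard error of a coefficient.
    """

    coefficients: pd.DataFrame
    stdev_unscaled: pd.DataFrame
    sigma: pd.Series
    df_resid: float
    amean: pd.Series
    design: pd.DataFrame

    def ebayes(self, contrast: str = "treatment", alpha: float = 0.05,
               use_adjusted: bool = True, d0_override: float | None = None
               ) -> "ModeratedDEResults":
        return moderate_and_test(self, contrast, alpha=alpha,
                                 use_adjusted=use_adjusted, d0_override=d0_override)


class GeneExpressionLM:
    """Gene-wise linear model of log2-CPM on an experimental design.

    Parameters
    ----------
    logcpm : NormalizedMatrix or DataFrame of log2-CPM (genes x samples).
    design : DataFrame (samples x coefficients), full rank.
    weights : optional per-observation precision weights (genes x samples),
        e.g. from :func:`estimate_precision_weights`.
    """

    def __init__(self, logcpm, design: pd.DataFrame, weights: pd.DataFrame | None = None):
        vals = logcpm.values if isinstance(logcpm, NormalizedMatrix) else logcpm
        if list(vals.columns) != list(design.index):
            design = design.reindex(vals.columns)
            if design.isna().any().any():
                raise ValidationError("design rows do not match sample columns")
        x = design.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name aliased columns by pivoting the QR factorization
            _, r = np.linalg.qr(x)
            aliased = [design.columns[i] for i in range(x.shape[1])
                       if abs(r[i, i]) < 1e-10] if r.shape[0] >= x.shape[1] else list(
                           design.columns[rank:])
            raise ValidationError(f"design is rank deficient; aliased columns: {aliased}")
        if x.shape[0] - x.shape[1] < 1:
            raise ValidationError("at least one residual degree of freedom required")
        self.exog_names = list(design.columns)
        self.design = design
        self.y = vals
        self.weights = weights

    def fit(self) -> LMFit:
        y = self.y.to_numpy(dtype=float)
        x = self.design.to_numpy(dtype=float)
        n, p = x.shape
        g = y.shape[0]
        coef = np.empty((g, p))
        unscaled = np.empty((g, p))
        sigma = np.empty(g)
        if self.weights is None:
            # one shared projection: ordinary least squares for every gene
            xtx_inv = np.linalg.inv(x.T @ x)
            beta = y @ x @ xtx_inv.T
            resid = y - beta @ x.T
            rss = np.sum(resid**2, axis=1)
            coef = beta
            unscaled[:] = np.sqrt(np.diag(xtx_inv))
            sigma = np.sqrt(rss / (n - p))
        else:
            w = self.weights.to_numpy(dtype=float)
            if w.shape != y.shape or np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValidationError("weights must be positive, finite, genes x samples")
            for i in range(g):
                wx = x * w[i][:, None]
                xtwx = x.T @ wx
                xtwx_inv = np.linalg.inv(xtwx)
                b = xtwx_inv @ (wx.T @ y[i])
                r = y[i] - x @ b
                rss = float(np.sum(w[i] * r * r))
                coef[i] = b
                unscaled[i] = np.sqrt(np.diag(xtwx_inv))
                sigma[i] = np.sqrt(rss / (n - p))
        idx = self.y.index
        return LMFit(
            coefficients=pd.DataFrame(coef, index=idx, columns=self.exog_names),
            stdev_unscaled=pd.DataFrame(unscaled, index=idx, columns=self.exog_names),
            sigma=pd.Series(sigma, index=idx, name="sigma"),
            df_resid=float(n - p),
            amean=pd.Series(y.mean(axis=1), index=idx, name="amean"),
            design=self.design,
        )


def fit_weighted_lm(logcpm, design: pd.DataFrame,
                    weights: pd.DataFrame | None = None) -> LMFit:
    """Functional wrapper: per-gene weighted least squares (OLS at unit weights)."""
    return GeneExpressionLM(logcpm, design, weights).fit()


# ---------------------------------------------------------------------------
# precision weights (mean-variance trend)
# ---------------------------------------------------------------------------

def estimate_precision_weights(
    counts: pd.DataFrame, design: pd.DataFrame, span: float = 0.5,
    min_genes: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-observation precision weights from the count mean-variance trend.

    Fits an unweighted gene-wise model to log2-CPM (prior 0.5), regresses the
    square root of each gene's residual standard deviation on its mean log2
    count by lowess, evaluates the trend at every observation's fitted log2
    count, and returns weight = predicted^-4 — so noisier (low-abundance)
    observations are down-weighted in the final fit.

    Returns
    -------
    (weights, trend) where weights is genes x samples and trend is the
    (mean log2 count, sqrt sd) lowess curve.

    Falls back to unit weights with a warning when fewer than ``min_genes``
    genes are available (the trend would not be stable).
    """
    if counts.shape[0] < min_genes:
        warnings.warn(
            f"only {counts.shape[0]} genes (< {min_genes}); using unit weights",
            stacklevel=2,
        )
        logger.warning("precision weights skipped: %d genes < %d", counts.shape[0], min_genes)
        unit = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
        return unit, pd.DataFrame(columns=["mean_log2_count", "sqrt_sd"])

    lib = counts.sum(axis=0).astype(float)
    norm = cpm(counts, log=True, prior_count=0.5, libsizes=lib + 1.0)
    fit = fit_weighted_lm(norm, design)
    # mean log2 count per gene: mean log2-CPM shifted back by the average library
    sx = fit.amean.to_numpy() + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(fit.sigma.to_numpy())
    curve = lowess(sy, sx, frac=span, return_sorted=True)
    cx, cy = curve[:, 0], np.maximum(curve[:, 1], 1e-6)

    x = fit.design.to_numpy(dtype=float)
    fitted_logcpm = fit.coefficients.to_numpy() @ x.T
    fitted_logcount = fitted_logcpm + np.log2(lib.to_numpy() + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_logcount, cx, cy)  # constant beyond the trend range
    w = pred**-4.0
    weights = pd.DataFrame(w, index=counts.index, columns=counts.columns)
    trend = pd.DataFrame({"mean_log2_count": cx, "sqrt_sd": cy})
    return weights, trend


# ---------------------------------------------------------------------------
# moderation and testing
# ---------------------------------------------------------------------------

@dataclass
class ModeratedDEResults:
    """Moderated-t test results for one contrast.

    ``table`` columns: logFC, t, p, adj_p, direction ('up'/'down'/'none').
    ``d0`` and ``s0sq`` are the estimated prior degrees of freedom and prior
    variance; ``s2_post`` the posterior (moderated) variances; ``df_total``
    the augmented degrees of freedom of the t reference distribution.
    """

    table: pd.DataFrame
    d0: float
    s0sq: float
    s2_post: pd.Series
    df_total: float
    contrast: str
    alpha: float
    use_adjusted: bool

    @property
    def degs(self) -> pd.Index:
        col = "adj_p" if self.use_adjusted else "p"
        return self.table.index[self.table[col] <= self.alpha]

    def summary(self, n: int = 10) -> str:
        t = self.table
        n_up = int(((t["direction"] == "up")).sum())
        n_dn = int(((t["direction"] == "down")).sum())
        crit = "adjusted" if self.use_adjusted else "raw"
        lines = [
            "Moderated differential expression"
            f" (contrast: {self.contrast}, {crit} p <= {self.alpha})",
            f"genes tested: {len(t)}   prior df d0: {self.d0:.3g}"
            f"   prior variance s0^2: {self.s0sq:.4g}",
            f"DEGs: {n_up + n_dn} ({n_up} up, {n_dn} down)",
            "",
            t.sort_values("p").head(n).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def moderate_and_test(fit: LMFit, contrast: str = "treatment", alpha: float = 0.05,
                      use_adjusted: bool = True, d0_override: float | None = None
                      ) -> ModeratedDEResults:
    """Empirical-Bayes moderated t-test of one coefficient.

    Shrinks gene-wise residual variances toward a common prior estimated by
    moment-matching log s2_g against a scaled-F model; the moderated t is the
    coefficient over (unscaled se * posterior sd) on d0 + d_g degrees of
    freedom.  ``d0_override`` forces the prior df (0 recovers the ordinary t).
    """
    if contrast not in fit.coefficients.columns:
        raise ValidationError(f"contrast {contrast!r} not among {list(fit.coefficients.columns)}")
    if len(fit.coefficients) < 2:
        raise ValidationError("moderation needs at least 2 genes")
    s2 = fit.sigma.to_numpy() ** 2
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 > 0:
            # prior variance still from moment matching for the pooling target
            _, _, s0sq = squeeze_var(s2, fit.df_resid)
        else:
            s0sq = float("nan")
        s2_post = (d0 * (0.0 if np.isnan(s0sq) else s0sq) + fit.df_resid * s2) / (
            d0 + fit.df_resid)
    else:
        s2_post, d0, s0sq = squeeze_var(s2, fit.df_resid)
    df_total = d0 + fit.df_resid
    beta = fit.coefficients[contrast].to_numpy()
    se = fit.stdev_unscaled[contrast].to_numpy() * np.sqrt(s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    if np.isinf(df_total) or df_total > 1e6:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.minimum(p, 1.0)
    adj = bh_adjust(p)
    crit = adj if use_adjusted else p
    direction = np.where(crit <= alpha, np.where(beta > 0, "up", "down"), "none")
    direction = np.where((crit <= alpha) & (beta == 0), "none", direction)
    table = pd.DataFrame(
        {"logFC": beta, "t": tstat, "p": p, "adj_p": adj, "direction": direction},
        index=fit.coefficients.index,
    )
    return ModeratedDEResults(table, float(d0), float(s0sq),
                              pd.Series(s2_post, index=fit.coefficients.index),
                              float(df_total), contrast, alpha, use_adjusted)


# ---------------------------------------------------------------------------
# end-to-end stratum pipeline
# ---------------------------------------------------------------------------

def de_pipeline(gene_counts: pd.DataFrame, sheet: pd.DataFrame, tissue: str,
                stage: int, alpha: float = 0.05, use_adjusted: bool = True,
                min_cpm: float = 1.0, min_samples: int | None = None
                ) -> ModeratedDEResults:
    """Full DE chain for one tissue x stage stratum.

    Subsets the samples, filters low-expression genes, estimates precision
    weights, fits the family-paired model and returns moderated test results
    for the treatment coefficient.
    """
    sub = sheet[(sheet["tissue"] == tissue) & (sheet["stage_dpf"] == stage)]
    if sub.empty:
        raise ValidationError(f"no samples for stratum ({tissue}, {stage})")
    counts = gene_counts[sub["sample_id"].to_numpy()]
    counts = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples)
    design = build_design(sub)
    weights, _ = estimate_precision_weights(counts, design)
    norm = cpm(counts, log=True, prior_count=0.5,
               libsizes=counts.sum(axis=0).astype(float) + 1.0)
    fit = GeneExpressionLM(norm, design, weights).fit()
    return fit.ebayes("treatment", alpha=alpha, use_adjusted=use_adjusted)
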