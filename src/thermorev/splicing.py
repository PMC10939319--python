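"""Exon-level differential splicing between treated and control batches.

A gene whose isoform usage shifts under treatment shows it as an exon whose
treatment fold change deviates from the gene's overall fold change.  The test
therefore fits the same family-paired precision-weighted model as the
gene-level analysis, but at exon resolution, and for every exon forms the
*deviation* log2 fold change — its treatment coefficient minus the average
coefficient of the gene's other exons.  Each deviation gets a moderated
t-statistic; per gene, the exon p-values are aggregated by the Simes rule, and
genes are called differentially spliced (DSG) at a BH FDR of 0.05.

The deviation construction makes the test invariant to adding any constant to
all of a gene's exon fold changes: pure differential *expression* never
creates a splicing signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, simes_p, squeeze_var
from .diffexp import (NormalizedMatrix, build_design, cpm,
                      estimate_precision_weights, fit_weighted_lm)
from .exceptions import ValidationError

__all__ = ["DSResults", "splice_test"]


@dataclass
class DSResults:
    """Gene-level splicing calls plus the per-exon evidence behind them.

    ``table`` (per gene): best_exon, deviation_logFC, gene_p, adj_p, dsg.
    ``exon_table`` (per exon): deviation_logFC, t, p.
    ``skipped`` lists genes excluded for having a single (usable) exon.
    """

    table: pd.DataFrame
    exon_table: pd.DataFrame
    skipped: list[str]

    @property
    def dsgs(self) -> pd.Index:
        return self.table.index[self.table["dsg"]]


def splice_test(
    exon_counts: pd.DataFrame,
    sheet: pd.DataFrame,
    tissue: str,
    stage: int,
    fdr: float = 0.05,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    gene_ids: pd.Index | None = None,
) -> DSResults:
    """Differential-splicing screen for one tissue x stage stratum.

    Parameters
    ----------
    exon_counts : DataFrame indexed by (gene_id, exon_id).
    gene_ids : optional gene universe; exons of genes outside it raise a
        key-mismatch error (guards against exon tables from a different
        annotation build than the gene table).
    """
    if not isinstance(exon_counts.index, pd.MultiIndex) or \
            exon_counts.index.names != ["gene_id", "exon_id"]:
        raise ValidationError("exon counts must be indexed by (gene_id, exon_id)")
    if gene_ids is not None:
        stray = exon_counts.index.get_level_values("gene_id").unique().difference(gene_ids)
        if len(stray):
            raise ValidationError(
                f"exon table contains genes absent from the gene table, e.g. {stray[:5].tolist()}"
            )
    sub = sheet[(sheet["tissue"] == tissue) & (sheet["stage_dpf"] == stage)]
    if sub.empty:
        raise ValidationError(f"no samples for stratum ({tissue}, {stage})")
    counts = exon_counts[sub["sample_id"].to_numpy()]

    # low-expression filter at exon level, then require >= 2 usable exons
    if min_samples is None:
        min_samples = (counts.shape[1] + 1) // 2
    c = cpm(counts).values
    counts = counts.loc[(c >= min_cpm).sum(axis=1).to_numpy() >= min_samples]
    n_exons = counts.groupby(level="gene_id", sort=False).size()
    skipped = sorted(n_exons.index[n_exons < 2])
    if skipped:
        warnings.warn(f"{len(skipped)} single-exon genes skipped by the splice test",
                      stacklevel=2)
    counts = counts.loc[counts.index.get_level_values("gene_id").isin(
        n_exons.index[n_exons >= 2])]
    if counts.empty:
        raise ValidationError("no multi-exon genes left after filtering")

    design = build_design(sub)
    weights, _ = estimate_precision_weights(counts, design)
    norm = cpm(counts, log=True, prior_count=0.5,
               libsizes=counts.sum(axis=0).astype(float) + 1.0)
    fit = fit_weighted_lm(norm, design, weights)

    beta = fit.coefficients["treatment"].to_numpy()
    u = fit.stdev_unscaled["treatment"].to_numpy()
    s2_post, d0, _ = squeeze_var(fit.sigma.to_numpy() ** 2, fit.df_resid)
    var = u * u * s2_post
    df_total = min(d0 + fit.df_resid, 1e6)

    groups = pd.Series(np.arange(len(counts)), index=counts.index).groupby(
        level="gene_id", sort=False)

    dev = np.empty_like(beta)
    dev_var = np.empty_like(beta)
    for _, pos in groups:
        ix = pos.to_numpy()
        m = ix.size
        tot = beta[ix].sum()
        vtot = var[ix].sum()
        other_mean = (tot - beta[ix]) / (m - 1)
        dev[ix] = beta[ix] - other_mean
        dev_var[ix] = var[ix] + (vtot - var[ix]) / (m - 1) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(dev_var > 0, dev / np.sqrt(dev_var), 0.0)
    p_exon = np.minimum(2.0 * stats.t.sf(np.abs(tstat), df_total), 1.0)

    exon_table = pd.DataFrame(
        {"deviation_logFC": dev, "t": tstat, "p": p_exon}, index=counts.index
    )

    gene_rows = []
    for gene, sub_t in exon_table.groupby(level="gene_id", sort=False):
        ps = sub_t["p"].to_numpy()
        best = sub_t["p"].idxmin()
        gene_rows.append(
            {"gene_id": gene, "best_exon": best[1],
             "deviation_logFC": float(sub_t.loc[best, "deviation_logFC"]),
             "gene_p": simes_p(ps)}
        )
    table = pd.DataFrame(gene_rows).set_index("gene_id")
    table["adj_p"] = bh_adjust(table["gene_p"].to_numpy())
    table["dsg"] = table["adj_p"] <= fdr
    return DSResults(table, exon_table, skipped)
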