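"""Screen for genes whose treatment response tracks the family reversal rate.

Because the sequenced families span very different reversal rates (IR from 12%
to 100% in the emulated design), a gene mechanistically tied to sex reversal
should respond to the treatment *more* in families that reversed more.  The
screen builds, per family, the log2(Ltherm / Control) fold change from
prior-counted log2-CPM (finite even at zero counts), and correlates each
gene's fold-change profile with the family IR vector by Pearson correlation.
With n families the p-value comes from t = r * sqrt((n-2)/(1-r^2)) on n - 2
degrees of freedom; a gene is called +Corr / -Corr when p <= alpha (raw p by
default — the screen is a hypothesis generator, not a confirmatory test).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import NormalizedMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["family_fold_changes", "trait_correlation"]


def family_fold_changes(
    logcpm: NormalizedMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    tissue: str,
    stage: int,
) -> pd.DataFrame:
    """Per-family treatment log2 fold-change matrix for one tissue x stage stratum.

    Entry (gene, family) = log2CPM(ltherm sample) - log2CPM(control sample).
    Families missing either arm in the stratum are excluded with a warning;
    columns follow the sample-sheet family order.
    """
    vals = logcpm.values if isinstance(logcpm, NormalizedMatrix) else logcpm
    if isinstance(logcpm, NormalizedMatrix) and not logcpm.log:
        raise ValidationError("fold changes need log-scale CPM values")
    sub = sheet[(sheet["tissue"] == tissue) & (sheet["stage_dpf"] == stage)]
    if sub.empty:
        raise ValidationError(f"no samples for stratum ({tissue}, {stage})")
    cols = {}
    for fam in sub["family"].drop_duplicates():
        arms = sub[sub["family"] == fam].set_index("treatment")["sample_id"]
        if "control" not in arms.index or "ltherm" not in arms.index:
            warnings.warn(f"family {fam}: incomplete pair in ({tissue}, {stage}), excluded",
                          stacklevel=2)
            logger.warning("family %s excluded from fold changes (missing arm)", fam)
            continue
        cols[fam] = vals[arms["ltherm"]].to_numpy() - vals[arms["control"]].to_numpy()
    if not cols:
        raise ValidationError(f"no complete control/ltherm family pair in ({tissue}, {stage})")
    fcm = pd.DataFrame(cols, index=vals.index)
    if not np.all(np.isfinite(fcm.to_numpy())):
        raise ValidationError("non-finite fold changes; use prior-counted log2-CPM")
    return fcm


def trait_correlation(
    fcm: pd.DataFrame, trait: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Pearson correlation of fold-change profiles against the IR trait.

    Returns a DataFrame (gene, r, p, sign) where sign is '+' / '-' when
    p <= alpha with the matching direction and 'none' otherwise.  Genes with a
    constant fold-change profile have undefined correlation: r and p are NaN
    and sign 'none'.  The correlation is invariant to affine rescaling of the
    trait (IR in percent or as a fraction gives identical results).
    """
    if len(fcm.columns) < 3:
        raise ValidationError("need at least 3 families for the correlation screen")
    missing = set(fcm.columns) - set(trait.index)
    if missing:
        raise ValidationError(f"trait vector missing families: {sorted(missing)}")
    y = trait.reindex(fcm.columns).to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("trait is constant; correlation undefined for every gene")
    x = fcm.to_numpy(dtype=float)
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc, axis=1))
    sy = np.sqrt(np.sum(yc * yc))
    degenerate = np.ptp(x, axis=1) == 0
    sx = np.where(degenerate, 0.0, sx)
    if degenerate.any():
        logger.warning("%d genes with constant fold change: correlation undefined",
                       int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    r = np.where(degenerate, np.nan, r)
    p = np.where(degenerate, np.nan, np.minimum(p, 1.0))
    sig = ~degenerate & (p <= alpha)
    sign = np.where(sig & (r > 0), "+", np.where(sig & (r < 0), "-", "none"))
    return pd.DataFrame({"r": r, "p": p, "sign": sign}, index=fcm.index)
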