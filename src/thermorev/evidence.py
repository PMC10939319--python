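"""Integration of DEG, DSG and IR-correlation calls into per-gene evidence.

Each gene analysed in a stratum gets three calls — differential-expression
direction (up/down/none), a differential-splicing flag, and an IR-correlation
sign (+/-/none) — rendered in the study's status notation:

* ``↑Exp`` / ``↓Exp``: significant up- / downregulation;
* ``↑exp`` / ``↓exp``: the same direction without significance (the lower-case
  form carries the sign of the non-significant fold change);
* ``+Corr`` / ``-Corr``: significant positive / negative correlation with the
  family reversal rate; ``No_Corr`` otherwise;
* ``DSG`` appended when the splicing flag is set.

On top of the table sit the three-set Venn partition (exclusive region counts)
and the cross-reference against a curated list of sex-differentiation genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "EVIDENCE_COLUMNS", "build_evidence", "render_status", "parse_status",
    "VennPartition", "venn_counts", "crossref_genes_of_interest",
    "filter_by_status", "DEFAULT_CURATED_GENES", "DEFAULT_SYNONYMS",
]

EVIDENCE_COLUMNS = ["deg_direction", "adj_p", "logFC", "dsg", "corr_sign", "r", "status"]

#: curated sex-differentiation / maturation genes cross-referenced by default
DEFAULT_CURATED_GENES = (
    "dmrt1", "esr1", "esr2", "cyp11c1", "gth-ri", "gth-rii", "hsd11b1Ia(2)",
    "amh", "dax1", "cyp19a1a", "cyp19a1b", "ara", "cyp21a2", "ihcgr",
    "bmpr2(1)", "bmpr2(2)", "sf1", "foxl2",
)

#: spelling variants resolved to one table id each
DEFAULT_SYNONYMS = {
    "hsd11b1Ia(2)": ("hsd11b1la(2)", "hsd11b1lac(2)"),
    "dax1": ("nr0b1",),
    "sf1": ("nr5a1",),
}


def render_status(deg_direction: str, logfc: float, corr_sign: str) -> str:
    """Status string from the three calls plus the non-significant fold-change sign."""
    if deg_direction == "up":
        exp = "↑Exp"
    elif deg_direction == "down":
        exp = "↓Exp"
    else:
        exp = "↑exp" if (logfc is not None and not np.isnan(logfc) and logfc >= 0) \
            else "↓exp"
    corr = {"+": "+Corr", "-": "-Corr"}.get(corr_sign, "No_Corr")
    return f"{exp} and {corr}"


def parse_status(status: str) -> tuple[str, str, str]:
    """Invert :func:`render_status` -> (deg_direction, fc_sign, corr_sign)."""
    try:
        exp, corr = status.split(" and ")
    except ValueError as err:
        raise ValidationError(f"malformed status string {status!r}") from err
    table = {"↑Exp": ("up", "+"), "↓Exp": ("down", "-"),
             "↑exp": ("none", "+"), "↓exp": ("none", "-")}
    if exp not in table:
        raise ValidationError(f"unknown expression token {exp!r}")
    deg, fc_sign = table[exp]
    corr_map = {"+Corr": "+", "-Corr": "-", "No_Corr": "none"}
    if corr not in corr_map:
        raise ValidationError(f"unknown correlation token {corr!r}")
    return deg, fc_sign, corr_map[corr]


def build_evidence(
    de_table: pd.DataFrame,
    ds_table: pd.DataFrame | None,
    corr_table: pd.DataFrame | None,
) -> pd.DataFrame:
    """Merge DE, splicing and correlation results into one evidence table.

    Indexed by gene; genes present in any input appear.  Missing calls default
    to 'none' / False / NaN.
    """
    idx = de_table.index
    if ds_table is not None:
        idx = idx.union(ds_table.index)
    if corr_table is not None:
        idx = idx.union(corr_table.index)
    ev = pd.DataFrame(index=idx)
    ev["deg_direction"] = de_table["direction"].reindex(idx).fillna("none")
    ev["adj_p"] = de_table["adj_p"].reindex(idx)
    ev["logFC"] = de_table["logFC"].reindex(idx)
    ev["dsg"] = (ds_table["dsg"].reindex(idx).fillna(False).astype(bool)
                 if ds_table is not None else False)
    ev["corr_sign"] = (corr_table["sign"].reindex(idx).fillna("none")
                       if corr_table is not None else "none")
    ev["r"] = corr_table["r"].reindex(idx) if corr_table is not None else np.nan
    ev["status"] = [
        render_status(d, f, c) + (" and DSG" if s else "")
        for d, f, c, s in zip(ev["deg_direction"], ev["logFC"], ev["corr_sign"], ev["dsg"])
    ]
    return ev[EVIDENCE_COLUMNS]


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VennPartition:
    """Exclusive region counts of the DEG / DSG / Corr three-set Venn diagram."""

    deg_only: int
    dsg_only: int
    corr_only: int
    deg_dsg: int
    deg_corr: int
    dsg_corr: int
    all_three: int

    @property
    def union_size(self) -> int:
        return (self.deg_only + self.dsg_only + self.corr_only + self.deg_dsg
                + self.deg_corr + self.dsg_corr + self.all_three)

    def as_dict(self) -> dict[str, int]:
        return {
            "deg_only": self.deg_only, "dsg_only": self.dsg_only,
            "corr_only": self.corr_only, "deg_dsg": self.deg_dsg,
            "deg_corr": self.deg_corr, "dsg_corr": self.dsg_corr,
            "all_three": self.all_three, "union": self.union_size,
        }


def venn_counts(deg: set, dsg: set, corr: set) -> VennPartition:
    """Exact partition of deg | dsg | corr into the 7 exclusive Venn regions."""
    deg, dsg, corr = set(deg), set(dsg), set(corr)
    abc = deg & dsg & corr
    return VennPartition(
        deg_only=len(deg - dsg - corr),
        dsg_only=len(dsg - deg - corr),
        corr_only=len(corr - deg - dsg),
        deg_dsg=len((deg & dsg) - abc),
        deg_corr=len((deg & corr) - abc),
        dsg_corr=len((dsg & corr) - abc),
        all_three=len(abc),
    )


# ---------------------------------------------------------------------------
# curated cross-reference and status filtering
# ---------------------------------------------------------------------------

def crossref_genes_of_interest(
    evidence: pd.DataFrame,
    curated: tuple[str, ...] | list[str] = DEFAULT_CURATED_GENES,
    synonyms: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Look curated genes up in the evidence table, resolving spelling variants.

    Each curated entry may match the table under its own name or any synonym;
    more than one distinct match is an ambiguity error listing the candidates.
    Returns per curated gene: present flag, resolved id, status, r, logFC.
    """
    if not curated:
        raise ValidationError("curated gene list is empty")
    synonyms = DEFAULT_SYNONYMS if synonyms is None else synonyms
    rows = []
    for name in curated:
        candidates = [name, *synonyms.get(name, ())]
        hits = [c for c in candidates if c in evidence.index]
        if len(set(hits)) > 1:
            raise ValidationError(f"curated gene {name!r} resolves ambiguously: {hits}")
        if hits:
            g = hits[0]
            rows.append({"curated": name, "present": True, "resolved_id": g,
                         "status": evidence.loc[g, "status"],
                         "r": evidence.loc[g, "r"], "logFC": evidence.loc[g, "logFC"]})
        else:
            rows.append({"curated": name, "present": False, "resolved_id": None,
                         "status": "absent", "r": np.nan, "logFC": np.nan})
    return pd.DataFrame(rows).set_index("curated")


def filter_by_status(evidence: pd.DataFrame, predicate) -> list[str]:
    """Genes matching a predicate over evidence rows, ordered by adjusted p then id.

    ``predicate`` receives a row (pd.Series) and returns bool; e.g.
    ``lambda r: r.deg_direction != 'none' and r.corr_sign != 'none'`` selects
    the DEG-and-Corr intersection.
    """
    hits = [g for g, row in evidence.iterrows() if predicate(row)]
    key = evidence.loc[hits, "adj_p"].fillna(np.inf)
    return sorted(hits, key=lambda g: (key[g], str(g)))
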