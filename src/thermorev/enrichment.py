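"""Over-representation analysis of categorized gene lists against term databases.

Three pieces: (1) majority-vote resolution of identifier mappings drawn from
several annotation sources (the association referenced by the most sources
wins; ties are dropped with a warning), (2) ortholog-based annotation
augmentation (a gene inherits the union of its own terms and its ortholog's
terms in a better-annotated donor species), and (3) the upper-tail
hypergeometric over-representation test per term with BH FDR across terms.

The universe is the set of genes that entered the stratum's analysis
(post-filter), not the whole genome — the standard guard against detection
bias.  Gene lists are categorized by evidence class: ↑Exp, ↓Exp, +Corr,
-Corr and DSG, each tested against the shared universe.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .exceptions import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["resolve_ids", "augment_by_ortholog", "hypergeom_enrich", "run_categorized",
           "CATEGORIES"]

CATEGORIES = ("↑Exp", "↓Exp", "+Corr", "-Corr", "DSG")


def resolve_ids(tables: pd.DataFrame | Iterable[pd.DataFrame]) -> dict[str, str]:
    """Majority-vote identifier resolution across mapping sources.

    For each from_id, keep the to_id referenced by the most sources; exact
    ties are dropped (warned, not raised) so the result is a function.
    Idempotent: resolving an already-resolved single-source table returns it.
    """
    if isinstance(tables, pd.DataFrame):
        merged = tables
    else:
        frames = list(tables)
        if not frames:
            raise ValidationError("need at least one mapping table")
        merged = pd.concat(frames, ignore_index=True)
    votes = (
        merged.drop_duplicates(["source", "from_id", "to_id"])
        .groupby(["from_id", "to_id"]).size()
    )
    resolved: dict[str, str] = {}
    dropped = []
    for from_id, sub in votes.groupby(level="from_id"):
        counts = sub.droplevel("from_id").sort_values(ascending=False)
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            dropped.append(from_id)
            continue
        resolved[str(from_id)] = str(counts.index[0])
    if dropped:
        logger.warning("%d ids dropped in majority-vote resolution (ties): e.g. %s",
                       len(dropped), dropped[:5])
    return resolved


def augment_by_ortholog(
    native: GeneSetCollection,
    ortholog_map: Mapping[str, str],
    donor: GeneSetCollection,
) -> GeneSetCollection:
    """Expand a native annotation with the donor terms of each gene's ortholog.

    Per gene the term set becomes native terms UNION donor terms of its
    ortholog; genes without an ortholog (or whose ortholog is unannotated) are
    unchanged.  Term names come from the native collection when the term
    exists there, else from the donor.
    """
    by_gene = native.annotations_by_gene()
    donor_by_gene = donor.annotations_by_gene()
    for gene, ortholog in ortholog_map.items():
        extra = donor_by_gene.get(ortholog, set())
        if extra:
            by_gene.setdefault(gene, set()).update(extra)
    out = GeneSetCollection()
    term_members: dict[str, set[str]] = {}
    for gene, terms in by_gene.items():
        for term in terms:
            term_members.setdefault(term, set()).add(gene)
    for term in sorted(term_members):
        name = native.names.get(term, donor.names.get(term, term))
        out.add(term, name, term_members[term])
    return out


def hypergeom_enrich(
    gene_list: Iterable[str],
    universe: Iterable[str],
    annotation: GeneSetCollection,
    min_term_size: int = 5,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For a term annotating K of the N universe genes, with n list genes of
    which k fall in the term, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    Terms are restricted to the universe before the size bounds apply; BH
    adjustment runs across the tested terms.  Columns: term, name, k, K, n, N,
    p, adj_p, fold (the (k/n)/(K/N) fold enrichment).
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list or not universe:
        raise ValidationError("gene list and universe must be non-empty")
    if not gene_list <= universe:
        stray = sorted(gene_list - universe)[:5]
        raise ValidationError(f"gene list not contained in universe, e.g. {stray}")
    n_univ = len(universe)
    n_list = len(gene_list)
    rows = []
    for term in annotation.terms():
        members = annotation.genes_of(term) & universe
        big_k = len(members)
        if not (min_term_size <= big_k <= max_term_size):
            continue
        k = len(members & gene_list)
        p = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_list))
        fold = (k / n_list) / (big_k / n_univ) if big_k else float("nan")
        rows.append({"term": term, "name": annotation.names[term],
                     "k": k, "K": big_k, "n": n_list, "N": n_univ,
                     "p": min(1.0, p), "fold": fold})
    result = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p", "fold"])
    result["adj_p"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    return result[["term", "name", "k", "K", "n", "N", "p", "adj_p", "fold"]]


def categorize_evidence(evidence: pd.DataFrame) -> dict[str, list[str]]:
    """Evidence table -> the five category gene lists (a gene may appear in
    several, e.g. ↑Exp and +Corr simultaneously)."""
    return {
        "↑Exp": list(evidence.index[evidence["deg_direction"] == "up"]),
        "↓Exp": list(evidence.index[evidence["deg_direction"] == "down"]),
        "+Corr": list(evidence.index[evidence["corr_sign"] == "+"]),
        "-Corr": list(evidence.index[evidence["corr_sign"] == "-"]),
        "DSG": list(evidence.index[evidence["dsg"].astype(bool)]),
    }


def run_categorized(
    evidence: pd.DataFrame,
    annotation: GeneSetCollection,
    universe: Iterable[str],
    min_term_size: int = 5,
    max_term_size: int = 500,
) -> dict[str, pd.DataFrame]:
    """Per-category over-representation runs against a shared universe.

    Empty categories are skipped (logged).  Each returned table carries a
    ``category`` column and equals a direct :func:`hypergeom_enrich` call on
    that category's list.
    """
    if evidence.empty:
        raise ValidationError("evidence table is empty")
    out: dict[str, pd.DataFrame] = {}
    for category, genes in categorize_evidence(evidence).items():
        if not genes:
            logger.info("category %s empty; skipped", category)
            continue
        res = hypergeom_enrich(genes, universe, annotation,
                               min_term_size=min_term_size, max_term_size=max_term_size)
        res.insert(0, "category", category)
        out[category] = res
    return out
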