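"""Co-expression networks over per-family treatment-response profiles.

Genes are compared not by expression but by *response*: each gene's profile is
its vector of per-family log2(Ltherm/Control) fold changes.  The adjacency is
the soft-thresholded unsigned similarity |cor|^beta — co-regulation in
opposite directions counts fully, and the power (default 6, the usual unsigned
convention) suppresses weak correlations while preserving the ranking.  A
seed-gene network keeps the seed plus its k strongest partners (default 19,
a 20-node neighborhood), with node annotations carrying differential-
expression direction and IR-correlation sign from the evidence table.
"""

from __future__ import annotations

import difflib
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["adjacency", "seed_network", "DEFAULT_SEED_GENES"]

#: default seed list: the study's ten genes of interest for sex differentiation
DEFAULT_SEED_GENES = (
    "amh", "cyp11c1", "cyp19a1a", "cyp19a1b", "dmrt1", "hsd11b1la",
    "hsd11b1lac(2)", "dax1", "sf1", "hsd11b2",
)


def adjacency(fcm: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta over family profiles.

    Genes with zero profile variance are excluded (logged); the result is
    symmetric with unit diagonal, entries in [0, 1].
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    if fcm.shape[1] < 3:
        raise ValidationError("adjacency needs at least 3 family columns")
    x = fcm.to_numpy(dtype=float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        logger.warning("%d zero-variance genes excluded from adjacency",
                       int((~keep).sum()))
    x = x[keep]
    genes = fcm.index[keep]
    if len(genes) == 0:
        raise ValidationError("no genes with non-zero profile variance")
    r = np.corrcoef(x)
    r = np.atleast_2d(r)
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def seed_network(
    adj: pd.DataFrame,
    seed_gene: str,
    k: int = 19,
    evidence: pd.DataFrame | None = None,
    partner_edge_floor: float = 0.1,
) -> nx.Graph:
    """The k-strongest-partner neighborhood of a seed gene.

    Partners are the k genes with largest adjacency to the seed, ties broken
    lexicographically by gene id.  Seed-partner edges always appear, weighted
    by adjacency; partner-partner edges appear when their adjacency reaches
    ``partner_edge_floor``.  Node attributes ``deg_direction`` (up/down/none),
    ``corr_sign`` (+/-/none) and ``is_seed`` come from the evidence table when
    given.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if seed_gene not in adj.index:
        near = difflib.get_close_matches(seed_gene, [str(g) for g in adj.index], n=5)
        raise ValidationError(
            f"seed gene {seed_gene!r} not in the adjacency matrix; near matches: {near}"
        )
    others = adj.index[adj.index != seed_gene]
    if len(others) < k:
        raise ValidationError(f"only {len(others)} candidate partners for k={k}")
    w = adj.loc[seed_gene, others]
    ranked = sorted(zip(-w.to_numpy(dtype=float), others.astype(str)))
    partners = [g for _, g in ranked[:k]]

    g = nx.Graph()
    for node in [seed_gene, *partners]:
        deg, corr = "none", "none"
        if evidence is not None and node in evidence.index:
            deg = str(evidence.loc[node, "deg_direction"])
            corr = str(evidence.loc[node, "corr_sign"])
        g.add_node(node, deg_direction=deg, corr_sign=corr,
                   is_seed=bool(node == seed_gene))
    for p in partners:
        g.add_edge(seed_gene, p, weight=float(adj.loc[seed_gene, p]))
    for i, p1 in enumerate(partners):
        for p2 in partners[i + 1:]:
            wpp = float(adj.loc[p1, p2])
            if wpp >= partner_edge_floor:
                g.add_edge(p1, p2, weight=wpp)
    return g
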