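"""Readers and writers for every file the pipeline touches.

Conventions: matrices are TSV (no quoting), metadata sheets are CSV, gene sets
are GMT, graphs are GraphML or edge-list TSV.  All files are UTF-8 with Unix
newlines.  Every writer produces a file its paired reader accepts losslessly.

Gene and exon identifiers are opaque strings: fixtures use Ensembl-style ids
but nothing enforces a format, since real tables mix Ensembl ids, NCBI LOC
ids and symbols.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .exceptions import ValidationError
from .phenotypes import BatchRecord

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "ltherm")
TISSUES = ("gonad", "brain")
STAGES = (15, 40)

SHEET_COLUMNS = ["sample_id", "family", "population", "treatment", "tissue", "stage_dpf"]
PHENOTYPE_COLUMNS = [
    "population", "family", "treatment", "n_stocked", "n_alive_31dpf", "n_sexed", "n_males",
]


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate design metadata: unique sample ids, legal factor levels, and at
    most one sample per (family, tissue, stage, treatment) cell."""
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    sheet["stage_dpf"] = sheet["stage_dpf"].astype(int)
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dup}")
    bad_t = set(sheet["treatment"]) - set(TREATMENTS)
    if bad_t:
        row = sheet.index[sheet["treatment"].isin(bad_t)][0]
        raise ValidationError(f"invalid treatment label {bad_t} at sheet row {row}")
    bad_ti = set(sheet["tissue"]) - set(TISSUES)
    if bad_ti:
        raise ValidationError(f"invalid tissue label {bad_ti}")
    bad_s = set(sheet["stage_dpf"]) - set(STAGES)
    if bad_s:
        raise ValidationError(f"invalid stage_dpf {bad_s}; expected {STAGES}")
    cell = sheet.groupby(["family", "tissue", "stage_dpf", "treatment"]).size()
    if (cell > 1).any():
        key = cell[cell > 1].index[0]
        raise ValidationError(f"more than one sample for (family, tissue, stage, treatment)={key}")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path))


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _check_integer_cells(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValidationError(f"{path}: non-numeric count at ({row}, {col})")
        if ((vals % 1) != 0).any() or (vals < 0).any():
            row = df.index[((vals % 1) != 0) | (vals < 0)][0]
            raise ValidationError(f"{path}: count at ({row}, {col}) is negative or non-integer")
    return df.astype("int64")


def read_counts(path: str | Path, kind: str = "gene",
                sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a gene-level or exon-level count TSV.

    Gene tables are indexed by ``gene_id``; exon tables by the MultiIndex
    (``gene_id``, ``exon_id``).  Optionally cross-validated against a sample
    sheet (columns must match its sample ids exactly).
    """
    if kind not in ("gene", "exon"):
        raise ValidationError(f"kind must be 'gene' or 'exon', got {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    keys = ["gene_id"] if kind == "gene" else ["gene_id", "exon_id"]
    missing = [k for k in keys if k not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing key columns {missing}")
    df = df.set_index(keys)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate {'/'.join(keys)} entries")
    df = _check_integer_cells(df, path)
    if sheet is not None:
        want = set(sheet["sample_id"])
        have = set(df.columns)
        if want != have:
            raise ValidationError(
                f"{path}: sample columns do not match sheet "
                f"(missing {sorted(want - have)}, extra {sorted(have - want)})"
            )
    return df


def write_counts(counts: pd.DataFrame, path: str | Path, kind: str = "gene") -> None:
    out = counts.copy()
    out.index.names = ["gene_id"] if kind == "gene" else ["gene_id", "exon_id"]
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> list[BatchRecord]:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: phenotype table missing columns {missing}")
    return [
        BatchRecord(
            population=str(r.population),
            family=str(r.family),
            treatment=str(r.treatment),
            n_stocked=int(r.n_stocked),
            n_alive_31dpf=int(r.n_alive_31dpf),
            n_sexed=int(r.n_sexed),
            n_males=int(r.n_males),
        )
        for r in df.itertuples()
    ]


def write_phenotypes(batches: list[BatchRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "population": b.population,
                "family": b.family,
                "treatment": b.treatment,
                "n_stocked": b.n_stocked,
                "n_alive_31dpf": b.n_alive_31dpf,
                "n_sexed": b.n_sexed,
                "n_males": b.n_males,
            }
            for b in batches
        ]
    ).to_csv(path, index=False)


def read_trait(path: str | Path) -> pd.Series:
    """Family -> IR (%) trait vector from a two-column CSV (family, ir)."""
    df = pd.read_csv(path)
    if not {"family", "ir"} <= set(df.columns):
        raise ValidationError(f"{path}: trait CSV needs columns family, ir")
    return df.set_index("family")["ir"].astype(float)


def write_trait(trait: pd.Series, path: str | Path) -> None:
    trait.rename("ir").rename_axis("family").reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene sets and mapping tables
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Term id -> (name, member set), insertion-ordered."""

    names: dict[str, str] = field(default_factory=dict)
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def add(self, term_id: str, name: str, genes) -> None:
        genes = frozenset(genes)
        if term_id in self.members:
            raise ValidationError(f"duplicate term id {term_id!r}")
        if not genes:
            raise ValidationError(f"term {term_id!r} has no members")
        self.names[term_id] = name
        self.members[term_id] = genes

    def terms(self) -> list[str]:
        return list(self.members)

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.members[term_id]

    def annotations_by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term, genes in self.members.items():
            for g in genes:
                out.setdefault(g, set()).add(term)
        return out

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated members).

    Terms with an empty member list are dropped with a warning.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: malformed GMT line")
            term, name, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                warnings.warn(f"{path}:{lineno}: term {term!r} has no members, dropped",
                              stacklevel=2)
                logger.warning("GMT term %s dropped (empty member list)", term)
                continue
            coll.add(term, name, genes)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in coll.terms():
            genes = sorted(coll.genes_of(term))
            fh.write("\t".join([term, coll.names[term], *genes]) + "\n")


def read_mapping(path: str | Path) -> pd.DataFrame:
    """Read an identifier mapping TSV with columns source, from_id, to_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "from_id", "to_id"} <= set(df.columns):
        raise ValidationError(f"{path}: mapping TSV needs columns source, from_id, to_id")
    if df.duplicated(["source", "from_id", "to_id"]).any():
        raise ValidationError(f"{path}: duplicate (source, from_id, to_id) triples")
    return df[["source", "from_id", "to_id"]]


def write_mapping(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping[["source", "from_id", "to_id"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-expression network as GraphML or an edge-list TSV.

    Node attributes: deg_direction in {up, down, none}, corr_sign in
    {+, -, none}, is_seed flag; edge attribute: weight in [0, 1].
    """
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edgelist":
        rows = [
            {"gene1": u, "gene2": v, "weight": d.get("weight", 1.0)}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["gene1", "gene2", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(path)
    for _, _, d in g.edges(data=True):
        d["weight"] = float(d.get("weight", 1.0))
    return g
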