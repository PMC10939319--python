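"""Config-driven orchestration of the full analysis with a machine-readable report.

Stage order per tissue x stage stratum: phenotypes -> normalization -> DE ->
splicing -> per-family fold changes -> IR correlation -> seed networks ->
evidence integration -> enrichment.  The four strata (gonad/brain x 15/40 dpf)
are processed independently, mirroring the separate per-stratum reporting of
the underlying study design.  Everything is deterministic for fixed inputs and
seed; any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import correlation, diffexp, enrichment, evidence, io, network, phenotypes, splicing
from .exceptions import ThermorevError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds driving :func:`run_all`.

    Any path left None skips the stages that need it (recorded in the report).
    Thresholds: ``de_alpha`` / ``de_use_adjusted`` for DEG calls, ``dsg_fdr``
    for splicing, ``corr_alpha`` for the IR screen, ``cld_alpha`` for the
    letter display; network: soft power ``beta``, partner count ``k``,
    ``partner_edge_floor``; expression filter: ``min_cpm`` in at least
    ``min_samples`` samples (None = half).
    """

    counts: str | None = None
    exon_counts: str | None = None
    sample_sheet: str | None = None
    phenotypes: str | None = None
    trait: str | None = None
    gene_sets: str | None = None
    mappings: str | None = None
    curated_genes: str | None = None
    seed_genes: str | None = None
    output_dir: str = "thermorev_out"

    de_alpha: float = 0.05
    de_use_adjusted: bool = True
    dsg_fdr: float = 0.05
    corr_alpha: float = 0.05
    cld_alpha: float = 0.05
    beta: float = 6.0
    k: int = 19
    partner_edge_floor: float = 0.1
    min_cpm: float = 1.0
    min_samples: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "dsg_fdr", "corr_alpha", "cld_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.k < 1 or self.beta <= 0:
            raise ValidationError("k must be >= 1 and beta > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ValidationError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)

    def defaults_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


def _stage(report: dict, name: str):
    """Context-manager-free stage timer that records wall clock and row counts."""
    report["stages"].append({"stage": name, "start": time.time()})
    return report["stages"][-1]


def run_all(config: RunConfig) -> dict:
    """Execute every stage the configured inputs allow; return the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": [],
                    "warnings": [], "strata": {}}

    def finish(entry: dict, **counts) -> None:
        entry["seconds"] = round(time.time() - entry.pop("start"), 3)
        entry.update(counts)

    # ---- phenotypes -------------------------------------------------------
    if config.phenotypes:
        entry = _stage(report, "phenotypes")
        try:
            batches = io.read_phenotypes(config.phenotypes)
            pairs = phenotypes.pair_families(batches)
            fam_table = phenotypes.family_pair_table(pairs)
            fam_table.to_csv(out / "family_pairs.tsv", sep="\t", index=False)
            summary = phenotypes.summarize_population(pairs, alpha=config.cld_alpha)
            summary.to_csv(out / "table1_population_summary.tsv", sep="\t", index=False)
            pops = summary["population"].unique()
            corr_rows = []
            for pop in pops:
                sub = fam_table[fam_table["population"] == pop]
                if len(sub) >= 3:
                    res = phenotypes.spearman_correlation(sub["ir"], sub["rsr"])
                    corr_rows.append({"scope": pop, "rho": res.rho, "p": res.p})
            res_all = (phenotypes.spearman_correlation(fam_table["ir"], fam_table["rsr"])
                       if len(fam_table) >= 3 else None)
            if res_all:
                corr_rows.append({"scope": "all", "rho": res_all.rho, "p": res_all.p})
            pd.DataFrame(corr_rows).to_csv(out / "table2_rsr_ir_correlation.tsv",
                                           sep="\t", index=False)
            finish(entry, n_batches=len(batches), n_pairs=len(pairs))
        except ThermorevError as err:
            raise ThermorevError(f"stage phenotypes failed: {err}") from err

    # ---- expression stages ------------------------------------------------
    if config.counts and config.sample_sheet:
        sheet = io.read_sample_sheet(config.sample_sheet)
        gene_counts = io.read_counts(config.counts, "gene", sheet)
        exon_counts = (io.read_counts(config.exon_counts, "exon", sheet)
                       if config.exon_counts else None)
        if exon_counts is None:
            report["warnings"].append("no exon table: splicing stage skipped")
        trait = io.read_trait(config.trait) if config.trait else None
        annotation = io.read_gmt(config.gene_sets) if config.gene_sets else None
        seeds = (Path(config.seed_genes).read_text().split()
                 if config.seed_genes else list(network.DEFAULT_SEED_GENES))

        for tissue in io.TISSUES:
            for stage_dpf in io.STAGES:
                key = f"{tissue}_{stage_dpf}dpf"
                sub = sheet[(sheet["tissue"] == tissue) & (sheet["stage_dpf"] == stage_dpf)]
                if sub.empty:
                    report["warnings"].append(f"stratum {key}: no samples, skipped")
                    continue
                report["strata"][key] = _run_stratum(
                    config, report, out, key, tissue, stage_dpf, gene_counts,
                    exon_counts, sheet, trait, annotation, seeds,
                )

    report["n_stages"] = len(report["stages"])
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _run_stratum(config, report, out, key, tissue, stage_dpf, gene_counts,
                 exon_counts, sheet, trait, annotation, seeds) -> dict:
    info: dict = {}
    # DE
    entry = _stage(report, f"diffexp[{key}]")
    de = diffexp.de_pipeline(gene_counts, sheet, tissue, stage_dpf,
                             alpha=config.de_alpha, use_adjusted=config.de_use_adjusted,
                             min_cpm=config.min_cpm, min_samples=config.min_samples)
    de.table.rename_axis("gene_id").to_csv(out / f"de_{key}.tsv", sep="\t")
    entry["seconds"] = round(time.time() - entry.pop("start"), 3)
    entry["n_genes"] = len(de.table)
    info["n_tested"] = len(de.table)
    info["n_deg"] = int(len(de.degs))

    # splicing
    ds = None
    if exon_counts is not None:
        entry = _stage(report, f"splice[{key}]")
        ds = splicing.splice_test(exon_counts, sheet, tissue, stage_dpf,
                                  fdr=config.dsg_fdr, min_cpm=config.min_cpm,
                                  min_samples=config.min_samples,
                                  gene_ids=gene_counts.index)
        ds.table.rename_axis("gene_id").to_csv(out / f"ds_{key}.tsv", sep="\t")
        entry["seconds"] = round(time.time() - entry.pop("start"), 3)
        entry["n_genes"] = len(ds.table)
        info["n_dsg"] = int(ds.table["dsg"].sum())

    # fold changes + correlation
    corr = None
    fcm = None
    sub = sheet[(sheet["tissue"] == tissue) & (sheet["stage_dpf"] == stage_dpf)]
    counts = diffexp.filter_low_expression(
        gene_counts[sub["sample_id"].to_numpy()],
        min_cpm=config.min_cpm, min_samples=config.min_samples)
    logcpm = diffexp.cpm(counts, log=True, prior_count=0.5)
    fcm = correlation.family_fold_changes(logcpm, sheet, tissue, stage_dpf)
    fcm.rename_axis("gene_id").to_csv(out / f"fold_changes_{key}.tsv", sep="\t")
    if trait is not None:
        entry = _stage(report, f"corr[{key}]")
        corr = correlation.trait_correlation(fcm, trait, alpha=config.corr_alpha)
        corr.rename_axis("gene_id").to_csv(out / f"corr_{key}.tsv", sep="\t")
        entry["seconds"] = round(time.time() - entry.pop("start"), 3)
        entry["n_genes"] = len(corr)
        info["n_corr"] = int((corr["sign"] != "none").sum())

    # evidence
    ev = evidence.build_evidence(de.table, ds.table if ds is not None else None, corr)
    ev.rename_axis("gene_id").to_csv(out / f"evidence_{key}.tsv", sep="\t")
    deg_set = set(de.degs)
    dsg_set = set(ds.dsgs) if ds is not None else set()
    corr_set = (set(corr.index[corr["sign"] != "none"]) if corr is not None else set())
    venn = evidence.venn_counts(deg_set, dsg_set, corr_set)
    venn_payload = {
        "exclusive": venn.as_dict(),
        "inclusive": {"DEG": len(deg_set), "DSG": len(dsg_set), "Corr": len(corr_set)},
    }
    (out / f"venn_{key}.json").write_text(json.dumps(venn_payload, indent=1))
    info["venn"] = venn_payload

    # networks
    adj = network.adjacency(fcm, beta=config.beta)
    built = []
    for seed_gene in seeds:
        if seed_gene not in adj.index or len(adj) <= config.k:
            continue
        g = network.seed_network(adj, seed_gene, k=config.k, evidence=ev,
                                 partner_edge_floor=config.partner_edge_floor)
        io.write_network(g, out / f"network_{key}_{_safe(seed_gene)}.graphml")
        built.append(seed_gene)
    info["networks"] = built

    # enrichment
    if annotation is not None:
        entry = _stage(report, f"enrich[{key}]")
        cats = enrichment.run_categorized(ev, annotation, universe=de.table.index)
        frames = list(cats.values())
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"enrichment_{key}.tsv", sep="\t", index=False)
        entry["seconds"] = round(time.time() - entry.pop("start"), 3)
        entry["n_categories"] = len(cats)
        info["enrichment_categories"] = list(cats)
    return info


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)
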