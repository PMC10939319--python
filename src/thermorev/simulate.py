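"""Synthetic data emulating the paired control / high-temperature study design.

The emulated design: full-sib tilapia families are each split into a control
(30 degC) and a treated (36.5 degC, 10-30 dpf) batch.  Phenotype tables carry
per-batch counts of stocked, surviving, sexed and male fish.  Expression data
are 2 treatments x 2 tissues (gonad, brain) x 2 stages (15, 40 dpf) libraries
per family — 48 libraries for the default six families — with *no*
within-condition replicates, which is why every downstream model is
family-paired.

Counts are negative binomial with Var = mu + phi * mu^2.  Exon counts are
generated first and gene counts are their sums, so the gene/exon consistency
the splicing test assumes holds by construction.  Three disjoint classes of
effects are planted and recorded in :class:`SimTruth`:

* DE genes: all exons shifted by ``de_lfc`` log2 units in treated samples
  (random sign per gene);
* IR-linked genes: treated shift of ``ir_slope * IR(family)`` log2 units,
  linear in the family's reversal rate (random sign per gene);
* DS genes: a single exon shifted by ``ds_exon_lfc`` while the others follow
  the gene baseline.

Default reversal rates are the six family IRs of the emulated study design:
18, 34, 73, 26, 100 and 12 percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GeneSetCollection
from .phenotypes import BatchRecord

__all__ = ["SimConfig", "SimTruth", "simulate_phenotypes", "simulate_counts",
           "simulate_annotation"]

#: family labels of the emulated six-family design, with their reversal rates
DEFAULT_FAMILIES = ("GB_F1", "GB_F2", "GO_F1", "GO_F3", "NGT_F1", "NGT_F3")
DEFAULT_IR_VALUES = (18.0, 34.0, 73.0, 26.0, 100.0, 12.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Phenotype arm: ``control_male_prob`` is the balanced-sex-ratio baseline,
    ``reversal_prob`` the probability that a female-fated fish is masculinized
    under treatment (treated male probability = p0 + (1 - p0) * reversal_prob),
    ``survival_probs`` the per-arm 31-dpf survival.

    Expression arm: log-normal baseline gene abundances, NB dispersion ``phi``
    (Var = mu + phi mu^2), library sizes jittered ~10% around
    ``lib_size_mean``, and the three disjoint planted-effect classes described
    in the module docstring.
    """

    n_families: int = 6
    n_genes: int = 2000
    exons_per_gene: tuple[int, int] = (2, 8)
    control_male_prob: float = 0.5
    reversal_prob: float = 0.44
    survival_probs: tuple[float, float] = (0.88, 0.84)
    n_fish_per_batch: int = 200
    lib_size_mean: float = 5e5
    nb_dispersion: float = 0.1
    frac_de: float = 0.05
    de_lfc: float = 2.0
    frac_ir_linked: float = 0.05
    ir_slope: float = 0.02
    frac_ds: float = 0.05
    ds_exon_lfc: float = 3.0
    ir_values: tuple[float, ...] = DEFAULT_IR_VALUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_genes < 1 or self.n_fish_per_batch < 1:
            raise ValidationError("n_families, n_genes and n_fish_per_batch must be positive")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ValidationError(f"invalid exons_per_gene range {self.exons_per_gene}")
        for name in ("control_male_prob", "reversal_prob", "frac_de", "frac_ir_linked",
                     "frac_ds"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for v in self.survival_probs:
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"survival_probs must be in [0, 1], got {v}")
        if self.frac_de + self.frac_ir_linked + self.frac_ds > 1.0 + 1e-12:
            raise ValidationError("frac_de + frac_ir_linked + frac_ds must not exceed 1")
        if self.nb_dispersion <= 0 or self.lib_size_mean <= 0:
            raise ValidationError("nb_dispersion and lib_size_mean must be positive")
        if len(self.ir_values) != self.n_families:
            raise ValidationError(
                f"ir_values has {len(self.ir_values)} entries for {self.n_families} families"
            )

    @property
    def families(self) -> tuple[str, ...]:
        if self.n_families == len(DEFAULT_FAMILIES):
            return DEFAULT_FAMILIES
        return tuple(f"F{i + 1}" for i in range(self.n_families))


@dataclass
class SimTruth:
    """Planted ground truth: which genes carry which effect, and how large."""

    de_genes: dict[str, float] = field(default_factory=dict)          # gene -> signed LFC
    ir_linked_genes: dict[str, float] = field(default_factory=dict)   # gene -> signed slope
    ds_genes: dict[str, tuple[str, float]] = field(default_factory=dict)  # gene -> (exon, LFC)

    def __post_init__(self) -> None:
        sets = [set(self.de_genes), set(self.ir_linked_genes), set(self.ds_genes)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError("planted effect classes must be disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["ds_genes"] = {g: list(v) for g, v in self.ds_genes.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["ds_genes"] = {g: (v[0], float(v[1])) for g, v in payload["ds_genes"].items()}
        return cls(**payload)


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    """One independent RNG stream per output table, split from the master seed,
    so enlarging the gene panel never perturbs the phenotype simulation."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("phenotypes", "structure", "counts", "annotation")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(config: SimConfig) -> tuple[list[BatchRecord], dict]:
    """Per-family control/treated batch counts plus the generating probabilities.

    Survivors ~ Binomial(n_stocked, survival per arm); all survivors are sexed;
    control males ~ Binomial(n_sexed, p0); treated males ~ Binomial(n_sexed,
    p0 + (1 - p0) * reversal_prob).  Deterministic for a fixed seed.
    """
    rng = _streams(config)["phenotypes"]
    p0 = config.control_male_prob
    p1 = p0 + (1.0 - p0) * config.reversal_prob
    s_ctrl, s_trt = config.survival_probs
    batches: list[BatchRecord] = []
    for fam in config.families:
        pop = fam.split("_")[0] if "_" in fam else "POP"
        for treatment, surv, pmale in (("control", s_ctrl, p0), ("ltherm", s_trt, p1)):
            n_alive = int(rng.binomial(config.n_fish_per_batch, surv))
            n_sexed = n_alive
            n_males = int(rng.binomial(n_sexed, pmale)) if n_sexed else 0
            batches.append(
                BatchRecord(pop, fam, treatment, config.n_fish_per_batch,
                            n_alive, n_sexed, n_males)
            )
    truth = {
        "control_male_prob": p0,
        "treated_male_prob": p1,
        "expected_ir": 100.0 * config.reversal_prob,
        "survival_probs": tuple(config.survival_probs),
    }
    return batches, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, Var mu + phi mu^2) via the (n, p) parameterization."""
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Exon- and gene-level count tables for the full 2x2x2 design plus truth.

    Returns (gene_counts, exon_counts, sample_sheet, truth).  Gene counts are
    exact sums of exon counts.  Effects are planted identically in all four
    tissue x stage strata; strata differ only in sampling noise.
    """
    streams = _streams(config)
    rs, rc = streams["structure"], streams["counts"]
    genes = [f"ENSONIG{i + 1:08d}" for i in range(config.n_genes)]

    lo, hi = config.exons_per_gene
    n_exons = rs.integers(lo, hi + 1, size=config.n_genes)
    # relative abundance: log-normal across genes, Dirichlet split across exons
    rel = rs.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    rel /= rel.sum()
    exon_share = [rs.dirichlet(np.full(k, 5.0)) for k in n_exons]

    # planted effect assignment (disjoint classes, random signs)
    order = rs.permutation(config.n_genes)
    k_de = int(round(config.frac_de * config.n_genes))
    k_ir = int(round(config.frac_ir_linked * config.n_genes))
    k_ds = int(round(config.frac_ds * config.n_genes))
    idx_de = order[:k_de]
    idx_ir = order[k_de:k_de + k_ir]
    idx_ds = order[k_de + k_ir:k_de + k_ir + k_ds]
    sign_de = rs.choice([-1.0, 1.0], size=k_de)
    sign_ir = rs.choice([-1.0, 1.0], size=k_ir)
    ds_exon = np.array(
        [rs.integers(0, n_exons[i]) for i in idx_ds], dtype=int
    ) if k_ds else np.empty(0, dtype=int)

    truth = SimTruth(
        de_genes={genes[i]: float(s * config.de_lfc) for i, s in zip(idx_de, sign_de)},
        ir_linked_genes={genes[i]: float(s * config.ir_slope)
                         for i, s in zip(idx_ir, sign_ir)},
        ds_genes={genes[i]: (f"{genes[i]}.e{e + 1}", float(config.ds_exon_lfc))
                  for i, e in zip(idx_ds, ds_exon)},
    )

    lfc_de = np.zeros(config.n_genes)
    lfc_de[idx_de] = sign_de * config.de_lfc
    slope_ir = np.zeros(config.n_genes)
    slope_ir[idx_ir] = sign_ir * config.ir_slope

    families = config.families
    ir = np.asarray(config.ir_values, dtype=float)

    sheet_rows = []
    sample_cols: dict[str, np.ndarray] = {}
    exon_index = [(genes[g], f"{genes[g]}.e{e + 1}")
                  for g in range(config.n_genes) for e in range(n_exons[g])]
    base_exon_rel = np.concatenate(
        [rel[g] * exon_share[g] for g in range(config.n_genes)]
    )
    gene_of_exon = np.concatenate(
        [np.full(n_exons[g], g) for g in range(config.n_genes)]
    )
    # per-exon index of the DS-affected exon rows
    ds_rows = np.zeros(base_exon_rel.size, dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(n_exons)])
    for i, e in zip(idx_ds, ds_exon):
        ds_rows[offsets[i] + e] = True

    for tissue in ("gonad", "brain"):
        for stage in (15, 40):
            for f, fam in enumerate(families):
                for treatment in ("control", "ltherm"):
                    sid = f"{fam}_{treatment}_{tissue}_{stage}"
                    pop = fam.split("_")[0] if "_" in fam else "POP"
                    sheet_rows.append(
                        {"sample_id": sid, "family": fam, "population": pop,
                         "treatment": treatment, "tissue": tissue, "stage_dpf": stage}
                    )
                    lib = config.lib_size_mean * rc.lognormal(0.0, 0.1)
                    mu = base_exon_rel * lib
                    if treatment == "ltherm":
                        shift = lfc_de[gene_of_exon] + slope_ir[gene_of_exon] * ir[f]
                        mu = mu * np.exp2(shift)
                        mu = np.where(
                            ds_rows, mu * np.exp2(config.ds_exon_lfc), mu
                        )
                        # fixed sequencing depth: planted effects shift the
                        # composition, not the total library mass
                        mu = mu * (lib / mu.sum())
                    sample_cols[sid] = _nb_draw(rc, mu, config.nb_dispersion)

    exon_counts = pd.DataFrame(
        sample_cols,
        index=pd.MultiIndex.from_tuples(exon_index, names=["gene_id", "exon_id"]),
        dtype="int64",
    )
    gene_counts = exon_counts.groupby(level="gene_id", sort=False).sum()
    sheet = pd.DataFrame(sheet_rows)
    return gene_counts, exon_counts, sheet, truth


# ---------------------------------------------------------------------------
# annotation / mapping fixtures
# ---------------------------------------------------------------------------

def simulate_annotation(
    n_genes: int,
    n_terms: int,
    sources: int = 3,
    seed: int = 0,
    conflict_fraction: float = 0.0,
    term_size_range: tuple[int, int] = (5, 50),
) -> tuple[GeneSetCollection, pd.DataFrame, dict]:
    """Gene-set collection plus multi-source ID mapping tables with planted conflicts.

    Each of ``sources`` mapping tables maps every native id to its true foreign
    id, except that for a ``conflict_fraction`` of genes a strict minority of
    sources (never enough to out-vote the rest) records a wrong association —
    so a majority-vote resolver can, by construction, recover the true mapping
    for every planted conflict.  With ``sources == 2`` a planted conflict is a
    1-1 tie instead.

    Returns (gene sets, mapping table, truth) where truth holds the true map
    and the conflicted id set.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if not 0.0 <= conflict_fraction <= 1.0:
        raise ValidationError("conflict_fraction must be in [0, 1]")
    if sources < 1:
        raise ValidationError("sources must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    genes = [f"ENSONIG{i + 1:08d}" for i in range(n_genes)]
    foreign = [f"LOC{100000 + i}" for i in range(n_genes)]
    true_map = dict(zip(genes, foreign))

    coll = GeneSetCollection()
    lo, hi = term_size_range
    hi = min(hi, n_genes)
    lo = min(lo, hi)
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        coll.add(f"T{t + 1:04d}", f"synthetic term {t + 1}", members)

    n_conflict = int(round(conflict_fraction * n_genes))
    conflicted = set(rng.choice(genes, size=n_conflict, replace=False)) if n_conflict else set()
    rows = []
    for s in range(sources):
        src = f"src{s + 1}"
        for g in genes:
            to = true_map[g]
            if g in conflicted:
                # a strict minority of sources disagrees (floor((k-1)/2) of them)
                n_wrong = max(1, (sources - 1) // 2) if sources >= 2 else 0
                if s < n_wrong:
                    to = f"WRONG_{true_map[g]}_{s}"
            rows.append({"source": src, "from_id": g, "to_id": to})
    mapping = pd.DataFrame(rows, columns=["source", "from_id", "to_id"])
    truth = {"true_map": true_map, "conflicted": conflicted}
    return coll, mapping, truth
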