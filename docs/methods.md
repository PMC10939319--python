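# Methods

This note documents the models, numerical choices and design decisions behind
`thermorev`, and what the synthetic-data tests do and do not establish about
real data.

## Study design assumed throughout

A full-sib family is split at ~9 dpf into a control batch (30 °C) and a
treated batch held at 36.5 °C from 10 to 30 dpf. Survival is counted at
31 dpf; sex is scored at 90 dpf. Expression libraries are taken per family ×
treatment × tissue (gonad, brain) × stage (15, 40 dpf) with **no
within-condition replicates** — six families give 48 libraries. Every
expression model in the package is therefore family-paired: family is a
block factor, and the treatment effect is estimated within families.

## Phenotype statistics

* **IR and RSR.** IR = 100·(SR_t − SR_c)/(1 − SR_c) with SR the male
  proportion; RSR is the same transform on 31-dpf survival. Both are
  reported unclamped (negative values are meaningful: treatment sometimes
  depresses survival) and are undefined when the control proportion is 1,
  which raises `UndefinedStatisticError` rather than returning a sentinel.
* **Exact tests.** The Fisher 2×2 and binomial tests use the
  "probability-mass ≤ observed" two-sided convention (the convention of the
  R `fisher.test` / `binom.test` functions), so p-values match what a typical
  R-based phenotype analysis reports. Both are verified in the test suite
  against literal enumeration of the null distribution.
* **Spearman correlation.** Mid-ranks, Pearson on ranks. For n ≤ 7 the
  p-value enumerates all n! permutations (exact, two-sided by |rho|);
  beyond that the usual t approximation on n−2 df. Constant input returns a
  flagged `undefined` result instead of raising, because screens routinely
  feed degenerate rows.
* **Group comparison.** Per-batch successes/failures enter a binomial-logit
  GLM; each pair of groups is tested by a likelihood-ratio test, pairwise
  p-values are BH-adjusted (the post-hoc procedure is a package choice; no
  single convention dominates for letter displays on proportions), and
  letters come from insert-and-absorb so that two groups share a letter
  exactly when their adjusted p exceeds alpha. If a group sits at 0 or 1
  (complete separation) that pair falls back to the exact Fisher test and the
  report records the route taken.
* **Summaries.** Sample SD (n−1), quartiles by linear interpolation
  (type 7, the R default), a single family reports SD 0.

## Expression chain

* **Normalization.** CPM by library size; logged values use a prior count
  scaled proportionally to each library (prior_s = p·lib_s/mean lib, value
  log2((x+prior_s)/(lib_s+2 prior_s)·10⁶)), keeping zeros finite and fold
  changes balanced across unequal libraries. Library sizes for modelling are
  column sums + 1.
* **Filtering.** CPM ≥ 1 in at least half the stratum's samples (configurable).
* **Precision weights.** Gene-wise OLS on log2-CPM gives residual sd s_g and
  mean log2 count; lowess (span 0.5) of sqrt(s_g) on mean log2 count defines
  the mean–variance trend; each observation's weight is the trend evaluated
  at its *fitted* log2 count, raised to the −4th power. Below 50 genes the
  trend is unstable and unit weights are used (with a warning). The trend is
  linearly interpolated and held constant beyond its range.
* **Moderation.** Residual variances are shrunk toward a common prior by
  matching the first two moments of log s²_g to the scaled-F model:
  e_g = log s²_g − ψ(d/2) + log(d/2), trigamma inversion of var(e) − ψ′(d/2)
  gives the prior df d₀ (Newton iteration; capped at 10⁶ and treated as full
  pooling when the inversion underflows), and
  s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)). Posterior variance is the
  df-weighted convex combination; the moderated t uses d₀ + d degrees of
  freedom (normal reference when the total df exceeds 10⁶).
  Setting the prior df to zero recovers the ordinary t exactly, which the
  tests exploit as a limit identity.
* **DEG calls** default to BH-adjusted p ≤ 0.05; raw-p calling is available
  by configuration because both conventions appear in practice for this kind
  of screen.
* **Splicing.** The same weighted model runs on exon counts. For a gene with
  m exons, each exon's deviation is logFC_e − mean(other exons), with
  variance u_e²s̃_e² + Σ_{j≠e} u_j²s̃_j²/(m−1)² treating exon estimates as
  independent; the per-exon moderated t p-values are aggregated per gene by
  the Simes rule and BH-adjusted across genes (DSG at FDR ≤ 0.05). Per-exon
  tests with Simes aggregation were chosen over a joint F-test because they
  identify *which* exon deviates and match the planted single-exon
  alternative; the deviation construction makes the statistic invariant to
  any shift common to all of a gene's exons, so pure differential expression
  cannot masquerade as splicing. Single-exon genes are skipped and listed.
* **Reversal-rate correlation.** Pearson correlation of each gene's
  per-family fold-change profile with the IR vector; with n families,
  t = r·sqrt((n−2)/(1−r²)) on n−2 df. Pearson rather than Spearman: at n = 6
  rank correlation is nearly degenerate (only coarse rho values are
  reachable) and the fold changes are already on a homoscedastic log scale.
  Significance for the ±Corr label is raw p ≤ 0.05 by default — this screen
  is a hypothesis generator feeding the evidence integration, not a
  confirmatory test — and the threshold is configurable.
* **Co-expression.** Unsigned soft-threshold adjacency |cor|^β over the same
  fold-change profiles, β = 6 (the customary unsigned default; the power is
  configurable and recorded in the run report). Raw adjacency is used rather
  than a topological-overlap transform — with six family columns the extra
  smoothing of TOM has little support. Seed networks keep the k = 19
  strongest partners (ties broken lexicographically by gene id, so results
  are independent of row order), always draw seed–partner edges, and draw
  partner–partner edges above an adjacency floor of 0.1.
* **Evidence and enrichment.** Status strings follow the ↑Exp/↓Exp (significant)
  vs ↑exp/↓exp (non-significant, sign of the fold change) and +Corr/−Corr
  notation; Venn partitions are reported both as inclusive list sizes and as
  the seven exclusive region counts, since published figures mix the two
  conventions. Identifier mappings from multiple annotation sources are
  resolved by majority vote (ties dropped with a warning); annotations can be
  augmented with the terms of a better-annotated ortholog (set union per
  gene). Over-representation is the upper-tail hypergeometric test with BH
  across terms, term-size bounds [5, 500], and the universe defined as the
  genes that entered the stratum's analysis after filtering — not the whole
  genome — to guard against detection bias.

## Synthetic data

The generator emulates the paired design above. Phenotypes: survivors ~
Binomial(n_stocked, survival per arm); all survivors sexed; control males ~
Binomial(n, p₀); treated males ~ Binomial(n, p₀ + (1−p₀)·reversal_prob), so
the expected IR is 100·reversal_prob. Counts: gene abundances log-normal
(σ = 1.2), split over 2–8 exons by a Dirichlet(5) fixed per gene; exon counts
are negative binomial with Var = μ + φμ² and gene counts are their sums, so
gene/exon consistency holds by construction. Libraries are jittered
log-normally (σ = 0.1) around the configured mean, and treated-sample means
are renormalized to the library total after effects are applied — fixed
sequencing depth, composition shifts. Planted effects occupy disjoint gene
sets: DE genes shift all exons by ±de_lfc in treated samples; IR-linked genes
shift by ±ir_slope·IR(family) (linear in IR on the log2 scale, matching the
Pearson screen's detectability assumption); DS genes shift exactly one exon.
Effects are planted identically in all four tissue × stage strata; strata
differ only by sampling noise. One RNG stream per output table is split from
the master seed, so enlarging the gene panel never perturbs the phenotype
simulation and identical configurations are byte-identical.

Defaults mirror the emulated study where it states values — six families with
reversal rates {18, 34, 73, 26, 100, 12}%, the 2×2×2 library layout, control
male probability 0.5, reversal probability 0.44 (the mean family reversal
level), survival 0.88/0.84 — and desk-scale choices where it does not:
2000 genes, mean library 5·10⁵, dispersion 0.1 (a typical bulk RNA-seq
value), 200 fish per batch. The recovery benchmarks for the reversal-linked
and splicing screens use dispersion 0.02, which at these depths puts the
per-family fold-change noise near sd 0.3 — the detectability regime those
screens assume; at dispersion 0.1 the fold-change noise roughly doubles and
a six-point correlation screen is underpowered by design, which the tests
document rather than hide.

**What passing tests show — and don't.** Recovery and calibration results on
this generator establish internal correctness (the chain finds what was
planted, at the planted scale, with calibrated error rates). Real data add
tissue-specific baselines, batch effects beyond family, GC/length biases,
outlier samples and annotation error, none of which are emulated; performance
there depends on those factors. The gene-level DE chain was additionally
cross-checked during development against an independent R implementation of
the same weighted-moderated model on identical counts (log fold changes
agreeing to < 0.03, p-values essentially identical), so the implementation
itself is not the limiting factor.

## Numerical details and degenerate inputs

BH adjustment delegates to the standard step-up implementation and is
property-tested against the literal definition. Simes p is min_i n·p_(i)/i,
capped at 1. Zero residual variance across all genes aborts moderation with
an error; a single zero-variance gene is shrunk to the prior. Correlation of
a constant profile is NaN with sign `none` (logged), never silently 0.
Fold-change matrices built from prior-counted log2-CPM are finite by
construction and validated as such. Pipeline outputs are deterministic for
fixed inputs; the run report records per-stage row counts, wall-clock and
warnings.

## Problem sizes used in the validation suite

Oracle-equivalence batteries use hundreds of random instances (2×2 tables
with margins ≤ 30, hypergeometric instances with universes ≤ 80, 1000 BH
vectors). Calibration and recovery use 2000-gene (400 for splicing) studies
over 3–10 seeds — small enough to iterate on a laptop, large enough that
binomial noise on the measured rates is a few percent.
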