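# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that make results reproducible.

## Data model

All stability computations consume a complete genes × biological-samples
matrix of mean Ct values (`CtMatrix`) with a sample → stage-group map and a
per-gene amplification efficiency `E ∈ (1, 2.2]`. Cells are the arithmetic
mean of the technical replicates of one (gene, sample) well group; the
replicate count and SD are kept as QC metadata and a cell is flagged when
its replicate SD exceeds 0.5 cycles or only a single replicate exists.
Stability analysis requires a complete matrix: genes or samples with
missing cells are dropped with a logged reason rather than imputed, because
every algorithm below compares genes *within* samples and imputation would
manufacture exactly the covariance being measured.

### Abundance filter

A gene is retained when its grand-mean Ct over all biological samples is
below 28 cycles. The boundary is exclusive (mean exactly 28 ⇒ excluded),
matching the convention of keeping genes *below* the threshold; the rule and
threshold are configurable. The filter runs once on the pooled data and the
retained panel is shared by every stratum, so per-stage rankings stay
comparable.

### Log quantities

`q_ij = log2(E_i) · (max_j' Ct_ij' − Ct_ij)` anchors each gene's
least-abundant sample at q = 0 and converts cycles into log2 expression
units through the gene's own efficiency. Anchoring is per gene, so any
per-gene constant cancels from all pairwise statistics; with E = 2 the
pairwise differences of q are exactly the negated Ct differences, which
yields the identity checked in the tests: full-panel geNorm M computed on q
equals the comparative ΔCt std-value computed on Ct, to machine precision.

## Stability algorithms

**Comparative ΔCt.** `value_j = mean_{k≠j} SD_samples(Ct_j − Ct_k)` with the
n−1 SD. Shared per-sample effects cancel in every difference, so the
statistic isolates gene-specific variation. Requires ≥ 3 genes and ≥ 3
samples.

**BestKeeper.** Per-gene descriptive dispersion of raw Ct plus the Pearson
correlation (two-sided p) with the BestKeeper index, the per-sample
geometric mean of Ct over the retained panel. The default "SD" is the mean
absolute deviation from the arithmetic mean — the original tool's
statistic — with the n−1 sample SD available as `sd_flavor="sample_sd"`
because published tables do not always state their dialect. Genes with
SD > 1 cycle are flagged unstable. BestKeeper is deliberately *not*
sample-centered: it is the one method here that sees loading effects, which
is documented and asserted (a per-sample shift leaves ΔCt/geNorm/NormFinder
values unchanged to 1e-9 but strictly increases some BestKeeper SD).

**NormFinder.** Sample-centered values `z_ij = Ct_ij − mean_genes(Ct_·j)`
remove loading effects but couple the genes: for k genes,
`E[s²_i] = σ²_i (1 − 2/k) + S/k²` with `S = Σ_i σ²_i`. Summing over genes
gives `E[Σ s²_i] = S (k−1)/k`, so `Ŝ = (k/(k−1)) Σ s²_i` and the
bias-corrected intragroup variance is
`σ̂²_i = max(0, (s²_i − Ŝ/k²)/(1 − 2/k))`. The correction divides by
1 − 2/k, hence the k ≥ 3 requirement. In grouped mode the same estimate is
formed per group; the per-group means `d_ig` of z yield an intergroup
variance `γ̂²_i = max(0, Var_g(d_ig) − mean_g σ̂²_ig/n_g)` and each observed
group difference is shrunk toward zero in proportion to its sampling noise,
`δ̃_ig = (d_ig − d̄_i)·γ̂²_i/(γ̂²_i + σ̂²_ig/n_g)`. The stability value is
`ρ_i = mean_g(|δ̃_ig| + √(σ̂²_ig/n_g))`.

Calibration: the intragroup estimator is unbiased before clamping, and a
1000-replicate Monte-Carlo check confirms the mean estimate within 10% of
truth in a regime where the non-negativity clamp rarely engages (σ ≥ 0.3
cycles, 40 samples). At very small σ relative to the estimator's sampling
noise the clamp necessarily inflates the mean — a property of every
truncated variance estimator, relevant when interpreting near-zero ρ
values. Numerical equality with the original NormFinder add-in is not
claimed; the implementation is validated by these calibration and ordering
properties and by brute-force oracle equivalence.

The pooled ("total") stratum runs grouped by stage; single-stage strata run
ungrouped (a single group has no intergroup term). Both modes are exposed.

**geNorm.** `M_j` is the mean over partner genes of the SD of the pairwise
log2 ratio `q_j − q_k`. Ranking removes the highest-M gene and recomputes M
until two inseparable genes remain; those share rank 1 and the runner-up
takes rank 3 under competition ranking. M ties during exclusion drop the
lexicographically last gene — an arbitrary but fixed rule that makes runs
reproducible; an all-identical panel is processed under the same rule and
flagged degenerate. The pairwise variation
`V_n = SD_samples(NF_n − NF_{n+1})`, with `NF_n` the arithmetic mean of q
over the top-n genes (the log-domain geometric-mean normalization factor),
is reported for n = 2..k−1 together with the smallest n below the 0.15
cutoff; when even `V_2` is below the cutoff a two-gene factor is already
sufficient and adding genes buys nothing.

## Comprehensive ranking

Per stratum, each method's values are converted to competition ranks
(ties share the minimal rank, the next rank skips the tie width) and each
gene's score is the geometric mean of its available ranks; missing methods
are simply excluded from the mean. Scores are reported to 2 decimals with
full precision retained for sorting; score ties break on the gene label.
The score is bounded by the smallest and largest input rank and worsening
any single rank can only worsen it.

## Target validation

For target t and reference set R: per sample
`ΔCt = Ct_t − mean_{r∈R}(Ct_r)`, `ΔΔCt = ΔCt − mean_calibrator(ΔCt)`,
`fold = 2^−ΔΔCt`. The multi-gene normalizer aggregates references by the
arithmetic mean of their Cts — the geometric mean of their quantities at
100% efficiency. The calibrator group's mean log2 fold change is exactly 0
by construction (its geometric-mean fold is 1). Stage contrasts use
Welch's t on log2 fold changes with tiers ns / * / ** at 0.05 / 0.01 and no
multiple-testing correction across the three stage pairs by default (the
three contrasts are usually reported individually; a Holm option exists).
The cross-normalizer matrix is the Pearson R between normalizers'
concatenated log2 fold profiles over all targets; a zero-variance profile
yields an undefined (NaN) entry rather than a fabricated one.

Sign convention worth stating: a reference gene whose Ct *drops* by c
cycles in some stage (up-regulation) attenuates every fold change measured
in that stage by 2^c; a Ct *rise* inflates them by the same factor. The
simulated unstable normalizer used in the validation tests is up-regulated
by 2 cycles in stage 3 and accordingly attenuates the recovered stage-3
fold by ≈ 4.

## Synthetic data

Each well draws
`Ct = baseline_i + φ_j + b_{i,g(j)} + ε_ij + τ_w` with φ the shared
per-sample loading effect, b the per-gene per-group offset, ε the per-gene
biological noise and τ the per-well technical noise — all on the Ct scale,
i.e. multiplicative on transcript quantity, reflecting the log-linearity of
PCR. Identical seeds give bitwise-identical tables.

Defaults (the study design the test-bench assumes): three stage groups of
8 biological samples (24 total; stage sizes are a documented choice — the
emulated design collapses eight sampling time points into three stages
without printing per-stage counts) with technical triplicates
(τ SD 0.15 cycles), loading SD 0.8 cycles, baselines uniform on 19–26
cycles, and a 17-gene candidate panel in three tiers:

* 4 stable genes, σ = 0.1 cycles, no stage effect;
* 6 noisy genes, σ from 0.5 to 1.5 cycles;
* 7 stage-regulated genes, σ = 0.3, stage-3 offsets 0.5–2.0 cycles with
  alternating sign.

The alternating sign is deliberate: all four algorithms measure stability
*relative to the panel*, so if every biased gene shifted the same way the
panel average itself would acquire a stage effect and the genuinely stable
genes would absorb it — most visibly in grouped NormFinder, where the
panel-mean shift appears as an intergroup difference on every gene. Mixed
regulation directions are also what real candidate panels look like.
Three targets accompany the panel: two rising monotonically (4-fold at
stage 2, 16-fold at stage 3 on the expression scale) and one peaking in the
middle stage, σ = 0.2.

The FPKM generator draws `FPKM_ij = exp(N(log μ_i, s_i²))` over 9
libraries, with s = 0.05 for the low-noise genes (expected CV ≈ 5%, the
regime worth nominating) and 0.4 otherwise.

Ground truth orders candidates by `σ_i + mean_g |b_ig|` ascending, ties by
label. What the generator does *not* emulate — plate-position effects,
inhibitor-driven efficiency shifts, fluorescence-curve artifacts, heavy-
tailed outlier wells, and any RNA-seq count noise structure beyond
log-normal dispersion — bounds what passing tests can claim: they establish
that the algorithms and their implementation recover known structure under
a realistic noise model, not that any particular wet-lab panel is stable.

## Screening defaults

CV uses the n−1 SD (9 libraries is small-n territory). The default
thresholds — mean FPKM ≥ 50, CV ≤ 0.06, MFC ≤ 1.22 — are a reconstruction
consistent with the extreme values of a published candidate table, not
published cutoffs; they are plainly labeled configurable and no test
depends on a specific candidate count. A gene with any zero FPKM has
undefined MFC, reported as +inf (fails any finite MFC filter); an all-zero
gene has undefined CV and is excluded with a reason.

## Problem sizes and numerical conventions

All SDs use the n−1 denominator except BestKeeper's default MAD flavor.
Negative variance estimates clamp to zero. Stochastic properties are
checked over 200 fixed seeds (recovery, significance power, correlation
ordering) or 1000 replicates (estimator calibration) on panels of 12–20
genes and 16–24 samples — sizes at which each check completes in seconds
while leaving Monte-Carlo error well inside the asserted margins. The
pipeline records the seed and a configuration hash in every summary so a
bundle can be reproduced bitwise.

## Known limitations

* BestKeeper's published tables exist in more than one SD dialect; without
  raw data the default (MAD) cannot be verified against any specific paper
  table, which is why both flavors are exposed.
* NormFinder near ρ = 0 is biased upward by clamping (see above).
* The geNorm exclusion tie-break is well-defined but arbitrary; on
  degenerate (identical-gene) panels the ranking is a convention, and the
  result is flagged.
* Efficiency is treated as known per gene (default 2.0, "around 100%");
  standard-curve estimation of E is out of scope.
* The comprehensive score aggregates ranks, not values: a method that
  separates genes by a hair counts as much as one that separates them by a
  cycle.
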