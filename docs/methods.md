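# Methods

This note documents the statistical procedures, the synthetic-data model that
stands in for the patient cohort and the perturbation experiment, the
defaults and why they were chosen, and the known limitations.

## Statistical procedures

**Isoform ratio and grade tests.** The ratio is computed per patient as
δ/α on normalized isoform expression; samples with α = 0 are excluded and
logged rather than coerced. Grade contrasts use the two-group Mann-Whitney U
test: the exact null distribution (full enumeration) when the pooled sample
has ≤ 20 untied observations, otherwise the tie-corrected normal
approximation with continuity correction. Identical pooled values return
p = 1. The three pairwise contrasts of each measure (α, δ, ratio) form one BH
adjustment family — the smallest family consistent with per-contrast FDR
reporting. Percent changes are reported both mean- and median-based, since
either convention is defensible for right-skewed normalized counts.

**Moderated differential expression.** Per gene, condition means by OLS with
the residual variance pooled across all design conditions. The
empirical-Bayes prior (s₀², d₀) is estimated by the classical moment match:
with e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over the
mean of ψ′(d_g/2) identifies ψ′(d₀/2) (inverted by Newton iteration on the
trigamma function, started at x = 0.5 + 1/y), and the mean of e identifies
s₀². Var(e) ≤ 0 yields d₀ = ∞ (complete shrinkage). p-values come from a t
distribution on d₀ + d_g df (normal when d₀ = ∞). Gates: BH FDR < 0.1 and
absolute linear fold change ≥ 1.5, i.e. |log₂FC| ≥ log₂ 1.5, applied within
each contrast's gene family. d₀ = 0 reproduces the ordinary equal-variance t
exactly (a unit-tested limit); a one-test R/limma fixture cross-checks t, p,
d₀ and s₀² on a 40-gene fixture. Patient contrasts run on log₂(count + 1):
normalized RSEM-style counts are heteroscedastic on the linear scale, and the
offset 1 keeps zeros finite; this transform is an assumption, documented
here, not a property of the source data.

**Microarray preprocessing.** Fixed order: flagged-spot removal → log₂ →
between-array quantile normalization → probe collapsing (arithmetic mean of
a transcript's probes) → expression filter (keep a gene iff some condition's
mean log₂ intensity is strictly > 6). Each (array, channel) is one
single-channel sample; no ratio-of-channels model. Quantile normalization
maps every column's values onto the per-rank mean of the sorted columns,
ties sharing the tied-rank mean; with missing entries each column is mapped
through quantiles interpolated from the reference curve, so nothing is
imputed. Whether probe averaging preceded normalization in comparable
published pipelines is ambiguous; the order above is fixed and asserted by
construction (collapsing operates on the normalized matrix only).

**Concordance and classification.** A condition imposes a sign on each
covariate (knockdowns lower GFAPα; recombinant GFAPδ raises the ratio;
recombinant GFAPα raises α and lowers the ratio). A gene's in-vitro
direction per unit covariate increase is the DE sign times that condition
sign; genes with conflicting harmonized signs across conditions are excluded
and logged, consistent signs count once. Patient direction is the DE sign in
grade IV, unioned over the II-vs-IV and III-vs-IV contrasts with conflicts
excluded. Concordance requires patient sign = harmonized direction × the
covariate's own grade-IV sign (α down, ratio up). Classification reports
Spearman's ρ but takes significance from the simple-regression slope test
(reconciling a rank-based effect display with a regression-based test);
thresholds 0.01 (strong correlation), 0.1 (δ-null filter) and 0.05
(within-grade follow-up) are config keys. Hierarchical clustering of |ρ|
vectors uses average linkage on Euclidean distance with genes pre-sorted
lexicographically, making the dendrogram and the two-cluster cut
deterministic under input permutation.

**Survival.** Kaplan-Meier estimation and the two-group log-rank test are
delegated to lifelines behind this module's surface. Median splits send
values equal to the median to the "low" stratum (a fixed, documented tie
rule). The BH family is all genes screened for one (grade, endpoint) panel;
a single screened gene has fdr = p. Degenerate inputs (no events anywhere,
constant genes, < 4 patients) are reported, not guessed at.

**GO over-representation.** One-sided hypergeometric upper-tail p per term
against the analysis universe (the tested background, not the genome). The
*elim* decorrelation visits terms children-first and removes the genes of a
term significant at α = 0.05 from its ancestors' annotation before testing
them; a flat DAG reduces to the plain test. Raw p-values are reported — no
across-term correction, matching how such tables are conventionally printed.
Note that eliminating a child's genes removes hits and non-hits alike, so an
ancestor's elim p is not mathematically guaranteed to exceed its plain p in
every configuration, though it does in the intended parent-driven-by-child
cases (asserted on constructed fixtures).

## The synthetic cohort

One seeded NumPy generator drives everything; equal specs give byte-identical
tables.

* **Patients.** 55 grade II, 105 grade III, 150 grade IV. Survival data
  exist for 41/91/150 of them (the rest are missing OS, as in the clinical
  table the sizes were taken from); PFS exists for grades II and III only.
* **Isoforms.** log α ~ N(μ_α + Δ_g, σ_α²) with Δ_IV = ln 0.55 (a 45%
  grade-IV decrease) and σ_α = 0.5; log δ ~ N(μ_δ, 0.5²), constant across
  grades. With δ held constant the planted ratio increase is exactly
  1/0.55 ≈ 182% of the lower-grade level in the mean/median sense; a larger
  explicit `ratio_grade4_multiplier` is honoured by tilting grade-IV δ by the
  residual factor, at the cost of weakening the planted δ-null pattern —
  the default leaves δ untouched.
* **Genes.** Planted low-malignant genes are log-normal with
  log x = μ_g + s(ρ z_α + √(1−ρ²) ε) where z_α is the standardized pooled
  log-α (grade structure included), ρ = 0.6 by default and s = 1.0;
  high-malignant genes use −ρ; null and survival-effect genes are
  independent. This one latent makes a gene simultaneously correlate with α
  (sign ±ρ), anti-correlate with the ratio (because log ratio = log δ −
  log α), stay independent of δ, and differ between grades — all four
  properties the downstream stages test. The dispersions are free
  parameters (the source cohort publishes no within-grade variances); s=1.0
  puts the planted grade-IV fold change (≈1.85) comfortably past the
  1.5-fold gate at the default sample sizes without making it trivial.
* **Survival.** Exponential times with grade-specific baseline hazards
  (median 3000/1500/400 days), administrative censoring at the horizon
  −ln(c)/λ₀ per grade, and hazard multiplied by 2 (default) for patients
  above a survival-effect gene's within-grade median, centred so the
  population scale is preserved. Censoring defaults are (0.90, 0.05, 0.35):
  grade II patients rarely reach an event within follow-up, while the grade
  III default is deliberately event-rich so that planted hazard effects are
  identifiable at the n = 91 stratum size — a design choice for
  verifiability, not a claim about real follow-up; observed cohort-style
  rates (≈0.95/0.77/0.35) can be set in the config, at which point ~21
  events remain and no median-split screen can recover HR = 2 effects.
* **A hard ceiling worth knowing about.** Even at zero censoring, the
  log-rank Z for a median-split HR = 2 effect at n = 91 has mean
  ln 2·√(91/4) ≈ 3.3, and each additional independent hazard gene adds
  (ln 2)²/4 of frailty log-variance that attenuates every marginal effect.
  The BH fixed point at FDR 0.05 over the screened family then caps mean
  sensitivity near 0.75 (measured 0.65–0.72 at the defaults, 4 planted genes,
  family = planted genes). The planted-recovery suite asserts the nominal 0.8
  anyway and that test documents the gap rather than hiding it; the screen's
  correctness is established independently by the hand product-limit and
  permutation-oracle tests.
* **Arrays.** Spot-level intensities 2^(b₁·(baseline + FC + N(0, 0.25²)) + b₀)
  with per-sample monotone affine distortions (slope 0.85–1.15, offset
  ±0.6) for quantile normalization to undo; ~30% of genes carry two probes;
  a configurable fraction of spots (default 5%, exact count) is flagged
  saturated/non-uniform/artefact; planted genes get baselines in log₂ 8–11 so
  the expression filter does not interact with the planted truth, null
  baselines are N(8, 1.5²). In-vitro fold changes for planted genes are ±1
  log₂ unit with signs consistent with their patient class (a low-malignant
  gene rises under GFAPα⁺, falls under the knockdowns and under GFAPδ⁺).
* **Annotations.** A generator-side gene→term map with two planted enriched
  terms (covering ~80% of each malignant class) plus random terms and a
  single-root DAG feeds the GO stage in synthetic runs.

**What passing tests do and do not show.** The generator's genes are
log-normal, independent given one latent, with exchangeable patients — no
batch effects, no count-level sampling noise, no correlated gene modules
beyond the planted latent, no informative censoring, no probe-sequence
effects. Recovery results on it validate the statistical machinery and the
plumbing, not performance on real cohorts.

## Numerical choices and degenerate inputs

* BH is the fixed reading of "FDR correction" throughout (the cited
  toolchains' default).
* Spearman p-values are exact permutation tails for n ≤ 9 untied pairs
  (enumeration; beyond that the n! table costs far more than the
  t-approximation error), the t-approximation otherwise.
* Mann-Whitney switches from exact to approximation at pooled n > 20 or any
  tie; extreme shifts produce p-values via the normal tail without
  under/overflow.
* Constant vectors: Shapiro-Wilk gate → "non-normal" with a warning;
  correlation → gene skipped with a record; median split → gene skipped;
  paired comparison → p = 1 with a warning.
* Zero residual df → contrast rejected; failed hyperparameter estimation →
  ordinary t with a warning.
* All TSVs use "NA" as the only missing-value token; `isoratio.io.read_table`
  reads them back without pandas' permissive NA coercion (gene identifiers or
  labels that look like NA strings survive).

## Scaled problem sizes in the test suite

The suite verifies oracle equivalences on enumerable sizes (groups ≤ 8,
universes ≤ 50, n ≤ 7 permutations), calibration on 100–400 scaled replicate
cohorts (≈60 patients, ≈40 genes each), and planted recovery on three full
default-size runs plus eight survival-screen cohorts — chosen so the whole
suite completes in about a minute while every claim is still measured, not
assumed.

## Known limitations

* No adapters for real TCGA/GEO/Agilent file layouts (synthetic and generic
  TSV inputs only); identifiers are opaque strings without symbol mapping.
* The GO stage implements plain Fisher and elim, not the weighted
  down-weighting scheme some published tables used; p-values on real
  annotations will differ accordingly.
* No Cox models, covariate adjustment, dye-swap handling, background
  subtraction or within-array loess; out of scope by design.
* The survival screen's power ceiling under median-split dichotomization is
  intrinsic (see above); interpret screen sensitivity against that bound.
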