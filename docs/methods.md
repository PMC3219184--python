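# Methods

`dcismir` implements an integrated analysis of miRNA and mRNA dysregulation
in a paired histologically-normal (HN) / preinvasive-lesion (DCIS) epithelium
design with a pooled healthy-tissue reference (PRM). This note documents the
statistical models, the defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the numerical decisions.

## miRNA qPCR stage

**Data model.** A TaqMan-style array reports one threshold cycle (Ct) per
miRNA per sample; Ct is inversely proportional to log2 template abundance,
and Ct = 40 conventionally means undetected.

**Nonexpression filter.** A feature is removed when it is undetected in more
than 2/3 of the pool replicates, or in more than 6/8 of the HN samples *and*
more than 6/8 of the DCIS samples. The clause precedence is A ∨ (B ∧ C):
the alternative (A ∨ B) ∧ C would discard pool-detected features that are
absent only in HN, which contradicts the intent of removing globally
nonexpressed assays. Thresholds are fractions, so other group sizes
generalize; precedence is configurable.

**Normalization.** Global-median rescaling: ΔCt(f, s) = Ct(f, s) −
median_f Ct(·, s) + 12. The target of 12 cycles is arbitrary but fixed;
normalization is idempotent and every sample's post-normalization median
equals the target exactly.

**Fold changes.** ΔΔCt = mean ΔCt(test) − mean ΔCt(reference) per comparison
(HN−PRM, DCIS−PRM, DCIS−HN); fold change = 2^−ΔΔCt, so fold > 1 means
overexpressed in the test group. The paired comparison averages per-patient
differences (identical to the difference of group means on a complete
design, robust to exclusions otherwise).

**Pooled-reference variance correction.** The pool is made by combining
equal RNA masses from κ = 9 healthy individuals and is measured in technical
triplicate. Its across-replicate variance is therefore almost purely
technical: the biological component has been averaged down by the pooling
and is *shared* across replicates, so the naive two-sample t against the
pool wildly understates the uncertainty the pool mean carries as an estimate
of the healthy population mean. The correction inflates the pool group's
sample variance by κ before forming the standard error,

  SE² = s²_G / n_G + κ · s²_P / n_P,

with Welch–Satterthwaite degrees of freedom computed on the inflated term.
κ defaults to the pool size (9) and is a config parameter, logged in the run
provenance. Under the default noise model (biological SD 0.5, technical SD
0.1, both log2) this choice is almost exactly calibrated: κ·σ²_t/n_P ≈
σ²_b/κ + σ²_t/n_P, and the measured null rejection rate at α = 0.005 over
10 000 features is within Monte-Carlo error of 0.005. κ = 1 reduces to an
ordinary Welch test; inflating κ never decreases a p-value.

**Paired comparison.** DCIS−HN uses a paired t on per-patient ΔCt
differences (samples are patient-matched); an unpaired Welch path is
available behind a flag for sensitivity analysis.

**Multiple-testing tiers.** Three flags per comparison: nominal p < 0.005;
Benjamini–Hochberg at FDR 0.05 (the realized step-up p-cut is reported so
the FDR↔p correspondence is inspectable); Bonferroni at 0.05/m with m the
number of features actually tested — which reproduces the printed 0.00025
cut at m = 200 and stays correct for other panel sizes. Note the ordering of
stringency: Bonferroni < nominal < realized BH cut, so the tiers are
reported as independent flags, not nested sets; the reported significant set
is "nominal in at least one comparison".

**Censored values.** Undetected entries enter normalization and group means
at the detection floor (policy `floor`; `exclude` drops them). Dropping
them would bias ΔΔCt toward zero for low-abundance features. A known
consequence of the floor policy: paired differences of near-ceiling features
are shrunk toward zero, which makes the paired test mildly conservative on
such features (measured ≈ 0.0042 empirical rate at nominal 0.005 under the
default design, vs ≈ 0.0051 for the corrected pool tests); on uncensored
features it is exactly calibrated.

## mRNA microarray stage

**Presence filter.** Probe sets present in < 15% of samples are removed.
Presence calls come from the loaded call matrix or a detection threshold.

**Posterior fold-change screen.** A Bayesian screening stage computes, per
probe, the posterior probability that the DCIS/HN fold change exceeds a
screen threshold. Per group the mean and variance get a conjugate
normal–inverse-gamma treatment (prior: mean centered at the probe's grand
mean with κ₀ = 0.01, variance Inv-Gamma(a₀ = 1, b₀ = 0.5) — vague on the
log2-expression scale); two variance models are entertained (shared across
groups, and group-specific), each yielding a t-form posterior for the
group-mean difference (closed form when shared; one-dimensional quadrature
over the reference-mean posterior otherwise), and the two are averaged with
weights proportional to closed-form marginal likelihoods under equal prior
model odds. Probes with posterior > 0.975 or < 0.025 pass the screen.

The screen threshold defaults to fold change 1.5; a sensitivity mode at 1.0
is available. The trade-off is deliberate and worth knowing: at threshold
1.5 the "up" side must clear P(FC > 1.5) > 0.975, which an up-regulated
1.8-fold gene with typical noise at n = 8 often cannot (posterior ≈ 0.95),
while any down-regulated or null probe trivially has P(FC > 1.5) < 0.025.
The conservative default therefore costs sensitivity for modest
up-regulation; at threshold 1.0 the screen is symmetric (identical groups
give exactly 0.5) and the planted-truth benchmark reaches ≥ 0.9 selection
sensitivity at ≤ 0.02 false-selection rate.

**Mixed model.** Screened probes get a linear mixed model with lognormal
errors — normal on the log2 scale — a fixed lesion effect and a random
patient intercept, fit by REML. On a balanced complete paired design the
REML inference for the group effect has a closed form: the estimate is the
mean within-patient log2 difference and the Wald t equals the paired t
statistic; p-values use n_patients − 1 degrees of freedom. This closed form
is used directly (vectorized); incomplete designs fall back to a per-probe
numerical REML fit, and a singular fit falls back to a paired t with a
warning. Variance components are the balanced-ANOVA/REML estimators,
truncated at zero.

**Selection.** A probe is differentially expressed when it passed the
screen, its mixed-model p < 0.05, and its fold change is > 1.5 (over) or
< 1/1.5 (under). Genes are deduplicated for set sizes, but all probes are
kept (multi-probe genes yield one row per probe).

## Pair integration

Candidate pairs are (miRNA, gene) pairs predicted by all loaded prediction
programs (the support threshold is configurable; two releases of one
program are unioned at load and count once). Candidates are restricted to
miRNA significant in the paired comparison and genes in the selected set,
expanding a gene to each of its selected probes. Each pair's Pearson r is
computed across all HN + DCIS samples between the miRNA's −ΔCt — the
log2-abundance orientation; raw Ct would flip every sign — and the probe's
log2 value, with a two-sided p from the t transform. Sign classifies the
pair: inverse (r < 0, the canonical destabilization signature), coordinate
(r > 0), and a third *undefined* class for exact zeros and non-computable
correlations (constant vectors, too few complete observations) rather than
forcing a side. The three classes partition the retained set.

## Locus co-expression

Loci (BED, 0-based half-open) are chained per chromosome by single linkage:
consecutive intervals whose gap (end-to-start, 0 if overlapping; midpoints
are not used) is at most the threshold merge; 50 kb is the clustering
default, 13 kb the tight threshold. Within each multi-member cluster all
pairwise Pearson correlations of −ΔCt are computed; a clustered miRNA counts
as positively correlated when all of its within-cluster pairs have r > 0,
and the non-positive pairs are listed as named exceptions — matching the
per-miRNA counting style used for such claims.

## Enrichment

One-sided over-representation of a study gene list against a background
universe: fisher_p = P(X ≥ k) under the hypergeometric null, and the EASE
score = the same tail at max(k − 1, 0) — a jackknife that sends single-gene
overlaps to p = 1. The background defaults to the genes surviving the
expression presence filter (the measurable universe, not the genome).
BH q-values over the EASE scores are attached. In the pipeline the study
list is the unique genes of the retained pairs.

## Synthetic benchmark

The generator emulates the study design: a 365-assay panel (the size of the
TaqMan v1 human panel) on 3 pool replicates + 8 patient pairs, and a
2 000-probe expression array (a down-scaled array surrogate chosen so that
full multi-seed benchmarks run in seconds per replicate).

- *Ct data*: per-feature mean log2 abundances uniform over (2, 14); per-
  individual biological deviations (SD 0.5); the pool is the arithmetic mean
  of linear-scale abundances of 9 individuals (equal-mass RNA pooling), log
  transformed, shared across its 3 technical replicates; Ct = 40 − log2
  abundance + technical noise (SD 0.1 cycles); censoring to Ct 40 with
  logistic probability in the latent Ct (midpoint 38, steepness 1.5/cycle),
  so the censoring rate is monotone in latent Ct.
- *Expression*: log2 value = probe mean + patient random intercept (SD 0.3)
  + planted lesion effect + Σ slope × centered latent miRNA level + residual
  (SD 0.25); lognormal on the linear scale by construction; presence calls
  from a fixed detection threshold.
- *Predictions*: each truly coupled pair emitted per program with that
  program's sensitivity (default 1.0 — program error is modeled as decoys,
  so intersection-survival measures the statistics, not an arbitrary
  prediction-miss rate); decoy pairs emitted independently at rate 0.1 per
  program, giving a three-way decoy intersection rate of 10⁻³.
- *Planted truth placement*: planted and coupled features draw their means
  from the quantifiable range (log2 abundance ≥ 6, i.e. mean Ct ≤ 34;
  expression means ≥ detection threshold + 2). An effect planted below the
  detection limit measures the detector, not the test — real studies report
  fold changes only for assays surviving the nonexpression filter — so
  recovery benchmarks plant on measurable features, while censoring behavior
  is exercised by the unplanted majority and by dedicated tests.
- *Determinism*: one global seed; every stage draws from a substream keyed
  by (seed, stage name) via CRC-32, so outputs are bit-identical across runs
  and adding a stage does not perturb earlier draws.

What the benchmark does *not* emulate: probe-level microarray physics,
sequence-based target prediction, correlated decoys between programs,
amplification-efficiency variation, batch structure across the merged
expression sources, or tumor heterogeneity within a lesion. Passing the
recovery benchmarks therefore demonstrates the statistical chain is
implemented correctly and has the designed operating characteristics under
its assumed noise model — not that those characteristics transfer to any
particular clinical data set.

## Numerical choices

- Quadrature for the separate-variance posterior: 201 Gauss–Legendre nodes
  under the substitution u = m + s·tan θ (maps the heavy-tailed t integral
  onto a finite interval); absolute error ≲ 1e-9, validated against
  adaptive quadrature.
- Zero-variance guards: t statistics are undefined (never "p = 0") when the
  squared standard error falls below 1e-20 (Welch path) or the paired SD
  below 1e-10 — far below any physical Ct variation, absorbing float noise
  on degenerate zero-noise inputs.
- Pearson r is clipped to [−1, 1]; |r| = 1 returns p = 0; fewer than 3
  complete observations or a constant vector give NaN with an explicit
  undefined flag.
- Model-average weights use a clipped log-odds difference to avoid overflow.
- Ties: r = 0 exactly is classified undefined; cluster gaps of exactly the
  threshold merge (≤); presence fraction exactly at the threshold is kept
  (≥).

## Problem sizes used by the shipped benchmarks

Calibration: 10 000 null features, one seed. miRNA recovery: 100 seeds of
the default planted design (10 effects of |log2 FC| = 2 among 365).
Integration recovery: 50 seeds of the planted design (20 coupled pairs,
slope −0.8, residual SD 0.25, 16 samples). Gene-selection harness: 5 seeds
of 50 planted 1.8-fold genes among 2 000 probes. These sizes are the
package's benchmark definition; all are regenerated programmatically at
test time.

## Known limitations

- The variance-inflation reading of the pooled-reference correction is one
  defensible concretization of a pooling-design correction; the original
  suggestion is a principle, not a formula. κ is exposed in config.
- The posterior screen is a re-specified surrogate for a model-averaging
  screening tool whose exact model space and priors are defined elsewhere;
  its thresholds (0.975/0.025) are honored verbatim, but reproducing any
  specific published probe list is not promised.
- Whether the original analyses paired the lesion-vs-normal t-test, and
  which expression scale entered the published pair correlations, is not
  stated in the source; the package documents its choices (paired; −ΔCt)
  and exposes the alternatives.
- Enrichment reproduces the procedure only; with small study lists the
  jackknifed tail rarely reaches significance, by design.
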