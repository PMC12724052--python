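# Methods

This note documents the statistical models, estimators, defaults, and known
limitations of the pipeline, in the order the stages run.

## Protein filtering and zero handling

Reversed-sequence decoy hits and known contaminants are removed first, then
proteins identified by fewer than `min_unique_peptides` (default 2, read as
"at least two") unique peptides.  For reporting, each protein is counted
once under the precedence reverse → contaminant → unique peptides, so the
`FilterReport` always reconciles (`n_kept = n_input − Σ removals`).

Zero intensities denote censored (undetected) signals, not true zeros, and
are converted to NA *after* filtering and *before* normalization.  The
default converts every zero cell; because "overall estimated intensity of
zero" can also be read per protein, a row-wise mode (`mode="row"`: only rows
whose total intensity is zero become fully missing) is provided.  The reader
never destroys zeros — encoding decisions stay out of the parsing layer.

## Variance-stabilizing normalization

**Model.** Raw intensities are assumed to follow the two-component error
model `x = m·e^η + ε` with multiplicative noise `η ~ N(0, S²)` and additive
noise `ε ~ N(0, σ²)`.  The transform applied to each present cell of sample
`s` is `h_s(x) = arsinh(a_s + b_s·x)`, the generalized-log (glog) family:
logarithmic above the crossover `1/b_s` (stabilizing multiplicative noise)
and linear below it (not inflating additive noise).

**Estimation** (deterministic, no tuning parameters beyond
`reference_fraction`, `max_iter`, `tol`):

1. *Relative scales.*  On a rank-invariant reference set (proteins present
   in ≥ 80% of samples with row means inside the IQR of row means), relative
   sample scale factors `s_s` are fitted by iterating medians of
   sample-to-reference ratios, normalized to geometric mean 1.
2. *Noise components.*  On scale-corrected data, `Ŝ` is the median per-row
   coefficient of variation of the reference rows and `σ̂²` the median excess
   variance (total minus multiplicative) of the lowest-decile rows.
3. *Crossover.*  `b_s = Ŝ/(σ̂·s_s)` is the first-order variance-minimizing
   crossover for the model above.  Because the delta-method rule leaves a
   second-order ripple (~±8% of the stabilized SD) in the transition zone —
   large enough that a robust trend test at 1000 proteins always detects
   it — the global scale of `b` is then calibrated directly against the
   stabilization objective: a bisection root-find of the Theil–Sen slope of
   per-protein SD versus mean rank, the moment-based analogue of the
   maximum-likelihood profile fit used by the reference implementation of
   this normalization family.  If the trend never changes sign on
   [1/16, 16]× (e.g. purely multiplicative noise, where any log-like member
   works), the grid point with the smallest absolute trend is used.
4. *Offsets.*  `a_s` aligns transformed per-sample reference medians; under
   exact proportionality between samples it is 0 and `b` scales inversely
   with the sample scale (`sample2 = 2·sample1 ⇒ b₂ = b₁/2`).

The transform is strictly increasing within each sample, so within-sample
orderings are preserved; missing values stay missing.

## Preranked GSEA engine

The ranking statistic is sorted descending with a stable sort; tied
statistics keep input order and are reported in a warning.  For a set with
`N_hit` members among `N` ranked items, the running sum increments by
`|stat|^w / Σ_hits |stat|^w` at hits (`w` = 1 by default; `w` = 0 recovers
the classic Kolmogorov–Smirnov statistic) and decrements by `1/(N − N_hit)`
at misses.  ES is the running-sum value at its maximum absolute deviation
(first such position on exact ties); the leading edge contains the set genes
at or before the extremum for positive ES, at or after it for negative ES.
If every hit weight is zero (a fully tied ranking), hit increments fall back
to `1/N_hit`.

**Permutation null.**  Only a ranking exists, so the null redraws the hit
positions uniformly (gene-label permutation preserving set size).  With the
observed ES's sign side of the null (counts `n_side`, extreme count `k`):
`p = (1 + k)/(1 + n_side)` and `NES = ES / mean(|null ES| of that sign)`
(the 2005 signed-mean convention; ES = 0 gives NES = 0, p = 1).  When the
same-sign side holds fewer than 10 permutations — which happens for strongly
bimodal rankings whose null is essentially one-sided — the comparison falls
back to the sign-agnostic `p = (1 + #{|null| ≥ |ES|})/(1 + n_perm)`; an
observed ES on the empty side is extreme evidence, and the naive formula
would report p ≈ 1 for it.  BH adjustment runs across all tested sets.
Sets outside `[min_size, max_size]` (defaults 5/500 for pathway runs) or
without overlap are returned with a skipped status, never silently dropped.
Defaults: 10 000 permutations for pathway analyses, 1 000 inside the
per-sample QC loop; both configurable.

## Blood-contamination score

Per sample, proteins are ranked by `value − mean over samples with present
values` (proteins missing in the sample are excluded; samples with fewer
than 50 present proteins are rejected as unscorable).  Preranked GSEA
against the adipose-elevated and blood-elevated signatures (size limits
bypassed) yields `(ES, p)` pairs, combined as

`score = [(1 − p_a)·sign(ES_a) − (1 − p_b)·sign(ES_b)] / 2 ∈ [−1, +1]`,

with `sign(0) = 0` so a degenerate zero enrichment contributes nothing.  The
p-values are each set's own permutation p (no BH) — the formula uses per-set
significance.  Samples strictly below the cutoff (default −0.75) are
excluded.  The formula's outer division by 2 applies to the whole bracketed
difference; that is the only reading consistent with the stated [−1, 1]
range.  Note the score is *relative*: it measures deviation from the cohort
mean, so it discriminates contaminated from clean samples only when the
cohort actually contains both kinds; in an entirely clean cohort the scores
are noise around zero.

## Differential abundance

Per protein, ordinary least squares of normalized abundance on group plus
covariates, on complete cases.  Group follows the deposited coding
(patients 0, controls 2), so a positive coefficient means higher in controls
and the full patient→control difference is `2 × coef`; results tables also
carry the negated, obesity-oriented coefficient.  Covariates: presurgery
weight-loss % (0 for controls), sex (female 0/male 1), sleep apnea, lipid
medication, blood-pressure medication (0/1).  T2DM is available but off by
default.  With one sample per subject no random-effect grouping is
identifiable, so the model is fixed-effects only.  Two-sided t-tests per
coefficient; BH-FDR per model term across all tested proteins.

**Testability filters.**  A protein is tested only if observed in at least
`min_n` samples (default 10), at least `min_n_per_group` (default 3) samples
of each group, and at least `min_present_fraction` (default 50%) of all
samples; otherwise it is reported as skipped and excluded from the FDR pool.
The presence-fraction rule matters statistically, not just practically:
proteins observed only near the detection limit have intensity-dependent
(not-at-random) missingness; selection compresses their observed residual
variance while per-sample detection depth varies, which can produce
arbitrarily extreme nominal p-values under the null.  No fixed-effects model
on observed values can absorb that bias — it must be filtered (or modeled
with censoring machinery that is out of scope here).  With the filter the
null false-discovery proportion of the FDR < 0.05 call set is at its nominal
level within Monte-Carlo error; the acceptance suite measures this.

The ranking handed to pathway GSEA is the group-term t-statistic,
sign-flipped so that positive means higher in obesity (configurable).

## Correlation screens

Spearman rho with mid-rank ties and the t-approximation p-value, computed
per protein×variable pair on pairwise-complete observations and only when at
least 10 paired measurements exist (the rule is sharp: n = 10 included,
n = 9 omitted).  Constant vectors yield an explicit undefined status rather
than NaN.  Screens run on all samples or within patient/control strata,
because whole-cohort and within-group associations answer different
questions.  No per-correlation multiplicity adjustment is applied; FDR
control happens at the enrichment stage, where sets are ranked by rho.

## Metabolite associations

Per measure: natural-log transform (non-positive values are an error by
default; an explicit `half_min` policy substitutes half the smallest
positive value), z-scoring on the pooled complete cases, logistic regression
of case status (patient = 1) on the z-score plus age, Wald 95% CI, BH across
measures, direction labels (up/down/ns) at FDR < 0.05.  The odds ratio is
per 1 SD of the log-measure, so rescaling a measure changes nothing.
Complete separation is detected (non-convergence, diverging estimates, or a
perfect-separation signal) and handled by an L2-penalized Newton fit with
standard errors from the penalized Hessian, flagged in the output rather
than crashing.  Group comparisons of single variables use the two-sided
Mann–Whitney U test: exact for n ≤ 8 per group without ties, otherwise the
tie-corrected normal approximation without continuity correction (keeping
null p-values close to uniform).

## Synthetic-data generator

The generator is first-class, tested code.  Study-scale defaults: 39
patients + 16 controls, 2412 quantified proteins, 168-gene adipose and
207-gene blood signatures, three contaminated samples per group; every test
shrinks dimensions explicitly.  Log-intensities are
`μ + baseline_p + sample_s + structure + ε` with `σ_baseline = 1.5`,
`σ_sample = 0.15`, residual `σ = 0.4` (a typical label-free residual SD on
the glog scale); intensities are `exp` of that.  Structure:

* *Tissue signatures.*  Adipose-elevated genes are raised by
  `signature_effect` (default 2.0 log units) times a per-gene Gamma(4, ¼)
  amplitude (mean 1) — tissue-elevated genes are heterogeneously, not
  uniformly, elevated.  A contaminated sample with mixing fraction λ is the
  convex log-scale mixture: adipose genes at `(1−λ)`, blood genes at `λ`
  times their effect.
* *Group effects.*  `frac_de` of proteins get a fixed-magnitude
  (`effect_size`, default 1.5 log units ≈ 4.5-fold), random-sign
  patient-minus-control shift.  Candidates are proteins outside the
  signatures with baseline abundance above the 40th percentile: planting a
  recovery benchmark on proteins the instrument cannot reliably quantify
  makes "recovery" ill-posed, so, as in spike-in benchmark design, truth is
  planted on quantifiable proteins.
* *Missingness.*  A cell is recorded as zero with probability
  `1/(1 + exp(steepness·(L − L₀)))`, logistic-decreasing in latent
  log-intensity, with `L₀` at the `missing_rate` quantile (default 0.12) and
  steepness 3/ln-unit — a detection-limit transition of roughly one ln unit,
  in the range reported for label-free platforms.
* *Covariates.*  Weight loss only in patients (`N(7, 2.5²)%`, clipped
  positive); sex 90% female in patients vs 45% in controls; sleep apnea
  45%/5%; lipid medication 30%/10%; blood-pressure medication 50%/15%;
  age `N(40, 12²)` clipped to 18–60 in both groups.  These induce realistic
  group–covariate collinearity (group variance-inflation factor ≈ 3–6 in the
  differential design).
* *Metabolites.*  Per measure, a latent standard-normal score with a
  location shift Δ for patients, where Δ solves `Δ·√(1 + pq·Δ²) = β` so the
  planted `β` is exactly the log-OR per *pooled* SD that the analysis
  estimates; log-normal measures are `exp(μ_m + σ_m·z)`.  Defaults plant
  β = −1 on 15 measures and +1 on 10 of a 30-measure panel.

All randomness derives from one seed through named `SeedSequence` child
streams (structure / intensity / missing / metadata / junk / metabolites /
pathways), so any component regenerates bit-identically in isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: peptide-level quantification and razor-peptide
ambiguity; correlated protein modules (beyond the two signatures, proteins
are independent given sample effects); batch/run-order drift; heavy-tailed
or protein-specific residual variances; covariate effects on the proteome
other than the group contrast; departures of real detection curves from a
single logistic.  Recovery rates measured here are therefore upper bounds on
what identical settings would achieve on real cohorts.

## Numerical and design choices

* Ranked-list ties are broken by input order after a stable sort, with a
  logged warning; proteins sharing a gene symbol are collapsed to the
  occurrence with the largest absolute statistic.
* `bh_adjust` is the textbook step-up (sort, `p·m/rank`, reverse cumulative
  minimum, cap at 1), order-preserving.
* The per-protein OLS batches proteins by missingness pattern and solves
  each pattern's normal equations once; results match statsmodels OLS to
  numerical precision (tested).
* The contamination score accepts p = 0 as the limiting case of a vanishing
  permutation p-value, so the analytic bounds ±1 are attainable exactly;
  p-values produced by the engine itself are always positive.
* Pipeline runs are pure functions of (inputs, config, seed): stage seeds
  are derived deterministically, result files are written with fixed float
  formatting, and the manifest contains no timestamps, so reruns are
  byte-for-byte identical.
* Desk-scale problem sizes used by the test and acceptance suites (e.g.
  1000 proteins × 54 samples × 50 replicates for the null FDR study;
  800 proteins × 30 samples × 20 seeds for contamination separation) were
  chosen so the full suite completes in a few minutes while keeping every
  statistical margin comfortable.

## Known limitations

* The glog calibration targets a flat SD-vs-mean-rank trend; under noise
  models far from additive+multiplicative (e.g. strong count-like noise) the
  fitted crossover is only a best compromise.
* MNAR censoring is filtered, not modeled; proteins quantified in under half
  the samples are never tested for differential abundance.
* The permutation GSEA p-value resolution is `1/(1 + n_perm)`; very small
  p-values require raising `n_perm` (there is no multilevel refinement).
* The contamination score is cohort-relative (see above) and undefined for
  cohorts of one tissue composition.
* The ridge fallback under complete separation yields finite but
  shrinkage-biased odds ratios; they are flagged and should be interpreted
  qualitatively.
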