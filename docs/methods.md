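# Methods

## The analysis problem

`cpglink` implements a candidate-gene DNA-methylation analysis linking a
continuous childhood-maltreatment exposure (CTQ-SF total, theoretical range
25–125) to a continuous depressive-symptom outcome (BDI-II total, 0–63)
through the percent-methylation levels of CpG units measured in
stress-related candidate genes. Methylation is treated both as a putative
**mediator** (maltreatment → methylation → depression) and as a putative
**moderator** (the maltreatment–depression slope depends on methylation
level). All models are ordinary least squares on complete cases; no
imputation is performed.

A *CpG unit* is one assay fragment covering one or more adjacent CpG
dinucleotides, reported as a single percent value in [0, 100] (EpiTYPER-style
quantification). Percent scale, not beta (0–1), is canonical throughout,
because coefficient scales in the reported tables are per-percent. GRCh37
1-based coordinates; no strand field (mass-spectrometry units carry none).

## Preprocessing

Applied in a fixed, audited order; unit accounting
(`units_in = removed + merged_away + analyzed`) is asserted every run.

1. **Winsorization** of the two questionnaire totals only: values beyond
   mean ± 3 SD (moments from the input sample) are replaced, by default,
   with the most extreme *observed* value inside the bound. A second mode
   replaces with the bound itself (mean ± k·SD). Both are exposed because
   the two readings of "highest value within three standard deviations"
   differ and neither is unambiguously standard; the observed-value mode is
   the default as the more conservative one (never creates unobserved
   values). Winsorization is not iterated in the pipeline; tests show the
   map converges to a fixed point within a few passes if iterated.
2. **Missingness filter**: units with > 20% missing values are dropped.
3. **Zero-inflation filter**: among survivors, units whose non-missing
   values are > 80% exactly zero are dropped (assay floor artifacts).
4. **Perfect-duplicate collapse**: same-gene units with pairwise Pearson
   r ≥ 1 − 1e−9 (pairwise-complete, ≥ 3 pairs) are merged transitively;
   the merged value is the per-participant mean (symmetric, and identical
   to either member when they are exact copies). The 1e−9 tolerance absorbs
   the few ulps by which floating-point r of exact duplicates can miss 1.0.
5. **Region grouping**: within a gene, units sorted by coordinate are
   chained when adjacent units are ≤ 500 bp apart *and* correlated at
   r ≥ 0.50; a region's value is the available-case mean of its members.
   Chaining (nearest-neighbour) rather than all-pairs cliques is used:
   promoter tilings are naturally sequential, and the all-pairs reading
   would make region membership depend on distant members. Regions are
   analyzed as a separate family; singleton units stay unit-level.

Upstream assay exclusions (high/low mass, technical duplicates) have no
computable definition from the matrix alone and are accepted as a
pre-excluded unit list in the annotation, not recomputed.

## Screening and confounders

Each unit is screened with methylation as the dependent variable and the
exposure (or the outcome) as the independent variable — matching the
convention of the study design this mirrors — unadjusted and adjusted for
the retained confounders. Two-sided t-tests; per-row failures (zero-variance
units, rank deficiency) are recorded, not fatal.

Candidate confounders (age, smoking, drug use, alcohol, BMI) are retained
when a simple regression links them at p < 0.10 to the exposure, the
outcome, or at least one methylation unit. Note that with hundreds of units
this rule retains almost any candidate; it is faithful to the stated
procedure, and the per-candidate qualifying associations are logged so the
decision is auditable.

Benjamini–Hochberg adjustment (via `statsmodels.multipletests`) is applied
per screen family — exposure-screen units, outcome-screen units, moderation
interactions — with region-level tests always a separate family. Whether
the original analysis pooled families is unstated; per-screen is the
default and is recorded in the run summary. Note that under a global null
BH at q = 0.20 still produces ≥ 1 false discovery in about 20% of runs per
family — FDR equals FWER there — so "no findings survive FDR" is the
*typical*, not guaranteed, null outcome.

## Mediation

For units significant in **both** screens (adjusted flags by default), and
for their cumulative index, the two-model estimator is fitted:

    M = i₁ + a·X + γ'C            (a-path)
    Y = i₂ + c'·X + b·M + δ'C     (b-path and direct effect)

ACME = a·b, ADE = c', total = a·b + c' (no exposure–mediator interaction
term, so the decomposition is exact). Uncertainty is quasi-Bayesian: 1,000
coefficient vectors are drawn from each model's estimated multivariate
normal sampling distribution; per draw the effects are recomputed, and 95%
percentile intervals are reported, with p = 2·min(P(draw ≤ 0), P(draw ≥ 0)).
Coefficient simulation was chosen over case resampling because it is
deterministic-by-seed and much faster; a nonparametric bootstrap mode is
included for sensitivity and agrees closely on well-behaved linear models.
Draws with |total| < 1e−8 are excluded from the proportion-mediated ratio
CI and counted in the run summary.

**Cumulative mediator index.** The index sums the candidate units'
methylation. Default mode is *sign-aligned*: each unit enters with the sign
of its exposure association (Σ sⱼ·Mⱼ), so opposite-signed mediators
reinforce rather than cancel; a literal raw sum is available
(`--index-mode literal`). Sign-aligned is the default because a raw sum of
two mediators with opposite-signed exposure paths would have a near-zero
a-path, contradicting the positive cumulative-index path the design
anticipates; the chosen mode is recorded in every output.

## Moderation

Exposure and moderator are mean-centered on the analysis sample; the
product is formed after centering; OLS with covariates. With centered
inputs the conditional slope at moderator level m is b_x + b_xm·m, with
SE² = Var(b_x) + m²·Var(b_xm) + 2m·Cov — verified in tests against a
re-centering refit oracle. Default simple-slope levels are mean ± 1 SD.

**Tertile risk score.** Units with a significant interaction (adjusted
models when confounders are retained) are each cut at empirical 1/3 and
2/3 quantiles (linear interpolation; ties at a cutpoint fall to the lower
tertile — deterministic and order-independent, since no convention was
stated); participants score −1/0/+1 per unit, oriented by the interaction
sign, and the scores are summed. Missing unit values contribute 0 and are
counted. Cumulative moderation refits the interaction model with the score
as moderator and reports conditional slopes at the mean score of three
equal score groups. "Three equal groups" is read as tertiles of the risk
score (not of predicted methylation). Johnson–Neyman regions are not
computed.

## Synthetic cohorts

The generator mirrors the fitted models, so every stage has ground truth:

* exposure: shifted gamma with floor 25 (CTQ totals are right-skewed),
  rejection-truncated to [25, 125], calibrated to mean 37.43 / SD 11.04;
* methylation: unit mean + a·(X − X̄) + covariate terms + optional region
  latent factor + Gaussian noise, clipped to [0, 100]; duplicates copied
  exactly; missingness MCAR per unit (no mechanism was reported, so none
  richer is modelled), applied after the outcome is computed;
* outcome: baseline + c'·(X − X̄) + Σ bⱼ(Mⱼ − μⱼ) + Σ ωⱼ(X − X̄)(Mⱼ − μⱼ)
  + covariate terms + Gaussian noise, clipped to [0, 63]. Interactions are
  generated on centered scales so c' keeps its main-effect meaning. The
  outcome is continuous by default (`round_outcome` adds integer rounding).

The default truth is the study conditions: n = 156, 191 units across the
nine candidate genes (per-gene counts matching the assay panel), CTQ/BDI
moments as above, two mediating units with opposite-signed a-paths
(+0.04/−0.05 %/point) and b-paths (+0.47/−0.39 points/%), direct effect
c' = 0.21 (total ≈ 0.25, proportion mediated ≈ 16%), fourteen moderating
units with mixed-sign interactions ≈ ±0.02–0.04, residual outcome SD 8.0,
2% MCAR missingness, and planted age/drug effects on methylation and
outcome so confounder selection has structure to find.

**Clipping.** The fraction of values clipped at the scale bounds is
recorded per variable in `cohort.meta`; a truth clipping > 50% of a
variable triggers a "degenerate truth" warning surfaced in the run summary.
At the default truth ~10% of outcome draws hit the BDI floor — realistic
for a general-population sample whose BDI piles up near zero — which
slightly attenuates outcome-side slopes relative to the latent
coefficients. Parameter-recovery tests therefore use truths with the
outcome baseline mid-scale (clipping < 1%) so the OLS estimand equals the
planted value; this is a property of bounded scales, not of the estimators.

**What the generator does not emulate:** integer questionnaire scores (by
default), cell-type composition, batch effects, assay heteroskedasticity
(noise SD independent of the mean percent), non-MCAR missingness, and
genomic correlation beyond the explicit duplicate/region maps. Passing
tests therefore demonstrate estimator correctness and calibration under
the stated generative model, not robustness to those real-data features.

## Determinism and numerics

A single global seed spawns named per-stage child seeds via
`numpy.random.SeedSequence`, so adding a stage never perturbs earlier
stages' randomness; identical inputs and seed give byte-identical reports.
Correlations require ≥ 3 pairwise-complete observations, else the pair is
skipped with a warning. OLS requires n ≥ p + 2 complete cases and full
column rank; offending terms are named in the error. Multivariate-normal
coefficient draws use the SVD square root, tolerant of the
positive-semidefinite covariances that arise in near-perfect fits.

## Problem sizes in the test suite

Simulation-based checks use 100–500 replicates at n = 156–800 with small
unit panels, and the full 156 × 191 default cohort for end-to-end and
determinism checks; these sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping the default suite around a minute.
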