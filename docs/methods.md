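# Methods

## The stratification model

`quadstrat` stratifies an epilepsy cohort on two plasma axes measured by
Olink proximity-extension assays.

**Composite pro-inflammatory score.** For each protein in a fixed block of
12 cytokines/chemokines (CASP1, CCL11, CCL2, CCL3, CXCL8, IFNG, IL17A,
IL18, IL1B, IL2, IL6, TNF), per-patient NPX values are standardized to
Z-scores over the full cohort and summed. Standardization uses the sample
standard deviation (n−1 denominator); the convention is immaterial
downstream because the banding step is percentile-based and percentiles are
invariant to a common rescaling. Z-scores are always computed over the
complete cohort — before any exclusion — so that the percentile split acts
on all patients.

**Banding and quadrants.** The score is cut at its 40th and 60th
percentiles (linear interpolation, rank = 1 + p·(n−1)): strictly below P40
is "low inflammation", strictly above P60 "high", and the central ~20 % is
deliberately unclassified, trading sample size for contrast between the
bands. Plasma NEFL is dichotomized at 0.5 NPX, a configuration constant
calibrated externally against an absolute immunoassay (10 pg/mL, the
abnormality threshold for ages 18–50); values exactly at the cutoff are
"normal" (the rule is "above which abnormal"). Crossing the two axes yields
four quadrants; an unclassified inflammation band always dominates and
removes the patient from quadrant analyses.

**Clinical category rules.** "Recent seizures" means the last seizure was
≤ 61 days ago, "intermediate" 62–365 days, "seizure-free" > 365 days or no
seizure on record; the calendar phrases "2 months" and "1 year" are
operationalized as 61 and 365 days (configurable constants). Drug-resistant
epilepsy (DRE) requires ≥ 2 anti-seizure medications and a seizure within
the last year; well-controlled epilepsy (WCE) exactly one medication and
seizure freedom for over a year; everyone else — including untreated
patients — is undetermined. The 1-year window for DRE/WCE is the complement
of "seizure-free", so the two derivations share one rule. Two-month seizure
counts are binned 0 / 1 / 2–100; counts above 100 are rejected as outside
the supported range.

## Statistics

* Categorical covariate × quadrant: Pearson chi-square of independence,
  no continuity correction, no minimum-expected-count exclusion (a warning
  is logged when an expected count is below 5 — the published statistics
  this package reproduces were themselves computed on such tables, which
  fixes the convention). When the omnibus test is significant, every
  unordered row pair is tested on its 2×c sub-table and the p-values are
  Benjamini–Hochberg adjusted across pairs; a column whose margin is zero
  within a sub-table is dropped for that pair only.
* Continuous covariate × quadrant: Kruskal–Wallis H with tie correction,
  p from χ²(k−1); if significant, Dunn's pairwise z tests on mean pooled
  ranks with the tie-corrected variance N(N+1)/12 − Σ(t³−t)/(12(N−1)),
  two-sided normal p, Bonferroni-multiplied. An all-tied pool returns
  H = 0, p = 1 rather than an error.
* Correlations: Spearman with mid-ranks, two-sided p from the t
  approximation on n−2 df. For n ≤ 10 an exact permutation p is available;
  it enumerates all pairings directly (the rank correlation depends on a
  permutation only through a dot product, so the n! arrangements are scored
  in vectorized chunks). Correlation-plot highlighting uses |r| > 0.1 and
  p < 0.05.
* Multiple testing: BH step-up and Bonferroni, both returning values in
  input order, capped at 1. Bonferroni dominates BH element-wise; both are
  property-tested.

## Correspondence analysis

The contingency table is converted to the correspondence matrix P = N/n,
and the standardized residuals S = D_r^(−1/2)(P − rcᵀ)D_c^(−1/2) are
decomposed by SVD. Both row (quadrant) and column (category) points are
reported in principal coordinates — the symmetric map — and association is
summarized by Euclidean distance between a row point and a column point in
the first two dimensions. Two caveats are deliberate design: (i) the
symmetric-map normalization is the one that exactly reproduces the five
published quadrant–category distances from the published tables, which
fixes the convention empirically; (ii) row-to-column distances in a
symmetric map are descriptive proximities, not chi-square distances, and
carry no inferential calibration. Total inertia (Σσ²) times the grand total
equals the Pearson chi-square; this identity is enforced in tests on the
fixtures and on random tables. Singular-vector signs are unconstrained and
all consumers are sign-invariant. For the 4×3 tables here only two
nontrivial dimensions exist, so k = 2 retains everything.

## Differential expression

NPX is log2-scale, so the difference of group mean NPX is the log2 fold
change (the Olink convention; not the log of a ratio of linear-scale
means). The per-protein test is Welch's unequal-variance t test by default
with a Wilcoxon rank-sum alternative behind a flag — the test is a
pluggable strategy because no single choice is canonical for this design.
BH-FDR is computed across all retained proteins, not only plotted ones.
Significance is the triple gate FDR < 0.05 ∧ p < 0.05 ∧ |log2FC| ≥ 1;
a relaxed variant lowers the fold-change gate to > 0.5. Zero p-values are
clamped to the smallest positive float for volcano coordinates (and
logged). The top-20 labeling orders by ascending p, breaking ties by
descending |log2FC| and then symbol, for determinism.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the assay chemistry:

* **Latent inflammation factor.** A single standard-normal factor u drives
  the block: protein p is a_p·u + √(1−a_p²)·ε with a_p = √ρ_block
  (default ρ_block = 0.4), reduced by 0.6 for CASP1 and IL2, which are the
  block members known to couple most weakly. A single-factor structure is
  the simplest model producing an all-positive correlation block without
  claiming any particular covariance.
* **NEFL coupling.** NEFL = λu + √(1−λ²)e, scaled to NPX (location 0,
  scale 0.75, putting ~25 % of patients above the 0.5 cutoff). λ is solved
  analytically so the induced Spearman correlation with the composite score
  hits the target (default 0.1): corr(u, S) follows from the loadings, and
  the bivariate-normal identity ρ = 2·sin(πρ_s/6) converts the Spearman
  target to the Pearson scale. At n = 5000 the realized correlation lands
  within ±0.01 of target.
* **High-high stratum and outcomes.** Patients with u above its 60th
  percentile and NEFL above the cutoff form the latent high-high stratum.
  They receive `outcome_odds` (default 4)-fold odds of recent seizures and
  of ≥ 2 medications — the combination downstream rules read as DRE — and a
  +1 NPX shift on MMP1, VEGFA and HGF (blood–brain-barrier markers). The
  tilt is compensated in the remaining patients so cohort-level marginals
  stay at their configured values (50/40/10 seizure status,
  9/55.7/23.3/11.9 % medication counts, 58.5 % female, ages uniform 18–50).
  The BBB proteins carry no factor loading, so the planted shift is
  recoverable exactly as a stratum mean difference; their correlation with
  the inflammation score arises through the shift itself.
* **Background proteome.** 50 unnamed proteins load weakly (0.2) on u; the
  rest are independent noise with random NPX locations and scales.
* **Determinism.** All randomness flows from one integer seed through
  spawned seed streams (latents / clinical / NPX), so the clinical table
  and the matrix can be regenerated independently and agree on latent
  state.

What the generator does **not** emulate: plate and bridge effects, limits
of detection, hook effects, missing cells, non-Gaussian tails, or any
realistic epilepsy-subtype covariance. Passing tests therefore demonstrate
that the machinery recovers planted structure under clean Gaussian
conditions, not that it is robust to Olink artefacts.

## Problem sizes and numerical choices

Tests run study-sized cohorts (n = 176) with 40–120 proteins — the 16
named proteins plus background — wherever the check does not depend on
proteome width; the differential-expression null calibration runs at the
full 1447-protein width, and law-of-large-numbers checks use n = 5000.
The quadrant-level chi-square on synthetic nulls runs conservative
(rejection ~2–4 % at nominal 5 %) because quadrant × status tables at
n = 176 put several expected counts below 5; the power/type-I tests assert
majority detection at the planted effect and a one-sided bound on the null
rate accordingly, while the Kruskal–Wallis/Dunn calibration on continuous
data is held to the tight (0.03, 0.07) band.

Exact ties with a percentile cut are never banded (strict inequalities);
exact mean-NPX ties in panel merging keep the lexicographically first panel
and warn; duplicate resolution compares arithmetic mean NPX, which orders
identically to the geometric mean on the linear scale but avoids
exponentiating log2 values.

## Known limitations

* Cross-set CA distances are descriptive only (see above).
* The per-protein DE test is a convention; with real Olink data a
  limma-style moderated test may be preferable at small group sizes.
* Subgroup (epilepsy-type) runs reuse quadrants computed on the full
  cohort by design; they re-tabulate, they do not re-band.
* The clinical generator draws covariates independently given the latent
  stratum; real cohorts have age–duration–type dependence it does not
  attempt.
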