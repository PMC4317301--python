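# Methods

This note documents the statistical model behind `memnet`, the design
choices that were genuinely open, and what the synthetic cohort does and
does not establish about real data.

## The analysis model

The scientific question is whether right dorsolateral prefrontal (DLPFC)
volume predicts verbal memory differentially across the ability range.  The
core tool is segmented (breakpoint) regression with memory z-score `x` as
the abscissa and ICV-residualized volume `y` as the response:

    y = β₀ + β₁·x + δ·(x − ψ)₊ + ε

The hinge basis `(x − ψ)₊` keeps the two segments continuous at the
breakpoint ψ and makes δ exactly the difference in slope between them, so
the t-test of δ = 0 is the slope-difference test.  The scan evaluates this
test at 120 candidate ψ values placed at evenly spaced quantiles of `x`
between its 10th-smallest and 10th-largest observations (quantile rather
than equal-z spacing guarantees feasible segment sizes for any score
distribution; candidates are additionally clamped just below the upper
order statistic so that ties — inevitable in composites of integer test
scores — can never leave a segment short).  Among candidates with p < .05
(raw, uncorrected: the scan is descriptive and its profile is reported in
full), the selected ψ is the one dividing the sample most evenly, ties
broken by smaller p, then lower ψ.  An empty significant set is a
legitimate "no breakpoint" outcome, expected for the right IFG control
region, and downstream stages are skipped and reported as such.

A free-lines variant (two unconstrained lines per candidate, Welch-style
slope comparison) is available via `scan_breakpoints(..., model="free")`
and the pipeline's `scan_model` flag, since a "two-segment model" can be
read either way; the hinge is the default because the re-parameterized
model is explicitly joined at the breakpoint.

Supporting procedures:

- **Williams' t** (the Steiger formulation, df = n − 3) compares two
  dependent correlations sharing one variable; it is used for all
  lateralization contrasts.  The pairing is always evaluated on the cases
  jointly complete for the memory composite and both compared variables,
  which is what produces the characteristic df pattern (n = 88 → 85 for the
  frontal contrast, 89 → 86 for the hippocampal one, and a joint-complete n
  for the two-tract contrasts).
- **Fisher's r-to-z** compares correlations from disjoint subsamples
  (the two segments).  The signed segment correlations are compared; a
  noise-free segment (|r| = 1, arising only in degenerate synthetic data)
  is reported as an infinitely significant difference rather than an error.
- **Hierarchical stepwise OLS**: predictors ordered by |r| (ties broken
  alphabetically), one OLS per step, standardized β from z-scored
  variables.  The default sample mode is `per_step` (each step uses the
  cases complete for the predictors entered so far, so the sample shrinks
  as predictors with more QC exclusions enter — matching a df trajectory
  like 1,84 → 2,82 → 3,79); `listwise` fits all steps on one sample and is
  the mode under which ΔR² ≥ 0 holds exactly.
- **Welch's t** with Welch–Satterthwaite fractional df for the network
  composite group comparison; the mean-100/SD-15 component scaling is
  affine, so results are identical to comparisons on plain z-scores (this
  equivalence is asserted in the tests).
- **ICC(A,1)** (two-way, absolute agreement, single measures) and
  Bland–Altman limits of agreement (mean difference ± 1.96 SD of
  differences) qualify the manual volumetry.  Absolute agreement is used
  because a constant inter-occasion offset should be penalized;
  single-measures because single-rater volumes feed the analysis.

## Preprocessing conventions

- Z-scores use the analysis sample with the n−1 SD throughout, including
  the mean-100/SD-15 scaling.
- Memory composites are the mean of the two relevant test z-scores (LM I +
  VPA I for Immediate; LM II + VPA II for Delayed); where exactly one score
  is missing the available one is used alone.  Composites are *not*
  re-standardized, so their SD is √((1+r)/2) ≈ 0.87 at the default
  inter-test correlation — the breakpoint ψ lives on this scale.
- Each regional volume is residualized on ICV per-region, on that region's
  complete cases (not listwise), preserving the per-block n's.
- Winsorization clips values beyond mean ± 3 SD to the boundary, iterating
  until the band is stable.  The iteration matters: clipping strictly
  shrinks the SD, so a single pass is never exactly re-applicable — the
  fixed point makes the operation a true projection (idempotent), while
  differing from a single pass by only a small fraction of an SD for the
  marginal outliers it is intended for.  Whether winsorization happens
  before or after residualization is a config switch
  (`winsorize_order`), defaulting to residualize-then-winsorize; note that
  winsorizing a residual perturbs its exact orthogonality to ICV on the
  clipped cells.

## The synthetic cohort

The generator emulates the joint structure the analysis assumes, via a
latent-factor construction rather than a raw 15×15 covariance (easier to
keep positive definite and to parameterize by reported correlation
targets):

- One standard-normal **memory factor** drives all four test z-scores with
  equal loadings √r, so every test pair correlates at `intertest_r`
  (default .53).  Raw scores are mean + SD × z, rounded to integers and
  clipped at each test's maximum — the VPA II ceiling (max 8, mean 6.09)
  is a deliberate, realistic source of right-censoring.
- One **ICV factor** carries `icv_loading` (default .25, matching a
  typical region–ICV correlation of ≈ .5) of each regional volume's
  variance, so regressing volume on ICV recovers R² ≈ .25.
- **Network variables** (splenium FA, right hippocampus, left DLPFC) load
  on the memory factor so that their population correlation with *both*
  composites is `network_effect_r` (default .28).  Genu FA/MD, splenium
  MD, left hippocampus and both IFGs carry no memory effect.
- The **right DLPFC** relates to the continuous Immediate composite
  through a hinge in the volume-given-memory direction: slope
  b·(C − ψ*)₊ below ψ* (`hinge_psi_true`, default −.3), zero above.  The
  slope b is calibrated in closed form from truncated-normal moments so
  the below-hinge conditional correlation equals `hinge_r_low`
  (default .45) while the marginal variance stays 1.  Monte-Carlo checks
  confirm the realized below-hinge correlation within ±.07 (≈ .42; the
  shortfall is rounding/ceiling attenuation, accepted as a small bias) and
  no leakage above the hinge.
- QC missingness blanks seeded-random rows per block (defaults 2 frontal,
  1 hippocampal, 7 genu, 4 splenium, 1 VPA), reproducing complete-case
  counts of 88/89/83/86 and exercising the LM-only composite fallback.
  Eight participants are flagged left-handed.  An optional
  `measurement_reliability` map adds test–retest noise; it is off by
  default.

What the generator does **not** emulate: spatial structure of any kind,
intra-construct correlations higher than inter-construct ones (a single
memory factor makes all six test-pair correlations equal), skewness or
floor effects beyond integer rounding, and age variation (the emulated
cohort is a single-year birth cohort).  Two consequences matter for
interpretation.  First, a one-sided hinge with zero slope above necessarily
induces a *positive group-level* right-DLPFC–memory correlation (≈ .2–.3),
whereas the emulated study found none; a generator that nulls the marginal
correlation would need a compensating negative slope above the hinge,
contradicting the "no association in high performers" structure being
modelled.  Second, passing tests demonstrate that the pipeline recovers
the structure this generator plants at these effect sizes — not that the
original study's specific estimates are correct.

## Numerical and power notes

- All segmented fits solve ordinary least squares directly (lstsq /
  normal equations on a 3-column design); tests verify agreement with an
  independent normal-equations solver at 1e-10 relative error.
- Both comparison tests hold their nominal .05 size at n = 90 (2000-rep
  Monte-Carlo, observed rates ≈ .046–.048).
- The slope-difference test at n = 90 with a below-hinge correlation of
  .45 has only ≈ 69% power at the true breakpoint (≈ 79% for
  any-candidate significance across the 120-point scan).  Consequently
  the joint qualitative event "DLPFC breakpoint with significant segment
  magnitude difference AND no IFG breakpoint" occurs in only ≈ 54% of
  synthetic cohorts — a power ceiling of the design at this effect size,
  not an implementation artifact (the emulated magnitude z of ≈ 2.2 itself
  corresponds to ≈ 55% power).
- The even-split selection rule is biased toward the sample median
  whenever most of the scan is significant; with the true hinge 0.3 below
  the median, the median absolute recovery error is ≈ 0.30.  Users who
  care about *locating* ψ rather than splitting power evenly should read
  the full scan profile (persisted as TSV) instead of the single selected
  breakpoint.
- Scan p-values are reported raw across the 120 correlated candidate
  tests; the family-wise any-significant rate under a pure-linear null is
  measured (not assumed) in the tests and is above .05, which is why
  selection, not the scan, carries the inferential weight.

## Monte-Carlo problem sizes

Calibration checks use 200 synthetic cohorts; test-size checks use 2000
replicates; the null alpha-level screen uses 300 cohorts.  These sizes give
Monte-Carlo standard errors comfortably below the tolerances being
asserted (e.g. ±.005 on a .05 rejection rate at 2000 reps).
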