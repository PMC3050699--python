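# Methods

## Model and estimation

All analysis happens on the natural-log scale, so multiplicative effects
become additive and results back-transform to geometric means and ratios.
The linear mixed model for a plot measurement has fixed effects for the
overall mean and the three-level genotype group (counterpart, GMO,
reference) and independent normal random effects for site (`V_s`),
block within site (`V_b`), genotype (`V_g`) and plot residual (`V_e`).

The two model variants differ only in which genotypes carry the random
genotype effect.  In variant 1 the GMO and counterpart are excluded
(their means are judged against plot error); in variant 2 they are
included, which adds `V_g` to the prediction variance of each of their
group means.  Because the extra random-effect columns of variant 2
coincide with fixed-effect columns, the restricted likelihood is
unchanged: a single REML optimisation serves both variants, and the seds
differ by the exact identities `sed_GC;2² = sed_GC;1² + 2V_g`,
`sed_GR;2² = sed_GR;1² + V_g` (valid for any layout, balanced or not).

REML maximises the restricted log-likelihood over the four variances
with an L-BFGS-B quasi-Newton iteration using analytic gradients,
non-negativity enforced by bounds (truncation at zero), a relative
deviance tolerance of 1e-10, three fixed starting points, and a fixed
evaluation order, so fits are reproducible bit-for-bit.  The residual
variance keeps a floor of 1e-10 times the response variance so the
marginal covariance stays invertible.  Dense n×n linear algebra is used
throughout; trial datasets are small (tens to a few hundred plots).

Degrees of freedom for the two contrasts use the Kenward–Roger
small-sample method (adjusted covariance plus the F-approximation df)
specialised to covariance structures linear in the parameters;
Satterthwaite is available through `df_method="satterthwaite"`.  The
implementation was validated against an independent reference
implementation on balanced and unbalanced synthetic layouts (agreement
to 1e-6 in seds, 1e-4 in dfs), and on balanced designs it reproduces the
classical ANOVA dfs exactly (residual df for GC under model 1,
`n_g − 1` for the model-2 contrasts).

Boundary policy: when `V_g` is estimated at zero the fit is flagged
degenerate; standard errors and dfs are then taken from the model that
omits the random genotype term.  Equivalence limits computed from such a
fit are typically far too narrow (the dfs are residual-order), so the
assessment returns no outcome type for these analytes.

## Limits, tests, classification

Equivalence limits are outer 95% confidence limits around the reference
mean, `m_R ± t(df_GR;2, 0.975) · sed_GR;2`, under model 2 — the option
that lets the estimation uncertainty widen the limits, appropriate when
observed reference variation understates the maximum acceptable
variation.  Test D uses the two-sided 90% interval of `m_G − m_C` under
model 1; E1 asks whether `m_G` lies inside the limits (equivalently, a
two-sided 95% model-2 test of `m_G − m_R`); E2/E3 compare
`m_G ± t(df, 0.95) · sed_GR;1` with the limits.  All levels are
configuration, not statistics: the defaults (90/95/97.5) follow the
convention that one pair of two-sided 90% intervals serves a 90%
difference test and 95% one-sided equivalence proofs.  One-sided
variants of the tests are available but off by default.

Tie policy: a point estimate or interval endpoint exactly on a limit is
treated as non-rejection of the relevant null — inside for E1, not
proven for E2/E3.  This is a measure-zero event chosen so proofs stay
conservative.

Outcome types: E3 proven → 7; E2 proven → 1 (no significant difference)
or 2 (significant); otherwise E1 inside → 3/4, E1 outside → 5/6; the
categories group {1,2}, {3,4}, {5,6}, {7}.  When the counterpart mean
itself falls outside the limits the classification is still returned but
the `counterpart_outside_limits` flag is raised: the counterpart is then
itself not equivalent to the reference range, which calls for a separate
non-statistical discussion rather than a different mechanical verdict
(the packaged maize study contains such cases, e.g. lysine, which
nevertheless carries an ordinary category-ii verdict).

Display: the adjusted limits
`(m_G−m_C) + [(m_R−m_G) ± lsd(GR;2;97.5)] · lsd(GC;1;95)/lsd(GR;1;95)`
rescale and shift the limits so that the single difference-test bar
reads off all four tests; this is an algebraic identity with the
canonical E2/E3 comparison, verified property-style on random fits.  The
multiplicative axis is log-scaled so 2× and ½× sit symmetrically.

## Preprocessing

An analyte is retained only if at least `min_quantified` (default 2)
results are quantified; an analyte whose results are all, or all but
one, below the reporting limit carries no usable variation.  Remaining
non-detects are set to half the reporting limit (configurable to
exclusion).  Outliers are an explicit user-supplied exclusion list —
they are expected to come from visual inspection of the diagnostic
plots, and no automatic rule is applied.  The "limit of reporting" is
treated as an opaque per-record threshold; whether it is a detection or
quantification limit does not enter the computations.  Preprocessing is
idempotent and fully logged (log length + retained count = input count).

## Summary-table route

Published per-analyte summaries (geometric means, variance components,
contrast seds/dfs and CI bounds) can be assessed without plot data:
`sed_GR;1` is recovered through the exact sed relation, and the model-1
GR df — rarely published — is proxied by the published GC df.  Where the
published CI bounds themselves are available they take precedence over
intervals recomputed from rounded seds, so borderline verdicts match the
published ones.  The adjusted-scale limits recomputed this way carry a
±0.02 uncertainty from the df proxy and the rounding of printed inputs.

## Simulation engine

The generator emulates a balanced multi-site randomised complete block
trial on the ln scale: 8 sites × 4 blocks × 8 genotypes (GMO,
counterpart, 6 references) with variance components
(V_s, V_b, V_g, V_e) = (0.0029, 0.0008, 0.0127, 0.0073) — the average
components across the 53 analytes of the packaged maize study.  GMO
rules: an independent draw from the reference distribution
(exchangeability), a fixed ln-scale offset `d`, or placement exactly at
the theoretical border; counterpart rules: reference draw, equal to the
reference mean, or identical to the GMO.  The equivalence border is
`z_0.975 · sed_GR;2` at the true components (0.2407 on the ln scale,
a 27.2% relative difference, for the defaults); the numeric value fixes
the normal quantile as the default rule, with a t option.

Per iteration the balanced closed-form (ANOVA/EMS) path supplies means,
mean squares and seds; on balanced data it coincides with iterative REML
up to the non-negativity truncation, which is asserted in the tests.
Dfs follow from the exact chi-square mixing of the two relevant mean
squares: residual df for `sed_GC;1`, `n_g − 1` for the model-2 seds, and
a Satterthwaite combination for `sed_GR;1`.

Equivalence-limit convention in the simulator: the operating
characteristics of E1/E2/E3 are properties of step E *conditional on*
step L, so by default the simulated tests use limits of the theoretical
half-width (known variance components) centred on the estimated
reference mean; per-iteration estimated limits are available via
`limit_rule="estimated"`.  Under the conditional convention the border
scenario shows the expected behaviour — E1 splits 50/50 and E2/E3 keep
their nominal 5% size — which estimated limits with so few reference
varieties (df 5) cannot deliver.

The semi-analytic oracle treats all seds as known (true components,
normal distributions; the E2/E3 quantile is a t at the true-component
Satterthwaite df) and serves as an independent check: it matches the
Monte-Carlo rates to well under one percentage point for D and E1, and
to about 2.5 points for E2/E3 at the border, where ignoring the spread
of the estimated sed biases the approximation low.

The null-hypothesis side study draws, per analyte, a variety difference
`d ~ N(0, 2V_g)` and tests `|d| > t(df, 0.975) · sed` with the published
per-analyte sed/df; over the packaged study this yields a mean of about
33.7 significant tests out of 53 (analytic expectation 33.6) with a 95%
count range of roughly (28, 40) — i.e. the 23 differences actually
observed are *fewer* than exchangeable genotype variation alone would
produce.

What the generator does not emulate: unbalanced layouts in the power
studies (the generator supports arbitrary layouts, but the
operating-characteristic studies assume balance), non-normal responses,
genotype-by-environment interaction (available as a separate Wald test,
mildly liberal in small samples as chi-square Wald tests are),
measurement error in the reporting limits, and year effects (designs
are single-year).  Passing tests therefore demonstrate correctness of
the procedure under its own model, not robustness to these departures.

## Problem sizes

The test suite and the acceptance script keep simulations modest by
design: 50,000 iterations for the headline operating characteristics
(Monte-Carlo SE ≤ 0.002), 6,000–10,000 for secondary checks, 1,000 for
the null-significance study (matching its original description), 500
replicates for variance-component recovery, and 250 replicates on a
reduced 4×2×6 layout for the GxE size calibration.  Randomness is
counter-based (Philox) keyed by user seeds, so every result is
reproducible and independent of execution order.

## Known limitations

* No multiplicity adjustment across analytes; verdicts are per
  characteristic.
* Equivalence limits from a handful of reference varieties are noisy
  (df ≈ n_g − 1); the conditional simulation convention quantifies the
  tests given the limits, not the two-step procedure unconditionally.
* The KR implementation covers the variance-components structures used
  here (linear covariance), not general correlated random effects.
* Automatic outlier detection is deliberately out of scope.
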