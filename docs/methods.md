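# Methods

`photogam` analyzes larval zebrafish locomotion under programmable light
schedules: per-second distance traces from multiwell plates are reduced to
a rolling-sum response, modeled with penalized-spline additive models, and
summarized as per-second group contrasts and photo-period
proportion-of-significance statistics.  This note documents the model, the
synthetic-data generator, the numerical choices, and the limits of what
the simulation-based tests demonstrate.

## Response variable and analysis unit

The raw measurement is the distance (mm) each fish moved in each 1-s bin.
The response is the trailing 60-s rolling sum, in mm/min: at second *t*,
`rsums(t) = sum of distance over (t-59..t)`.  The window is *trailing*
(causal); the first 59 seconds of a recording have no complete window and
are excluded (under the default regimens they fall inside the acclimation
period, which never enters the model anyway).  The analysis unit is not
the individual fish but the across-fish mean of this rolling sum within
each (assay, group) cell: fish-level movement is severely zero-inflated
and right-skewed, and averaging over wells at each second yields a
response that an additive Gaussian model can describe.  Dark-light repeat
assays are analyzed at one point per second; long baseline recordings at
one point per 30 s.

## The additive model

For the repeat assays the model is

    rsums ~ geno + s(time, k, by=geno) + s(assay, bs="re")

an identity-link Gaussian additive model with

* **parametric factor terms** (genotype; for baseline assays illumination
  and developmental stage), treatment-coded against the conventional
  reference levels (WT, dark, 4 dpf);
* **one penalized smooth of time per factor level** ("by"-smooths), so
  each genotype gets its own trajectory;
* **a ridge-penalized assay-indicator block**, the exact penalized-
  regression equivalent of a Gaussian per-assay random intercept.

Smooths use a cubic B-spline basis on equally spaced knots with a
second-order difference penalty (P-splines).  This is a deliberately
low-rank member of the same penalized-smoother family as thin-plate
regression splines; the basis dimension `k` plays the identical role of
capping the smooth's effective degrees of freedom, and the penalty, not
`k`, determines the effective flexibility.  Each smooth is centered
(sum-to-zero over its observed rows) so the factor main effects remain
estimable.  Note that the second-order penalty leaves one unpenalized
linear direction per centered smooth, so a smooth's edf floor is 1, not
0 — the same property mgcv's default thin-plate smooths have.

Fitting minimizes `||y - Xb||^2 + sum_j lambda_j b' S_j b`.  Smoothing
parameters are chosen by restricted maximum likelihood (REML; GCV is
available), using the Gaussian identity

    -2 l_r(lambda) = (n - M)(log(2 pi s2) + 1) + log|X'X + S_lambda|
                     - log|S_lambda|_+,
    s2 = (RSS + penalty) / (n - M),

where `M` counts all unpenalized directions (parametric columns plus
penalty null spaces) and `|.|_+` is the product of the positive
eigenvalues.  The criterion is minimized over log-lambda by a
derivative-free simplex search (tolerance ~2% per lambda, one restart on
non-convergence; log-lambda clipped to ±25).  A relative floor of
`1e-10 * y'y` on `RSS + penalty` keeps the profile well defined when data
sit exactly in the basis span (float round-off would otherwise pull
lambda to zero).  The fitter was validated externally: handing the
identical design matrix and penalty blocks to an established REML GAM
implementation reproduces the smoothing parameters, effective degrees of
freedom, residual variance, coefficients and coefficient covariance to
4–6 significant digits (this cross-check runs in the test suite).

Per-term effective degrees of freedom are block traces of the influence
matrix; the coefficient covariance is `V = s2 (X'X + S_lambda)^(-1)`
(the Bayesian/posterior form); deviance explained is `1 - RSS/TSS`.

### Inference on terms

Parametric dummy coefficients get two-sided Wald t tests with residual
degrees of freedom `n - total edf`.  Each smooth (and the random-effect
block) gets a Wald quadratic form on its coefficients with the
pseudo-inverse of its covariance block, referred to F with numerator df
equal to the rounded edf.  This is a simpler statistic than the refined
smooth-term test used by mgcv's summary; it is documented here as an
approximation and is only used for term screening, not for the headline
contrasts.

### Adequacy checks

`check_basis_dimension` mirrors the usual "is k big enough" diagnostic:
the k-index is the mean squared difference of time-adjacent residuals
within each assay-by-group series over twice the residual variance
(values well below 1 mean neighboring residuals are far more similar than
white noise, i.e. unmodeled structure), with a permutation p-value
(residuals shuffled over time within each series, 500 shuffles).  A
smooth is flagged when its edf is within 0.5 of the basis ceiling or the
permutation p is below 0.05.  Exception: when the fit is essentially
exact (residual variance below `1e-8 * mean(y^2)`), neither arm fires —
machine-precision residuals cannot indicate an inadequate basis.

Model variants are compared by AIC with model dimension
`total edf + 1` on the Gaussian log-likelihood at the ML variance.

## Estimated marginal means and per-second contrasts

The EMM of a group level at time *t* is the model prediction at that
(time, level) with the random-effect columns zeroed and any other
parametric factors averaged with **equal weights** over their levels (the
standard least-squares-means convention; observed-frequency weighting is
the main alternative and would matter only for unbalanced baseline
designs).  At every analyzed second, all pairwise EMM differences are
tested: `t = diff / SE`, SE from the coefficient covariance, and the
Tukey adjustment `p = P(Q_{m,nu} >= sqrt(2)|t|)` with `m` groups and
`nu = n - total edf`.  With two groups the studentized range of two means
is exactly `sqrt(2)|t|`, so the adjusted p *is* the two-sided t-test p
and is computed directly from the t distribution.  For `m >= 3` the
studentized-range tail is computed by a vectorized double Gauss–Legendre
quadrature (160 nodes over the normal axis, 48 over the chi scale
mixture, ±12 sd window); it agrees with an independent numerical
integration to better than 1e-6 across the practical range.

**Known property, flagged rather than fixed:** the Tukey adjustment is
across the pairs *within* one second only.  Nothing corrects across the
thousands of seconds of a trajectory, and — more fundamentally — at
per-second sampling the rolling-sum response is autocorrelated by
construction (adjacent seconds share 59/60 of their window), which the
model's iid-residual assumption ignores.  Per-second standard errors are
therefore too small and per-second significance calls are anticonservative.
This is a property of the original per-second workflow that this package
reproduces; correcting it (e.g. FDR over time, or an AR residual model)
would change the method.  The pipeline's own adequacy diagnostic exposes
the violation: per-second fits produce k-index values near 0.  Treat the
per-second significance trajectory as descriptive; the period-level
proportions inherit the same property.  When a *calibrated* test is
needed (e.g. the null-calibration study below), sample one point per
60-s window, where disjoint windows make the points independent and the
genotype test's type-I error is at its nominal level.

## Proportion of significance and cross-regimen tests

For a fixed ordered pair (e.g. WT vs HM) and a declared direction
(WT larger), the proportion of significance over a set of photo periods
is the fraction of analyzed seconds (post-stride) in those periods where
the adjusted p is below alpha *and* the difference has the declared sign;
seconds significant in the opposite direction never count.  The default
dark-phase set is the 3rd–5th dark periods of the standard four-cycle
regimen (configurable, because early assays lacking the final dark period
only reach dark4).

Two proportions from different regimens are compared with the
two-proportions z test with Yates' continuity correction, reported as the
equivalent 1-df chi-squared

    chi2 = (max(|p1 - p2| - (1/n1 + 1/n2)/2, 0))^2
           / (pooled (1 - pooled) (1/n1 + 1/n2)),

identical to the Yates-corrected chi-squared of the 2x2 table of
significant vs non-significant seconds (cross-validated against the
contingency implementation to 1e-9).  When both proportions are 0 or both
1 the statistic is 0 with p = 1 and a warning — a plateau carries no
information about a difference.  No correction is applied across the many
regimen-pair comparisons, matching the original workflow.

## The synthetic-data generator

The generator stands in for the deposited assay recordings so that every
downstream stage is testable offline.  Per fish and second,

    movement = Bernoulli(1 - pi_state) * Gamma(shape, scale) * rate(t),

a zero-inflated Gamma whose rate profile carries the photoperiod
physiology:

| parameter | default | meaning |
|---|---|---|
| `zero_inflation_dark / _light` | 0.80 / 0.50 | probability of a zero-movement second |
| `burst_shape`, `burst_scale` | 0.8, 3.0 mm | Gamma burst per active second (mean 2.4 mm) |
| `base_rate_dark / _light` | 0.5 / 1.0 | state baseline multiplier (light > dark) |
| `onset_spike_amp`, `onset_spike_decay_s` | 1.5, 20 s | transient after any illumination switch |
| `rebound_amp` | 4.0 | ceiling of the post-light dark rebound (rate multiplier) |
| `rebound_halfsat_min` | WT/HT 1, HM 6 min | light duration reaching half the rebound ceiling |
| `rebound_decay_s` | 240 s | rebound relaxation through the dark period |
| `assay_sd` | 0.15 | sd of the per-assay log-normal multiplier |
| `activity_mult` | WT/HT 1.0, HM 0.75 | genotype basal activity (HM deficit) |

The dark rebound after a light-to-dark switch is Michaelis-type in the
preceding light duration *d*: `ceiling * s/(s+1)` with
`s = d / halfsat`, decaying exponentially through the dark period.
Genotype enters **only** through the basal multiplier and the rebound
half-saturation, so recovery tests have a well-defined target: wild-type
larvae mount the rebound after ~1 min of light, homozygous mutants need
~6 min, heterozygotes behave like wild type.  Defaults were chosen once
to encode the qualitative biology (light > dark baseline; rebound
exceeding light-phase activity; movement scales of tens of mm/min; a
basal mutant deficit detectable at the studied sample sizes) — effect
magnitudes in the source data are only available as model predictions, so
these are order-of-magnitude choices, not calibrated values.

Randomness: one global seed; each well's stream derives deterministically
from (seed, assay index, well index), and assay effects from a separate
substream, so output is byte-identical across runs and robust to
generation order.

**What the generator does not emulate:** millisecond-scale startle
kinematics, within-well position, slow circadian drift, fish-to-fish
personality (a fish's zero-inflation does not persist across seconds),
and — importantly — *group-level* noise beyond the shared assay
multiplier: in real data, different fish families in different wells make
group means vary between assays in group-specific ways.  Passing tests on
synthetic data therefore demonstrate the statistical machinery, not the
biological effect sizes of any real recording.

## Simulation-based checks and the problem sizes used

* **Null calibration**: 200 studies of 6 assays x 3 genotypes x 16 fish
  on a 600-s repeat regimen with a *stationary* null configuration (no
  transients, no rebound, equal base rates, no genotype effect), sampled
  at one point per 60-s window.  Genotype main-effect rejection at
  alpha = 0.05 stays inside the exact binomial 95% band, and the median
  directional dark-period proportion is ~0.  The stationary null isolates
  calibration: with photoperiod-locked dynamics a deliberately coarse
  basis would add shared lack-of-fit and make the test conservative
  instead.
* **Pattern recovery**: 25 seeds x four regimens (2-, 4-, 6-, 7.5-min
  light; two cycles, 4 assays x 8 fish, per-second workflow).  The HM
  main effect is detected in essentially all 2-min runs, and the
  WT-exceeds-HM dark proportion is monotone non-increasing in
  illumination duration.  At these effect sizes and per-second
  resolution the proportions saturate at 100% in all four regimens (a
  plateau of ties); the declining WT/HM dark-phase EMM ratio
  (~2.0 at 2 min falling toward ~1.75 at 7.5 min) carries the direction
  of the duration effect quantitatively.
* Study sizes above (2 cycles instead of 4, 4 assays, 8–16 fish,
  reduced acclimation) are the package's standard reduced-scale test
  conditions; the full-scale four-cycle regimens run identically through
  the same code paths.

## Degenerate inputs and tie-breaks

* Constant response: smooths shrink to their linear floor (edf -> 1 per
  smooth), deviance explained 0, fitted values equal the mean.
* Zero SE with zero difference in a contrast: p = 1; zero SE with a
  nonzero difference is an error.
* Empty (assay, group) cells simply produce no series; aggregation
  requires at least one fish per present cell.
* Half-open period intervals `[start, end)` with 0-based integer seconds:
  every second belongs to exactly one photo period; the regimen end
  itself is out of range.
* Period numbering: post-acclimation dark periods are dark1..darkN with
  the terminal dark as dark(N+1) (dark5 under the standard four-cycle
  regimen); acclimation never enters inference.

## Known limitations

* Per-second inference is anticonservative (see above); the package
  reproduces the workflow and flags it rather than silently correcting.
* The smooth-term F test is a coefficient-Wald approximation, not the
  refined test of the reference GAM implementation.
* Basis dimension `k = 1200` for a developmental-stage smooth over 1440
  thirty-second samples is expressible (the builder only requires k not
  to exceed the number of distinct time values) but leaves almost no
  residual degrees of freedom per level; the adequacy check will flag
  such fits.
* Smoothing-parameter search is derivative-free; with many penalized
  blocks (> ~8) it becomes the dominant cost and a gradient-based REML
  would be preferable.
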