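# Methods

## Model

The package assumes a two-stage generative model of evoked BOLD
responses in a neural-doubling (pure BOLD summation) experiment:

1. **Neural stage.** The aggregate neural response to a single-sided
   stimulus of Weber contrast *c* follows a Naka-Rushton function
   R(c) = r0 + r_max·c^n/(c^n + c50^n), with r_max > 0, c50 ∈ (0, 1],
   n > 0, r0 ≥ 0.  R is nondecreasing on [0, 1].  A double-sided
   stimulus drives two co-localized, independent populations and evokes
   exactly 2·R(c).  This doubling is an assumption of the design (valid
   when the two populations are truly co-localized and do not interact),
   not something the package tests.
2. **Hemodynamic stage.** BOLD amplitude is B = k·Z^γ (% signal change),
   k > 0, γ > 0.  k absorbs the arbitrary units of Z; γ is the quantity
   of interest.  γ = 1 is linear coupling; γ < 1 compressive.

Under this model b_double/b_single = 2^γ at every contrast — the
doubling identity that both estimators exploit.

## Stitching

Given n amplitude pairs, we estimate 1 = Z₁ ≤ … ≤ Z_n so that the 2n
points {(Z_i, B1_i)} ∪ {(2Z_i, B2_i)} lie on one smooth monotone curve:

* **Curve family.** Piecewise cubic Hermite with m control points (a
  value and a slope per knot: 2m free parameters), knots at the data
  extremes and equally spaced between.  m = 2 is a single general cubic;
  it is also the only admissible choice for n = 5, since the residual
  degrees of freedom are n + 1 − 2m (2n points minus n − 1 latent
  parameters minus 2m curve parameters) and must be positive.
* **Fit space.** Default log₁₀ x / log₁₀ y.  A power law is a straight
  line there, so exact power-law data are recovered exactly — the basis
  of the package's identifiability tests.  A log-x/linear-y option
  exists for data with near-zero amplitudes.  Residuals are unweighted
  by default (sum of squared errors); an SE-weighted option propagates
  measurement SEs into fit space by the delta method.
* **Monotonicity.** The curve derivative is constrained to be ≥ 0 at 101
  equally spaced points of the domain.  The unconstrained least-squares
  solution is used when it already satisfies the constraint (always the
  case near an exact power law); otherwise an SLSQP quadratic solve
  enforces it.  Exact cubic-monotonicity conditions would add complexity
  without practical benefit at this scale.
* **Outer search.** Latent levels are parameterized as cumulative
  positive increments of log Z (u_i unconstrained, log Z_i = Σ exp(u_j)),
  which enforces the ordering without constraints.  Nelder-Mead simplex
  minimizes the normalized chi-square, with multi-start: one informed
  start from the pooled doubling-ratio exponent, the rest seeded random
  perturbations of an equal-log-spacing start (default 8 restarts;
  simplex tolerances 1e-10, max 4000 iterations per start).
* **Degenerate input.** If all amplitudes are identical the latent
  levels are unidentifiable; the result is returned flagged
  (`identifiable=False`, flat curve, Z ≡ 1) rather than silently
  "solved".

## Exponent estimators and uncertainty

* **Stitch + log-log OLS** (`estimate_gamma`): γ is the OLS slope of
  log B on log Z over the stitched points; k = exp(intercept).  Exact on
  noiseless power-law data.
* **Doubling ratio** (`ratio_gamma`): γ_i = log₂(B2_i/B1_i), pooled by
  an unweighted mean (default) or an inverse-variance-weighted mean with
  variances propagated from the amplitude SEs.  The weighted pooling is
  the efficient estimator under the latent-level model and is what the
  package recommends for noisy data: with SEs at 5% of the maximum
  amplitude, the lowest-contrast pair alone carries ≈ 0.5 SD of
  log-ratio noise, which an unweighted mean lets dominate.
* **Confidence intervals**: parametric bootstrap (default 1000
  replicates) resampling each amplitude from Normal(mean, SE),
  percentile 2.5/97.5.  The bootstrap method is a package choice; any
  seed gives reproducible intervals.  Coverage on synthetic data under
  the stated noise model is ≈ 94–96%.
* **Combination across regions** (`combine_gamma`): inverse-variance
  weighting, se = (Σ 1/var)^(−1/2); an unweighted mean with a warning
  when variances are missing.

## Linearity diagnostics

`linearity_diagnostics` reports: OLS of b_double on b_single with a
nested-model F-test of the intercept (under the power law the two are
exactly proportional with slope 2^γ, so a nonzero intercept indicates
model violation); a constancy test of the doubling ratios across
contrast (one-way ANOVA on per-run ratios when available, otherwise a
trend test on log contrast); paired t-tests of the measured double-sided
amplitudes against the linear-BOLD-summation prediction (sum of the two
single-sided amplitudes) and the contrast-summation prediction
(single-sided amplitude interpolated linearly in log contrast at twice
the contrast, clipped at contrast 1.0); and a straight-line fit of B on
the stitched neural levels, whose intercept is positive exactly when
B(Z) is concave (γ < 1) — the "paradoxical nonzero BOLD at zero neural
response" signature of compressive coupling.  Note the b_double-on-
b_single intercept is *not* sensitive to γ: proportionality holds for
any γ, so compression must be read from the B-vs-Z fit.

## Deconvolution

Time series are %-transformed per scan ((y − ȳ)/ȳ·100), then deconvolved
in a single least-squares solve against a finite-impulse-response design:
one delta-indicator column per condition and lag (default window 20 s,
covering the 16-s blanks plus spillover), scan intercepts always
included, optional per-scan cosine drift basis up to 0.0118 Hz, and
arbitrary nuisance regressors (e.g. the top principal components of a
stimulus-silent noise pool, the package's simplified stand-in for global
physiological denoising — noise-pool membership and component count are
explicit arguments, not selected automatically).  Per-lag SEs come from
the residual variance and design covariance (GLM-based, not across-trial).
Amplitudes: 6-s blocks → mean response at lags 7, 8, 9 s (1-s sampling);
1-s blocks → response at lag 5 s.

## Synthetic data

The generator emulates the summation experiment: five Weber contrasts in
equal log steps from 0.05 to 1.0; 19 stimulus blocks per scan (6-s or
1-s blocks, 16-s blanks, 1-s sampling, one scan per contrast); stimulus
types A, B, A+B in a first-order counterbalanced order (each type
preceded by every type equally often; feasible when n_blocks − 1 is
divisible by 9, built as a randomized Eulerian circuit and verified);
a canonical double-gamma HRF (peak 6 s, undershoot 16 s, 6:1 ratio —
a conventional choice, as is the whole HRF shape); the unit block
response truncated to the deconvolution window and normalized so a
unit-amplitude event extracts to exactly 1, which makes
simulate→deconvolve→extract an exact round trip and parameter recovery
well-posed.

Noise: amplitude tables receive Gaussian noise of SD amp_noise_sd/√n_runs
per entry (amp_noise_sd is the per-run SD) and carry that same value as
their SE, so reported SEs are correct by construction; time series
receive AR(1) innovations (SD 0.3%, coefficient 0.3), a slow cosine
drift (amplitude 0.5%), and shared components mixed across the ROI and a
pool of stimulus-silent units (3 components, loading SD 0.3, 20 pool
units).  These defaults are plausible ROI-level values for block-design
visual fMRI; they are conventions of the simulator, not measurements.

What the simulator does **not** emulate — and what passing tests
therefore cannot certify about real data: violations of co-localization
(which bias γ toward 1, as the design's key vulnerability), gaze
instability, voxel-level retinotopic structure, HRF variability across
regions or durations, non-Gaussian physiological noise, and motion.

## Meta-analysis

`fit_naka_rushton` fits (r_max, c50, n, r0) by bounded nonlinear least
squares (optionally SE-weighted), multi-started from a coarse
(c50, n) grid; flat responses are flagged degenerate rather than fitted.
`match_gamma` minimizes Σ w_i (bold_i − k·R(c_i)^γ)² with w = 1/SE²
(unit weights with a warning when SEs are absent): for each γ, k has a
closed-form weighted-regression solution, so the problem reduces to a
1-D search over γ ∈ [0.05, 2] (79-point grid, then bounded refinement to
1e-10).  The fit is in linear BOLD space because published BOLD values
can be near zero or negative at low contrast.  No baseline offset by
default; `allow_offset=True` adds one.  Digitized tables from the
literature are not shipped; `synthetic_meta_datasets` generates
table-shaped synthetic studies with planted exponents for testing.

## Problem sizes and numerical conventions

The test suite and the acceptance script run everything at the scale of
the design itself (5 contrasts, 19 blocks/scan): noiseless checks are
single fits; the noisy-recovery study uses 200 replicates with the
weighted ratio estimator; bootstrap-coverage uses 500 simulations × 200
bootstrap replicates; stitching inside simulations uses 3–4 restarts.
These sizes make every run complete in seconds to a few minutes on one
core while keeping Monte-Carlo error well inside the asserted margins.
Ties and near-flat inputs: ordering is enforced strictly (increments
bounded below at exp(u) > 0), flat data are flagged, and zero-SE
bootstrap inputs return width-0 intervals with a warning.

## Known limitations

* γ and k are only identified up to the arbitrary unit of Z; all
  reported k values are relative to Z₁ = 1.
* The stitching objective is non-convex in the latent levels; multi-start
  Nelder-Mead has always found the global optimum in our property tests,
  but pathological datasets could require more restarts.
* The bootstrap treats reported SEs as exact Gaussian scales; heavy-tailed
  amplitude noise would make the CIs anti-conservative.
* The simplified shared-noise removal requires the caller to supply the
  noise pool and component count; it does not reproduce published
  cross-validated denoising pipelines.
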