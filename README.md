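# boldstitch

Tools for inferring the quantitative relationship between the fMRI BOLD
signal and the aggregate neural response it reflects, from "neural
doubling" (pure BOLD summation) experiments.

## The problem

BOLD amplitude *B* is an indirect, hemodynamic proxy for the local
aggregate neural response *Z*.  Most fMRI analyses assume the mapping
*B(Z)* is linear, but testing that assumption is hard because changing a
stimulus normally changes *Z* through unknown neuronal nonlinearities.
A neural-doubling design sidesteps this: when two co-localized but
*independent* neuronal populations share the same voxels (as in achiasmic
visual cortex, where each voxel carries two mirrored population receptive
fields), stimulating one population (single-sided stimulus A or B) evokes
some response *Z*, and stimulating both together (double-sided stimulus
A+B) evokes exactly 2*Z* — with no stimulus-level summation confound.
Each stimulus contrast *c_i* then yields a pair of BOLD amplitudes
(*B1_i* at *Z_i*, *B2_i* at 2*Z_i*) whose neural levels are known up to
scale, even though the *Z_i* themselves are not.

## The method

**Stitching.** Set *Z_1* = 1 (units of *Z* are arbitrary) and estimate
the ordered latent levels 1 ≤ *Z_2* ≤ … ≤ *Z_n* such that the 2*n* points
{(*Z_i*, *B1_i*)} ∪ {(2*Z_i*, *B2_i*)} are maximally consistent, in the
least-squares sense, with a single smooth monotone curve — a monotone
cubic with *m* control points (2*m* free parameters), fitted in log-log
coordinates.  The objective is the normalized chi-square: residual sum of
squares divided by the residual degrees of freedom *n* + 1 − 2*m*.  For
the standard *n* = 5 contrast design only *m* = 2 (a single monotone
cubic) leaves any residual degrees of freedom.  The outer search over
latent levels uses a derivative-free simplex with seeded multi-start; the
inner monotone fit is a shape-constrained linear least-squares solve.

**The power law.** The stitched curve is well described by
*B* = *k Z*^γ.  γ is estimated by OLS of log *B* on log *Z* over the
stitched points, or in closed form from the doubling identity
*B2_i*/*B1_i* = 2^γ, i.e. γ_i = log₂(*B2_i*/*B1_i*), pooled across
contrasts (optionally SE-weighted).  Uncertainty comes from a parametric
bootstrap that resamples each amplitude from Normal(mean, SE).

**Meta-analysis.** Given a neuronal contrast response function
(Naka-Rushton: *R*(*c*) = *r0* + *r_max·c^n*/(*c^n* + *c50^n*)) and a
published BOLD contrast-response dataset, `match_gamma` finds the (k, γ)
minimizing the error-weighted squared difference between *k R*(*c*)^γ
and the BOLD data, and `batch_match` summarizes γ across datasets.

The package also contains the machinery around these estimators: a
synthetic-experiment generator (block designs with first-order
counterbalanced stimulus sequences, canonical double-gamma HRF, AR(1) +
drift + shared-component noise), per-scan % transform, FIR deconvolution
to peristimulus time courses, amplitude extraction (mean of the 7–9 s
lags for 6-s blocks; the 5 s lag for 1-s blocks), shared-noise principal
components, and linearity diagnostics.

## Worked example

```python
import boldstitch as bs

crf = bs.NeuralCRF(r_max=1.0, c50=0.25, exponent_n=2.0)   # neural CRF
law = bs.BvZLaw(k_scale=2.0, gamma=0.5)                   # true B = 2 Z^0.5
design = bs.ExperimentDesign(amp_noise_sd=0.15, n_runs=5, seed=1)

ds = bs.generate_amplitudes(design, crf, law)
res = bs.stitch(ds, bs.StitchConfig(seed=1))
fit = bs.fit_powerlaw(res.stitched_points)
boot = bs.bootstrap_gamma_ci(ds, estimator="ratio", n_boot=1000,
                             seed=1, weighted=True)
```

prints (via the obvious `print` calls):

```
contrasts: [0.05   0.1057 0.2236 0.4729 1.    ]
b_single : [0.419 0.789 1.364 1.737 1.981]
b_double : [0.557 1.138 1.836 2.49  2.712]
z_rel    : [ 1.     4.319 12.16  21.346 26.958]
nchisq   : 0.0001728
gamma=0.477 k=0.406 R2=0.9990
ratio gamma=0.475 95% CI (0.415, 0.536)
```

The five single/double amplitude pairs were generated from a compressive
square-root law with measurement noise; stitching recovers latent neural
levels spanning a ~27-fold range, the stitched points fall on a nearly
perfect log-log line (R² = 0.999), and both estimators return γ ≈ 0.48
with a bootstrap CI that covers the true value 0.5.  The doubling ratio
*B2*/*B1* ≈ √2 at every contrast is the model's signature: doubling the
neural response multiplies BOLD by 2^γ, not 2.

The same chain is available from the shell:

```sh
boldstitch pipeline --seed 1 --out runs/demo
```

which simulates amplitudes and raw time series, deconvolves, stitches and
writes `gamma_report.json` (all outputs embed the seed and a config hash).

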