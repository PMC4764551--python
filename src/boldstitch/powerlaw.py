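"""Power-law exponent estimation and linearity diagnostics.

Two routes to the exponent gamma of B = k Z^gamma:

* ``fit_powerlaw`` — ordinary least squares of log B on log Z applied to
  the stitched (Z, B) points (``estimate_gamma`` wires the two together);
* ``ratio_gamma`` — the closed-form estimator gamma_i = log2(B2_i / B1_i)
  from the doubling identity B2/B1 = 2^gamma, pooled over contrasts.

Uncertainty comes from a parametric bootstrap that resamples each
amplitude from Normal(mean, SE).  ``linearity_diagnostics`` runs the
companion checks: a linear regression of double- on single-sided
amplitudes with a nested-model intercept test, a constancy test of the
per-contrast doubling ratios, and paired comparisons of the measured
double-sided response against the linear-BOLD-summation and
contrast-summation predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stitching import StitchConfig, stitch

__all__ = [
    "PowerLawFit",
    "LinearityReport",
    "fit_powerlaw",
    "ratio_gamma",
    "estimate_gamma",
    "bootstrap_gamma_ci",
    "combine_gamma",
    "summation_predictions",
    "paired_comparison",
    "linearity_diagnostics",
]


@dataclass
class PowerLawFit:
    """Estimated power law B = k_scale * Z**gamma."""

    gamma: float
    k_scale: float
    r_squared: float
    method: str = "stitch+loglog-fit"
    ci95: tuple | None = None
    n_boot: int = 0
    seed: int | None = None


def fit_powerlaw(points, method: str = "loglog-ols") -> PowerLawFit:
    """OLS of log B on log Z: gamma is the slope, k the exp(intercept).

    ``points`` is an (N, 2) array of strictly positive (Z, B) pairs;
    R^2 is reported in log-log space.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need an (N>=2, 2) array of (Z, B) points")
    if np.any(pts <= 0):
        raise ValueError("power-law fit requires strictly positive Z and B")
    lx, ly = np.log(pts[:, 0]), np.log(pts[:, 1])
    if np.ptp(lx) == 0:
        raise ValueError("all Z identical: slope undefined")
    res = stats.linregress(lx, ly)
    return PowerLawFit(
        gamma=float(res.slope),
        k_scale=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2) if np.ptp(ly) > 0 else 1.0,
        method=method,
    )


def estimate_gamma(dataset, config: StitchConfig | None = None) -> PowerLawFit:
    """Stitch the dataset, then fit the power law to the stitched points."""
    result = stitch(dataset, config)
    fit = fit_powerlaw(result.stitched_points, method="stitch+loglog-fit")
    return fit


def ratio_gamma(dataset, weighted: bool = False):
    """Per-contrast and pooled exponent from the doubling ratio.

    gamma_i = log2(b_double_i / b_single_i); the pooled value is the
    unweighted mean over usable contrasts (``weighted=True`` weights by
    inverse variance propagated from the amplitude SEs).  Pairs with a
    nonpositive amplitude are excluded with a warning; if every pair is
    excluded this is an error.
    """
    b1 = np.asarray(dataset.b_single, dtype=float)
    b2 = np.asarray(dataset.b_double, dtype=float)
    gamma_i = np.full(len(b1), np.nan)
    usable = (b1 > 0) & (b2 > 0)
    if not np.all(usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} contrast(s) with nonpositive "
            "amplitude from the ratio estimator", stacklevel=2)
    if not np.any(usable):
        raise ValueError("no contrast has positive single and double amplitudes")
    gamma_i[usable] = np.log2(b2[usable] / b1[usable])
    if weighted:
        se1 = np.asarray(dataset.se_single, dtype=float)
        se2 = np.asarray(dataset.se_double, dtype=float)
        var = ((se1 / b1) ** 2 + (se2 / b2) ** 2) / np.log(2.0) ** 2
        w = np.where(usable & (var > 0), 1.0 / np.where(var > 0, var, 1.0), 0.0)
        if w.sum() == 0:
            pooled = float(np.nanmean(gamma_i))
        else:
            pooled = float(np.nansum(w * gamma_i) / w.sum())
    else:
        pooled = float(np.nanmean(gamma_i))
    return gamma_i, pooled


def _resample(dataset, rng: np.random.Generator):
    from copy import copy

    ds = copy(dataset)
    ds.b_single = dataset.b_single + rng.normal(size=len(dataset.b_single)) * dataset.se_single
    ds.b_double = dataset.b_double + rng.normal(size=len(dataset.b_double)) * dataset.se_double
    return ds


def bootstrap_gamma_ci(
    dataset,
    estimator: str = "ratio",
    n_boot: int = 1000,
    seed: int = 0,
    config: StitchConfig | None = None,
    weighted: bool = False,
) -> PowerLawFit:
    """Parametric-bootstrap 95% CI for gamma.

    Each replicate resamples every amplitude from Normal(mean, SE) and
    re-estimates gamma with the chosen estimator (``"ratio"`` or
    ``"stitch"``; ``weighted`` selects SE-weighted pooling of the ratio
    estimator); the CI is the percentile 2.5/97.5 interval.  Zero SEs
    everywhere yield a degenerate width-0 interval with a warning.
    Deterministic under a fixed seed.  The bootstrap distribution is
    attached as ``fit.boot_gammas``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if estimator not in ("ratio", "stitch"):
        raise ValueError("estimator must be 'ratio' or 'stitch'")
    se_all = np.concatenate([dataset.se_single, dataset.se_double])
    rng = np.random.default_rng(seed)

    def point(ds):
        if estimator == "ratio":
            return ratio_gamma(ds, weighted=weighted)[1]
        return estimate_gamma(ds, config).gamma

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gamma_hat = point(dataset)
        if np.all(se_all == 0):
            warnings.simplefilter("default")
            warnings.warn("all SEs are zero: returning a width-0 CI",
                          stacklevel=2)
            boot = np.full(n_boot, gamma_hat)
        else:
            boot = np.empty(n_boot)
            for i in range(n_boot):
                try:
                    boot[i] = point(_resample(dataset, rng))
                except ValueError:
                    boot[i] = np.nan
            boot = boot[np.isfinite(boot)]
            if len(boot) == 0:
                raise RuntimeError("every bootstrap replicate failed")
    lo, hi = np.percentile(boot, [2.5, 97.5])
    fit = PowerLawFit(gamma=float(gamma_hat), k_scale=np.nan, r_squared=np.nan,
                      method=estimator, ci95=(float(lo), float(hi)),
                      n_boot=n_boot, seed=seed)
    fit.boot_gammas = boot
    return fit


def combine_gamma(estimates) -> tuple[float, float | None]:
    """Inverse-variance-weighted combination of (gamma, se) estimates.

    Entries may be (gamma, se) or (gamma, (lo, hi)) — a 95% CI is converted
    to an SE via its half-width / 1.96.  Missing uncertainties trigger an
    unweighted mean with a warning (se None).
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    gammas, ses = [], []
    for g, unc in estimates:
        gammas.append(float(g))
        if unc is None:
            ses.append(None)
        elif np.iterable(unc):
            lo, hi = unc
            ses.append((hi - lo) / 2.0 / 1.96)
        else:
            ses.append(float(unc))
    gammas = np.asarray(gammas)
    if any(s is None or s <= 0 for s in ses):
        if len(gammas) > 1:
            warnings.warn("missing variances: falling back to an unweighted "
                          "mean", stacklevel=2)
        return float(np.mean(gammas)), None
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    return float(np.sum(w * gammas) / w.sum()), float(1.0 / np.sqrt(w.sum()))


def summation_predictions(dataset):
    """Per-contrast linear-BOLD-summation and contrast-summation predictions.

    linear-sum: the sum of the two single-sided amplitudes (2 * b_single
    when sides are absent) — what the double-sided response would be if
    BOLD summed linearly.  contrast-sum: the single-sided amplitude read
    out at twice the contrast (linear interpolation in log contrast,
    clipped at contrast 1.0) — what it would be if the double-sided
    stimulus merely acted like a doubled-contrast single-sided one.
    Returns (linear_sum, contrast_sum, extrapolated_mask).
    """
    c = np.asarray(dataset.contrasts, dtype=float)
    b1 = np.asarray(dataset.b_single, dtype=float)
    if dataset.b_single_A is not None and dataset.b_single_B is not None:
        linear_sum = dataset.b_single_A + dataset.b_single_B
    else:
        linear_sum = 2.0 * b1
    target = np.minimum(2.0 * c, 1.0)
    extrapolated = target > c.max()
    target_c = np.minimum(target, c.max())
    contrast_sum = np.interp(np.log(target_c), np.log(c), b1)
    return linear_sum, contrast_sum, extrapolated


def paired_comparison(measured, predicted):
    """Paired t-test of measured vs predicted values.

    Returns (t, dof, p).  Zero variance of the differences yields t = 0,
    p = 1 when the mean difference is zero and a signed infinite t with
    p = 0 otherwise.
    """
    a = np.asarray(measured, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("measured and predicted must be equal-length, n >= 2")
    d = a - b
    dof = len(d) - 1
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, dof, 1.0
        return float(np.sign(d[0]) * np.inf), dof, 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), dof, float(res.pvalue)


@dataclass
class LinearityReport:
    """Diagnostics of the power-law (vs linear) summation structure."""

    slope: float
    intercept: float
    intercept_F: float
    intercept_p: float
    r_squared: float
    ratios: np.ndarray
    ratio_stat: float
    ratio_p: float
    ratio_test: str
    vs_linear_sum: tuple = field(default=(np.nan, 0, np.nan))
    vs_contrast_sum: tuple = field(default=(np.nan, 0, np.nan))
    bvz_slope: float = np.nan
    bvz_intercept: float = np.nan
    degenerate: bool = False


def linearity_diagnostics(dataset, per_run_table=None) -> LinearityReport:
    """Run the linearity checks on an amplitude dataset.

    OLS of b_double on b_single with a nested-model F-test of the
    intercept.  Under the power law the two are exactly proportional
    (slope 2^gamma), so this intercept should not differ from zero; the
    compressive nonlinearity itself shows up in the B-vs-Z fit below.
    The doubling ratios b_double/b_single are
    tested for a contrast effect: a one-way ANOVA across contrast levels
    when per-run ratios are supplied (``per_run_table`` columns
    ``contrast`` and ``ratio``), otherwise a nested-model trend test of
    the per-contrast ratios on log contrast.  Paired comparisons against
    both summation predictions are embedded.

    When the dataset supports stitching (n >= 4, positive amplitudes), a
    straight line is also fitted to BOLD amplitude vs the stitched neural
    level (``bvz_slope``, ``bvz_intercept``): a concave BOLD-vs-neural
    curve (gamma < 1) forces a positive intercept — a paradoxical nonzero
    BOLD response at zero neural response — whereas gamma = 1 fits
    through the origin.
    """
    import statsmodels.api as sm

    b1 = np.asarray(dataset.b_single, dtype=float)
    b2 = np.asarray(dataset.b_double, dtype=float)
    n = len(b1)
    if n < 3:
        raise ValueError("need at least 3 contrast levels")

    X = sm.add_constant(b1)
    full = sm.OLS(b2, X).fit()
    origin = sm.OLS(b2, b1).fit()
    rss_full = float(full.ssr)
    rss_origin = float(origin.ssr)
    degenerate = rss_full <= 1e-20 * max(float(b2 @ b2), 1.0)
    if degenerate:
        intercept_F, intercept_p = np.nan, np.nan
    else:
        intercept_F = (rss_origin - rss_full) / (rss_full / (n - 2))
        intercept_p = float(stats.f.sf(intercept_F, 1, n - 2))

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(b1 != 0, b2 / b1, np.nan)

    if per_run_table is not None:
        groups = [g["ratio"].to_numpy()
                  for _, g in per_run_table.groupby("contrast")]
        if all(np.ptp(g) == 0 for g in groups):
            ratio_stat, ratio_p, ratio_test = np.nan, np.nan, "degenerate"
        else:
            res = stats.f_oneway(*groups)
            ratio_stat, ratio_p = float(res.statistic), float(res.pvalue)
            ratio_test = "one-way ANOVA (per-run ratios)"
    else:
        ok = np.isfinite(ratios)
        if np.ptp(ratios[ok]) <= 1e-12 * max(np.abs(ratios[ok]).max(), 1.0):
            ratio_stat, ratio_p, ratio_test = np.nan, np.nan, "degenerate"
        else:
            lc = np.log(np.asarray(dataset.contrasts, dtype=float)[ok])
            Xr = sm.add_constant(lc)
            trend = sm.OLS(ratios[ok], Xr).fit()
            const = sm.OLS(ratios[ok], np.ones_like(lc)).fit()
            df_denom = ok.sum() - 2
            ratio_stat = (float(const.ssr) - float(trend.ssr)) / (
                float(trend.ssr) / df_denom)
            ratio_p = float(stats.f.sf(ratio_stat, 1, df_denom))
            ratio_test = "trend test (per-contrast ratios on log contrast)"

    linear_sum, contrast_sum, _ = summation_predictions(dataset)
    vs_lin = paired_comparison(b2, linear_sum)
    vs_con = paired_comparison(b2, contrast_sum)

    bvz_slope, bvz_intercept = np.nan, np.nan
    if n >= 4 and np.all(b1 > 0) and np.all(b2 > 0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                st = stitch(dataset, StitchConfig(n_restarts=3))
            if st.identifiable:
                Xz = sm.add_constant(st.stitched_points[:, 0])
                line = sm.OLS(st.stitched_points[:, 1], Xz).fit()
                bvz_intercept = float(line.params[0])
                bvz_slope = float(line.params[1])
        except (ValueError, RuntimeError):
            pass

    return LinearityReport(
        slope=float(full.params[1]),
        intercept=float(full.params[0]),
        intercept_F=intercept_F,
        intercept_p=intercept_p,
        r_squared=float(full.rsquared) if not degenerate else 1.0,
        ratios=ratios,
        ratio_stat=ratio_stat,
        ratio_p=ratio_p,
        ratio_test=ratio_test,
        vs_linear_sum=vs_lin,
        vs_contrast_sum=vs_con,
        bvz_slope=bvz_slope,
        bvz_intercept=bvz_intercept,
        degenerate=degenerate,
    )
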