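"""Exponent estimators, bootstrap CIs, combination, and linearity
diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from boldstitch import (BvZLaw, ExperimentDesign, NeuralCRF, StitchConfig,
                        SummationDataset, bootstrap_gamma_ci, combine_gamma,
                        estimate_gamma, fit_powerlaw, generate_amplitudes,
                        linearity_diagnostics, paired_comparison, ratio_gamma,
                        summation_predictions)
from boldstitch.synthetic import noiseless


def make_dataset(b_single, b_double, se=0.0, contrasts=None):
    n = len(b_single)
    c = np.geomspace(0.05, 1.0, n) if contrasts is None else np.asarray(contrasts)
    return SummationDataset(
        roi_label="toy", duration_s=6.0, contrasts=c,
        b_single=np.asarray(b_single, float), se_single=np.full(n, se),
        b_double=np.asarray(b_double, float), se_double=np.full(n, se),
        n_runs=np.full(n, 5.0))


class TestFitPowerlaw:
    def test_exact_line(self):
        z = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_powerlaw(np.column_stack([z, 3.0 * z**0.5]))
        assert fit.gamma == pytest.approx(0.5, abs=1e-12)
        assert fit.k_scale == pytest.approx(3.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_point_slope(self):
        fit = fit_powerlaw([(1.0, 1.0), (2.0, np.sqrt(2.0))])
        assert fit.gamma == pytest.approx(0.5, abs=1e-12)

    def test_linear_case(self):
        fit = fit_powerlaw([(1.0, 2.0), (2.0, 4.0), (4.0, 8.0)])
        assert fit.gamma == pytest.approx(1.0, abs=1e-12)
        assert fit.k_scale == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_powerlaw([(1.0, 1.0), (2.0, -1.0)])


class TestRatioGamma:
    def test_constant_ratios(self):
        for ratio, gamma in ((2.0, 1.0), (np.sqrt(2.0), 0.5)):
            b1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
            _, pooled = ratio_gamma(make_dataset(b1, ratio * b1))
            assert pooled == pytest.approx(gamma, abs=1e-12)

    def test_nonpositive_pair_excluded(self):
        b1 = np.array([-0.1, 2.0, 3.0, 4.0, 5.0])
        ds = make_dataset(b1, 2.0 * np.abs(b1))
        with pytest.warns(UserWarning, match="excluding"):
            gamma_i, pooled = ratio_gamma(ds)
        assert np.isnan(gamma_i[0])
        assert pooled == pytest.approx(1.0, abs=1e-12)

    def test_all_excluded_errors(self):
        ds = make_dataset([-1.0, -1.0, -1.0, -1.0], [1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ratio_gamma(ds)

    @pytest.mark.parametrize("gamma", [0.3, 0.5, 0.7, 1.0])
    def test_agrees_with_stitch_on_exact_data(self, design, crf, gamma):
        ds = generate_amplitudes(noiseless(design), crf,
                                 BvZLaw(k_scale=2.0, gamma=gamma))
        _, pooled = ratio_gamma(ds)
        fit = estimate_gamma(ds, StitchConfig(n_restarts=3))
        assert abs(fit.gamma - pooled) < 0.02


class TestBootstrap:
    def test_zero_se_degenerate(self, clean_dataset):
        with pytest.warns(UserWarning, match="zero"):
            fit = bootstrap_gamma_ci(clean_dataset, n_boot=100, seed=0)
        lo, hi = fit.ci95
        assert hi - lo == 0.0

    def test_seed_determinism(self, design, crf, sqrt_law):
        ds = generate_amplitudes(
            ExperimentDesign(amp_noise_sd=0.2, n_runs=1, seed=2), crf,
            sqrt_law)
        a = bootstrap_gamma_ci(ds, n_boot=200, seed=5)
        b = bootstrap_gamma_ci(ds, n_boot=200, seed=5)
        assert a.ci95 == b.ci95
        c = bootstrap_gamma_ci(ds, n_boot=200, seed=6)
        assert a.ci95 != c.ci95

    def test_ci_brackets_point_estimate(self, design, crf, sqrt_law):
        ds = generate_amplitudes(
            ExperimentDesign(amp_noise_sd=0.2, n_runs=1, seed=3), crf,
            sqrt_law)
        fit = bootstrap_gamma_ci(ds, n_boot=500, seed=1, weighted=True)
        lo, hi = fit.ci95
        assert lo < fit.gamma < hi


class TestCombineGamma:
    def test_equal_precision_mean(self):
        g, se = combine_gamma([(0.54, 0.05), (0.55, 0.05)])
        assert g == pytest.approx(0.545)
        assert se == pytest.approx(0.05 / np.sqrt(2))

    def test_single_estimate(self):
        g, se = combine_gamma([(0.5, 0.1)])
        assert (g, se) == (0.5, pytest.approx(0.1))

    def test_precise_estimate_dominates(self):
        g, _ = combine_gamma([(0.4, 1e-6), (0.9, 1.0)])
        assert g == pytest.approx(0.4, abs=1e-6)

    def test_missing_variance_falls_back_to_mean(self):
        with pytest.warns(UserWarning, match="unweighted"):
            g, se = combine_gamma([(0.4, None), (0.6, 0.1)])
        assert g == pytest.approx(0.5)
        assert se is None

    def test_ci_converted_to_se(self):
        g, se = combine_gamma([(0.5, (0.4, 0.6))])
        assert se == pytest.approx(0.1 / 1.96)


class TestSummationPredictions:
    def test_flat_crf(self):
        ds = make_dataset([2.0] * 5, [3.0] * 5)
        lin, con, _ = summation_predictions(ds)
        np.testing.assert_allclose(lin, 4.0)
        np.testing.assert_allclose(con, 2.0)

    def test_grid_hit_at_half_contrast(self):
        c = np.array([0.125, 0.25, 0.5, 1.0])
        b1 = np.array([1.0, 2.0, 3.0, 4.0])
        ds = make_dataset(b1, 1.5 * b1, contrasts=c)
        _, con, extr = summation_predictions(ds)
        assert con[2] == pytest.approx(4.0)  # single at 2*0.5 = 1.0
        assert con[3] == pytest.approx(4.0)  # clipped at contrast 1.0
        assert not extr[2] and not extr[3]

    def test_compressive_law_below_linear_sum(self, clean_dataset):
        lin, _, _ = summation_predictions(clean_dataset)
        assert np.all(clean_dataset.b_double < lin)


class TestPairedComparison:
    def test_identical(self):
        t, dof, p = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_balanced_differences(self):
        t, _, _ = paired_comparison([1.0, 0.0], [0.0, 1.0])
        assert t == pytest.approx(0.0)

    def test_textbook_value(self):
        # differences {1, 2, 3}: t = mean/(sd/sqrt(3)) = 2*sqrt(3)
        t, dof, p = paired_comparison([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert dof == 2

    def test_constant_nonzero_difference_is_infinite_t(self):
        t, _, p = paired_comparison([2.0, 3.0], [1.0, 2.0])
        assert np.isinf(t) and t > 0 and p == 0.0


class TestLinearityDiagnostics:
    def test_linear_law_slope_two_through_origin(self, design, crf):
        ds = generate_amplitudes(noiseless(design), crf,
                                 BvZLaw(k_scale=2.0, gamma=1.0))
        rep = linearity_diagnostics(ds)
        assert rep.slope == pytest.approx(2.0, abs=1e-9)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.degenerate  # exact fit: residual variance 0
        assert rep.bvz_intercept == pytest.approx(0.0, abs=1e-6)

    def test_compressive_law_positive_bvz_intercept(self, clean_dataset):
        """gamma < 1 makes B(Z) concave: the straight-line fit of B on the
        stitched neural levels has a positive intercept, while double- and
        single-sided amplitudes stay exactly proportional (slope 2^gamma,
        zero intercept)."""
        rep = linearity_diagnostics(clean_dataset)
        assert rep.slope == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.bvz_intercept > 0.01
        np.testing.assert_allclose(rep.ratios, np.sqrt(2.0), rtol=1e-9)
        assert rep.ratio_test == "degenerate"  # constant ratios, zero noise

    def test_per_run_anova_finds_no_contrast_effect_under_power_law(self):
        rng = np.random.default_rng(1)
        rows = []
        for c in np.geomspace(0.05, 1.0, 5):
            for _ in range(8):
                rows.append({"contrast": c,
                             "ratio": np.sqrt(2) + rng.normal(0, 0.05)})
        ds = make_dataset(np.array([1, 2, 3, 4, 5.0]),
                          np.sqrt(2) * np.array([1, 2, 3, 4, 5.0]))
        rep = linearity_diagnostics(ds, per_run_table=pd.DataFrame(rows))
        assert rep.ratio_test.startswith("one-way ANOVA")
        assert rep.ratio_p > 0.05


def test_noisy_recovery_median_error(crf, sqrt_law):
    """SE at 5% of the maximum amplitude: the SE-weighted doubling-ratio
    estimator recovers gamma = 0.5 with median absolute error <= 0.05
    over 200 replicates."""
    from boldstitch import naka_rushton_response

    max_amp = sqrt_law.bold(2 * naka_rushton_response(1.0, crf))
    errs = []
    for rep in range(200):
        d = ExperimentDesign(amp_noise_sd=0.05 * max_amp, n_runs=1,
                             seed=40_000 + rep)
        ds = generate_amplitudes(d, crf, sqrt_law)
        _, pooled = ratio_gamma(ds, weighted=True)
        errs.append(abs(pooled - 0.5))
    assert np.median(errs) <= 0.05
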