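"""Percent transform, FIR deconvolution, shared-noise components and
amplitude extraction."""

import numpy as np
import pytest

from boldstitch import (EventSchedule, PeristimulusTimecourse,
                        TimeSeriesDataset, extract_amplitude, fir_deconvolve,
                        percent_transform, shared_noise_components)
from boldstitch.deconvolution import cosine_drift_regressors


def make_ts(signal, tr=1.0, boundaries=(0,)):
    return TimeSeriesDataset(tr_s=tr, signal=np.atleast_2d(signal),
                             scan_boundaries=np.array(boundaries))


class TestPercentTransform:
    def test_constant_series_maps_to_zero(self):
        out = percent_transform(make_ts(np.full(10, 42.0)))
        np.testing.assert_array_equal(out.signal, 0.0)

    def test_two_sample_scan(self):
        out = percent_transform(make_ts([99.0, 101.0]))
        np.testing.assert_allclose(out.signal[0], [-1.0, 1.0])

    def test_scale_invariance_and_zero_mean_per_scan(self):
        rng = np.random.default_rng(0)
        y = 100 + rng.normal(size=40)
        a = percent_transform(make_ts(y, boundaries=(0, 20)))
        b = percent_transform(make_ts(5 * y, boundaries=(0, 20)))
        np.testing.assert_allclose(a.signal, b.signal, atol=1e-12)
        for sl in a.scan_slices():
            assert a.signal[0, sl].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="zero per-scan mean"):
            percent_transform(make_ts([-1.0, 1.0]))


class TestFirDeconvolve:
    def test_exact_recovery_with_overlap(self):
        """A noiseless superposition of known per-condition responses is
        recovered to numerical precision, even with overlapping events."""
        rng = np.random.default_rng(1)
        L = 12
        resp = {"a": rng.normal(size=L), "b": rng.normal(size=L)}
        T = 100
        events = [("a", 5.0, 2.0), ("b", 10.0, 2.0), ("a", 14.0, 2.0),
                  ("b", 40.0, 2.0), ("a", 44.0, 2.0), ("b", 47.0, 2.0),
                  ("a", 70.0, 2.0), ("b", 74.0, 2.0)]
        y = np.zeros(T)
        for cond, onset, _ in events:
            i = int(onset)
            y[i:i + L] += resp[cond][: T - i]
        ptcs = fir_deconvolve(make_ts(y), EventSchedule(events), window_s=12.0)
        for p in ptcs:
            np.testing.assert_allclose(p.response, resp[p.condition],
                                       atol=1e-8)

    def test_all_zero_signal(self):
        ptcs = fir_deconvolve(make_ts(np.zeros(60)),
                              EventSchedule([("a", 5.0, 2.0), ("a", 30.0, 2.0)]),
                              window_s=10.0)
        np.testing.assert_allclose(ptcs[0].response, 0.0, atol=1e-12)

    def test_orthogonal_nuisance_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=120)
        sched = EventSchedule([("a", 10.0, 2.0), ("a", 50.0, 2.0),
                               ("a", 90.0, 2.0)])
        base = fir_deconvolve(make_ts(y), sched, window_s=10.0)[0]
        # build a nuisance column, then orthogonalize it against the full
        # design (indicators + scan intercept)
        X = np.zeros((120, 31))
        for k, onset in enumerate((10, 50, 90)):
            for lag in range(10):
                X[onset + lag, lag] = 1.0
        X[:, 30] = 1.0
        nui = rng.normal(size=120)
        nui -= X @ np.linalg.lstsq(X, nui, rcond=None)[0]
        with_nui = fir_deconvolve(make_ts(y), sched, window_s=10.0,
                                  nuisance=nui[:, None])[0]
        np.testing.assert_allclose(with_nui.response, base.response,
                                   atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        # two conditions with identical event trains are perfectly collinear
        sched = EventSchedule([("a", 5.0, 1.0), ("b", 5.0, 1.0)])
        with pytest.raises(ValueError, match="collinear"):
            fir_deconvolve(make_ts(np.random.default_rng(0).normal(size=40)),
                           sched, window_s=5.0)

    def test_se_scales_with_event_count(self):
        """GLM standard errors shrink as 1/sqrt(number of events) on white
        noise (within Monte-Carlo error)."""
        rng = np.random.default_rng(3)
        spacing, L = 25, 10

        def mean_se(n_events):
            vals = []
            for _ in range(40):
                T = spacing * n_events + L
                y = rng.normal(size=T)
                events = [("a", float(5 + spacing * i), 2.0)
                          for i in range(n_events)]
                p = fir_deconvolve(make_ts(y), EventSchedule(events),
                                   window_s=float(L))[0]
                vals.append(p.se.mean())
            return np.mean(vals)

        ratio = mean_se(4) / mean_se(16)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_linearity_of_estimates(self):
        """Deconvolving the sum of two signals gives the sum of the
        individual estimates (shared design)."""
        rng = np.random.default_rng(4)
        y1, y2 = rng.normal(size=80), rng.normal(size=80)
        sched = EventSchedule([("a", 10.0, 2.0), ("a", 45.0, 2.0)])
        r1 = fir_deconvolve(make_ts(y1), sched, window_s=8.0)[0].response
        r2 = fir_deconvolve(make_ts(y2), sched, window_s=8.0)[0].response
        r12 = fir_deconvolve(make_ts(y1 + y2), sched, window_s=8.0)[0].response
        np.testing.assert_allclose(r12, r1 + r2, atol=1e-9)


class TestSharedNoiseComponents:
    def test_planted_sinusoid_is_first_component(self):
        rng = np.random.default_rng(5)
        t = np.arange(300)
        shared = np.sin(2 * np.pi * t / 50)
        pool = np.array([shared * rng.uniform(0.5, 2.0)
                         + rng.normal(0, 0.05, size=300) for _ in range(30)])
        ts = make_ts(pool)
        comp = shared_noise_components(ts, range(30), 3)
        r = np.corrcoef(comp[:, 0], shared)[0, 1]
        assert abs(r) > 0.99

    def test_orthonormal_components_and_empty_case(self):
        rng = np.random.default_rng(6)
        ts = make_ts(rng.normal(size=(8, 50)))
        comp = shared_noise_components(ts, range(8), 4)
        np.testing.assert_allclose(comp.T @ comp, np.eye(4), atol=1e-10)
        assert shared_noise_components(ts, range(8), 0).shape == (50, 0)
        with pytest.raises(ValueError):
            shared_noise_components(ts, range(8), -1)

    def test_components_remove_shared_noise_in_deconvolution(self):
        """Using pool-estimated components as nuisance regressors recovers
        the planted response under strong shared noise."""
        rng = np.random.default_rng(7)
        T = 400
        shared = np.cumsum(rng.normal(size=T))
        shared /= np.abs(shared).max()
        resp = np.exp(-0.5 * (np.arange(10) - 4.0) ** 2)
        events = [("a", float(10 + 30 * i), 2.0) for i in range(12)]
        y = 3.0 * shared + rng.normal(0, 0.02, size=T)
        for _, onset, _ in events:
            y[int(onset):int(onset) + 10] += resp
        pool = np.array([shared * rng.uniform(0.5, 2.0)
                         + rng.normal(0, 0.02, size=T) for _ in range(20)])
        ts = make_ts(np.vstack([y, pool]))
        sched = EventSchedule(events)
        comp = shared_noise_components(ts, range(1, 21), 2)
        naive = fir_deconvolve(ts, sched, window_s=10.0)[0].response
        denoised = fir_deconvolve(ts, sched, window_s=10.0,
                                  nuisance=comp)[0].response
        assert (np.abs(denoised - resp).max()
                < 0.3 * np.abs(naive - resp).max())


class TestExtractAmplitude:
    def make_ptc(self, values):
        lags = np.arange(len(values), dtype=float)
        return PeristimulusTimecourse("a", lags, np.asarray(values, float),
                                      np.zeros(len(values)))

    def test_windows(self):
        flat = self.make_ptc(np.ones(15))
        assert extract_amplitude(flat, 6) == pytest.approx(1.0)
        ramp = self.make_ptc(np.arange(15.0))
        assert extract_amplitude(ramp, 6) == pytest.approx(8.0)  # mean(7,8,9)
        assert extract_amplitude(ramp, 1) == pytest.approx(5.0)

    def test_uncovered_window_errors(self):
        short = self.make_ptc(np.ones(5))
        with pytest.raises(ValueError, match="lag grid"):
            extract_amplitude(short, 6)
        with pytest.raises(ValueError, match="duration"):
            extract_amplitude(self.make_ptc(np.ones(15)), 3)


def test_cosine_drift_regressors_cover_low_frequencies():
    ts = make_ts(np.zeros(400), boundaries=(0, 200))
    D = cosine_drift_regressors(ts, cutoff_hz=0.0118)
    # 200 s scans at 0.0118 Hz cutoff -> floor(2*200*0.0118) = 4 per scan
    assert D.shape == (400, 8)
    assert np.all(D[200:, :4] == 0) and np.all(D[:200, 4:] == 0)
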