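"""FIR deconvolution of block-design BOLD time series.

Converts ROI time series plus event schedules into peristimulus time
courses (one response estimate per condition and lag, with GLM-based SEs)
and scalar response amplitudes.  The estimator is a single ordinary
least-squares solve of a finite-impulse-response design: each condition
contributes one indicator column per lag (a Dirac delta placed at each
stimulus onset, shifted), so overlapping responses are treated as
additive.  Scan-wise intercepts are always included; slow drift can be
absorbed with an optional per-scan cosine basis, and arbitrary nuisance
regressors (e.g. motion parameters or shared noise components) can be
appended and are estimated then discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesDataset",
    "EventSchedule",
    "PeristimulusTimecourse",
    "percent_transform",
    "fir_deconvolve",
    "shared_noise_components",
    "cosine_drift_regressors",
    "extract_amplitude",
]


@dataclass
class TimeSeriesDataset:
    """Multi-unit time series sampled every ``tr_s`` seconds.

    ``signal`` is (units x time); ``scan_boundaries`` holds the start index
    of each scan (first entry 0), partitioning the time axis.
    """

    tr_s: float
    signal: np.ndarray
    scan_boundaries: np.ndarray
    unit_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.scan_boundaries = np.asarray(self.scan_boundaries, dtype=int)
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        b = self.scan_boundaries
        if len(b) == 0 or b[0] != 0:
            raise ValueError("scan_boundaries must start at index 0")
        if np.any(np.diff(b) <= 0) or b[-1] >= self.signal.shape[1]:
            raise ValueError("scan_boundaries must be ascending and in range")
        if not self.unit_labels:
            self.unit_labels = [f"unit_{i}" for i in range(self.signal.shape[0])]

    @property
    def n_time(self) -> int:
        return self.signal.shape[1]

    def scan_slices(self) -> list[slice]:
        edges = list(self.scan_boundaries) + [self.n_time]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class EventSchedule:
    """Stimulus events as (condition label, onset_s, duration_s) triples."""

    events: list

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("schedule must contain at least one event")
        for cond, onset, dur in self.events:
            if not cond:
                raise ValueError("condition labels must be non-empty")
            if onset < 0 or dur <= 0:
                raise ValueError("onsets must be >= 0 and durations > 0")

    @property
    def conditions(self) -> list:
        seen: dict = {}
        for cond, _, _ in self.events:
            seen.setdefault(cond, None)
        return list(seen)


@dataclass
class PeristimulusTimecourse:
    """Deconvolved response of one condition on a lag grid starting at 0."""

    condition: str
    lags_s: np.ndarray
    response: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must be strictly ascending")
        if not len(self.lags_s) == len(self.response) == len(self.se):
            raise ValueError("lags, response and se must have equal length")


def percent_transform(ts: TimeSeriesDataset) -> TimeSeriesDataset:
    """Per-scan percent signal change: ``(y - mean) / mean * 100``.

    Applied independently per unit and scan; the per-scan output mean is 0
    by construction.  A zero per-scan mean is an error (the transform is
    undefined for mean-free raw data).
    """
    out = np.empty_like(ts.signal)
    for sl in ts.scan_slices():
        seg = ts.signal[:, sl]
        mean = seg.mean(axis=1, keepdims=True)
        if np.any(mean == 0):
            raise ValueError(f"zero per-scan mean in scan {sl.start}:{sl.stop}")
        out[:, sl] = (seg - mean) / mean * 100.0
    return TimeSeriesDataset(ts.tr_s, out, ts.scan_boundaries.copy(),
                             list(ts.unit_labels))


def _fir_design(ts: TimeSeriesDataset, schedule: EventSchedule,
                n_lags: int) -> tuple[np.ndarray, list]:
    conditions = schedule.conditions
    T = ts.n_time
    X = np.zeros((T, len(conditions) * n_lags))
    col_of = {c: i * n_lags for i, c in enumerate(conditions)}
    total_s = T * ts.tr_s
    for cond, onset_s, _ in schedule.events:
        if onset_s >= total_s:
            raise ValueError(f"event onset {onset_s}s beyond series end {total_s}s")
        i0 = int(round(onset_s / ts.tr_s))
        for lag in range(n_lags):
            if i0 + lag < T:
                X[i0 + lag, col_of[cond] + lag] += 1.0
    return X, conditions


def _name_collinear(X: np.ndarray, names: list, tol: float = 1e-8) -> list:
    """Greedy QR pass: columns (by name) that are linear combinations of
    earlier ones."""
    bad, basis = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col.copy()
        for b in basis:
            resid -= (b @ resid) * b
        if np.linalg.norm(resid) <= tol * max(np.linalg.norm(col), 1.0):
            bad.append(names[j])
        else:
            basis.append(resid / np.linalg.norm(resid))
    return bad


def fir_deconvolve(
    ts: TimeSeriesDataset,
    schedule: EventSchedule,
    window_s: float = 20.0,
    nuisance: np.ndarray | None = None,
    unit: int = 0,
) -> list[PeristimulusTimecourse]:
    """Estimate one peristimulus time course per condition by FIR regression.

    The indicator design places a delta at each onset of a condition and
    shifts it across ``window_s / tr_s`` lags; the least-squares solution is
    the per-condition, per-lag response in the units of ``ts`` (expected:
    % signal change).  Per-lag SEs come from the residual variance and the
    design covariance.  Scan intercepts are always modelled; extra nuisance
    columns are fitted and discarded.  Rank-deficient designs raise an
    error naming the collinear columns.
    """
    n_lags = int(round(window_s / ts.tr_s))
    if n_lags < 1:
        raise ValueError("window_s must cover at least one sample")
    X_fir, conditions = _fir_design(ts, schedule, n_lags)
    lag_names = [f"{c}[lag {l}]" for c in conditions for l in range(n_lags)]

    # scan intercepts
    slices = ts.scan_slices()
    X_scan = np.zeros((ts.n_time, len(slices)))
    for i, sl in enumerate(slices):
        X_scan[sl, i] = 1.0
    names = lag_names + [f"scan_{i}" for i in range(len(slices))]
    blocks = [X_fir, X_scan]

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != ts.n_time:
            nuisance = nuisance.T
        if nuisance.shape[0] != ts.n_time:
            raise ValueError("nuisance matrix length does not match the series")
        blocks.append(nuisance)
        names += [f"nuisance_{i}" for i in range(nuisance.shape[1])]

    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _name_collinear(X, names)
        raise ValueError(f"rank-deficient FIR design; collinear columns: {bad}")

    y = ts.signal[unit]
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = ts.n_time - X.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov_diag = sigma2 * np.diag(np.linalg.pinv(X.T @ X))
    se = np.sqrt(np.clip(cov_diag, 0.0, None))

    lags = np.arange(n_lags) * ts.tr_s
    out = []
    for i, cond in enumerate(conditions):
        sl = slice(i * n_lags, (i + 1) * n_lags)
        out.append(PeristimulusTimecourse(cond, lags, beta[sl], se[sl]))
    return out


def shared_noise_components(ts: TimeSeriesDataset, noise_pool,
                            n_components: int) -> np.ndarray:
    """Top principal-component time courses of a stimulus-silent unit pool.

    Returns a (time x n_components) matrix of mutually orthogonal,
    unit-norm time courses, suitable as nuisance regressors.  ``noise_pool``
    may hold unit indices or unit labels.
    """
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    pool = list(noise_pool)
    if not pool:
        raise ValueError("noise_pool must be non-empty")
    if isinstance(pool[0], str):
        pool = [ts.unit_labels.index(p) for p in pool]
    if n_components > len(pool):
        raise ValueError("n_components exceeds the noise-pool size")
    if n_components == 0:
        return np.empty((ts.n_time, 0))
    mat = ts.signal[pool].T  # time x units
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    return u[:, :n_components]


def cosine_drift_regressors(ts: TimeSeriesDataset,
                            cutoff_hz: float = 0.0118) -> np.ndarray:
    """Per-scan discrete-cosine drift basis up to ``cutoff_hz``.

    Supplying these as nuisance regressors plays the role of high-pass
    filtering while keeping the estimator a single least-squares solve.
    """
    cols = []
    for sl in ts.scan_slices():
        n = sl.stop - sl.start
        dur = n * ts.tr_s
        k_max = int(np.floor(2.0 * dur * cutoff_hz))
        t = np.arange(n)
        for k in range(1, k_max + 1):
            col = np.zeros(ts.n_time)
            col[sl] = np.cos(np.pi * k * (2 * t + 1) / (2 * n))
            cols.append(col)
    if not cols:
        return np.empty((ts.n_time, 0))
    return np.column_stack(cols)


def _extraction_value(lags_s: np.ndarray, response: np.ndarray,
                      duration_s: float, tol: float = 1e-6) -> float:
    """Amplitude read-out: 6-s blocks use the mean response at lags 7, 8
    and 9 s (around the peak); 1-s blocks use the response at lag 5 s."""
    if duration_s == 6:
        targets = (7.0, 8.0, 9.0)
    elif duration_s == 1:
        targets = (5.0,)
    else:
        raise ValueError(
            f"no amplitude window defined for duration {duration_s}s "
            "(supported: 1 s and 6 s)")
    vals = []
    for t in targets:
        idx = np.nonzero(np.abs(lags_s - t) < tol)[0]
        if len(idx) == 0:
            raise ValueError(f"lag grid does not cover the {t}s sample "
                             f"required for duration {duration_s}s")
        vals.append(response[idx[0]])
    return float(np.mean(vals))


def extract_amplitude(ptc: PeristimulusTimecourse, duration_s: float) -> float:
    """Scalar response amplitude (% signal change) of a time course."""
    return _extraction_value(ptc.lags_s, ptc.response, duration_s)
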