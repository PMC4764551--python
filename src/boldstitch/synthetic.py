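"""Synthetic BOLD summation experiments.

This module generates the data the rest of the package analyses: a
"neural doubling" design in which two co-localized, independent neuronal
populations are driven either separately (single-sided stimuli A, B) or
together (double-sided stimulus A+B).  The generative model is

* a Naka-Rushton neural contrast response ``R(c) = r0 + r_max c^n / (c^n + c50^n)``,
* exact doubling of aggregate neural response for double-sided stimuli,
* a power-law hemodynamic transform ``B = k Z^gamma`` from aggregate neural
  response ``Z`` to BOLD amplitude ``B`` (% signal change),

with block designs (stimulus blocks separated by long blanks), Gaussian
amplitude noise, and AR(1) + drift + shared-component time-series noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .deconvolution import EventSchedule, TimeSeriesDataset

__all__ = [
    "NeuralCRF",
    "BvZLaw",
    "TimeSeriesNoise",
    "ExperimentDesign",
    "SummationDataset",
    "naka_rushton_response",
    "contrast_grid",
    "double_gamma_hrf",
    "block_response_kernel",
    "counterbalanced_sequence",
    "generate_amplitudes",
    "generate_timeseries",
]

STIM_TYPES = ("single_A", "single_B", "double")


@dataclass(frozen=True)
class NeuralCRF:
    """Naka-Rushton contrast response function.

    Parameters are in "neural units" (arbitrary but fixed): ``r_max`` is the
    peak evoked response, ``c50`` the semi-saturation Weber contrast,
    ``exponent_n`` the slope parameter and ``r0`` an optional baseline.
    """

    r_max: float
    c50: float
    exponent_n: float
    r0: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if not 0 < self.c50 <= 1:
            raise ValueError(f"c50 must be in (0, 1], got {self.c50}")
        if not self.exponent_n > 0:
            raise ValueError(f"exponent_n must be > 0, got {self.exponent_n}")
        if self.r0 < 0:
            raise ValueError(f"r0 must be >= 0, got {self.r0}")

    def __call__(self, c):
        return naka_rushton_response(c, self)


@dataclass(frozen=True)
class BvZLaw:
    """Power-law BOLD transform ``B = k_scale * Z**gamma``."""

    k_scale: float
    gamma: float

    def __post_init__(self) -> None:
        if not self.k_scale > 0:
            raise ValueError(f"k_scale must be > 0, got {self.k_scale}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    def bold(self, z):
        z = np.asarray(z, dtype=float)
        return self.k_scale * z**self.gamma


def naka_rushton_response(c, crf: NeuralCRF):
    """Evoked neural response at Weber contrast ``c``.

    ``R(c) = r0 + r_max * c^n / (c^n + c50^n)``; nondecreasing on [0, 1].
    Accepts scalars or arrays; contrasts outside [0, 1] are a domain error.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0) or np.any(c_arr > 1):
        raise ValueError("Weber contrast must lie in [0, 1]")
    cn = c_arr**crf.exponent_n
    out = crf.r0 + crf.r_max * cn / (cn + crf.c50**crf.exponent_n)
    return float(out) if np.isscalar(c) else out


def contrast_grid(c_min: float, c_max: float, n_levels: int) -> np.ndarray:
    """Ascending Weber contrasts in equal logarithmic steps.

    The 5-level grid used throughout, ``contrast_grid(0.05, 1.0, 5)``, spans
    0.05 to 1.0 in four equal log steps.
    """
    if not 0 < c_min <= c_max <= 1:
        raise ValueError("need 0 < c_min <= c_max <= 1")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if n_levels == 1:
        if c_min != c_max:
            raise ValueError("n_levels=1 requires c_min == c_max")
        return np.array([c_min])
    return np.geomspace(c_min, c_max, n_levels)


@dataclass(frozen=True)
class TimeSeriesNoise:
    """Time-series noise model: AR(1) innovations + slow drift + components
    shared across units (the structure global denoising is meant to remove).

    ``white_sd`` is the AR(1) innovation SD in % signal change; ``drift_amp``
    the per-scan amplitude of a slow cosine drift; ``n_shared`` global noise
    components are mixed into every unit with random loadings of SD
    ``shared_sd``.  ``n_pool_units`` stimulus-silent units are generated
    alongside the ROI so the shared components can be estimated from them.
    """

    white_sd: float = 0.3
    ar1: float = 0.3
    drift_amp: float = 0.5
    n_shared: int = 3
    shared_sd: float = 0.3
    n_pool_units: int = 20

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_amp < 0 or self.shared_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if self.n_shared < 0 or self.n_pool_units < 0:
            raise ValueError("counts must be >= 0")

    @property
    def silent(self) -> bool:
        return self.white_sd == 0 and self.drift_amp == 0 and (
            self.shared_sd == 0 or self.n_shared == 0
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Block design of the BOLD summation experiment.

    Defaults follow the 6-s protocol: 19 stimulus blocks per scan, each
    followed by a 16-s blank, one scan per contrast level, sampled at 1 s.
    ``amp_noise_sd`` is the per-run amplitude noise SD (% signal change); a
    tabulated amplitude, being an average over ``n_runs`` runs, is perturbed
    with SD ``amp_noise_sd / sqrt(n_runs)`` and carries that value as its SE.
    """

    contrasts: tuple = tuple(np.geomspace(0.05, 1.0, 5))
    duration_s: float = 6.0
    blank_s: float = 16.0
    n_blocks: int = 19
    tr_s: float = 1.0
    amp_noise_sd: float = 0.0
    n_runs: int = 5
    ts_noise: TimeSeriesNoise = field(default_factory=TimeSeriesNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("contrasts must be a non-empty 1-D sequence")
        if np.any(np.diff(c) <= 0):
            raise ValueError("contrasts must be strictly ascending")
        if np.any(c <= 0) or np.any(c > 1):
            raise ValueError("contrasts must lie in (0, 1]")
        if self.duration_s <= 0 or self.blank_s <= 0 or self.tr_s <= 0:
            raise ValueError("durations must be > 0")
        if self.amp_noise_sd < 0:
            raise ValueError("amp_noise_sd must be >= 0")
        if self.n_runs < 1 or self.n_blocks < 1:
            raise ValueError("n_runs and n_blocks must be >= 1")

    @property
    def contrast_array(self) -> np.ndarray:
        return np.asarray(self.contrasts, dtype=float)


@dataclass
class SummationDataset:
    """Single- and double-sided BOLD amplitudes over a contrast grid.

    ``b_single`` is the average of the A- and B-side amplitudes (the two
    sides evoke statistically identical responses, so their mean is used in
    all analyses).  ``ground_truth`` carries the generating (CRF, BvZLaw)
    pair for simulated data and is ``None`` for measured data.
    """

    roi_label: str
    duration_s: float
    contrasts: np.ndarray
    b_single: np.ndarray
    se_single: np.ndarray
    b_double: np.ndarray
    se_double: np.ndarray
    n_runs: np.ndarray
    b_single_A: np.ndarray | None = None
    b_single_B: np.ndarray | None = None
    ground_truth: tuple | None = None

    def __post_init__(self) -> None:
        n = len(self.contrasts)
        for name in ("b_single", "se_single", "b_double", "se_double", "n_runs"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        if np.any(self.se_single < 0) or np.any(self.se_double < 0):
            raise ValueError("SEs must be >= 0")
        for name in ("b_single_A", "b_single_B"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=float))

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)


def generate_amplitudes(
    design: ExperimentDesign,
    crf: NeuralCRF,
    law: BvZLaw,
    roi_label: str = "sim",
) -> SummationDataset:
    """Simulate an amplitude table from the doubling model.

    Noiseless (``amp_noise_sd == 0``): ``b_single(c) = k R(c)^gamma`` and
    ``b_double(c) = k (2 R(c))^gamma`` exactly, with zero SEs.  With noise,
    each side-specific and double-sided entry receives independent Gaussian
    noise of SD ``amp_noise_sd / sqrt(n_runs)`` and carries that SE; the
    single-sided amplitude is the A/B mean (SE smaller by sqrt(2)).
    Seeded and reproducible via ``design.seed``.
    """
    c = design.contrast_array
    z = naka_rushton_response(c, crf)
    clean_single = law.bold(z)
    clean_double = law.bold(2.0 * z)

    sigma = design.amp_noise_sd / math.sqrt(design.n_runs)
    if sigma > 0:
        rng = np.random.default_rng(design.seed)
        b_a = clean_single + rng.normal(0.0, sigma, size=len(c))
        b_b = clean_single + rng.normal(0.0, sigma, size=len(c))
        b_double = clean_double + rng.normal(0.0, sigma, size=len(c))
        se_single = np.full(len(c), sigma / math.sqrt(2.0))
        se_double = np.full(len(c), sigma)
    else:
        b_a = clean_single.copy()
        b_b = clean_single.copy()
        b_double = clean_double.copy()
        se_single = np.zeros(len(c))
        se_double = np.zeros(len(c))

    return SummationDataset(
        roi_label=roi_label,
        duration_s=design.duration_s,
        contrasts=c,
        b_single=(b_a + b_b) / 2.0,
        se_single=se_single,
        b_double=b_double,
        se_double=se_double,
        n_runs=np.full(len(c), design.n_runs, dtype=float),
        b_single_A=b_a,
        b_single_B=b_b,
        ground_truth=(crf, law),
    )


# --------------------------------------------------------------------------
# hemodynamics


def double_gamma_hrf(t, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Difference of two gamma densities peaking at ``peak_s`` and
    ``undershoot_s`` with peak:undershoot amplitude ratio ``ratio``;
    normalized to unit peak.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    # shape a, scale 1 => mode at a-1; choose a = peak + 1
    h = gamma_dist.pdf(t, peak_s + 1.0) - gamma_dist.pdf(t, undershoot_s + 1.0) / ratio
    h = np.where(t < 0, 0.0, h)
    peak = h.max()
    return h / peak if peak > 0 else h


def block_response_kernel(duration_s: float, tr_s: float,
                          window_s: float = 20.0) -> np.ndarray:
    """Unit BOLD response to one stimulus block, sampled on the lag grid.

    A boxcar of ``duration_s`` convolved with the canonical HRF, truncated
    to ``window_s`` and normalized so that the amplitude-extraction window
    of a unit-amplitude event reads exactly 1 (6-s blocks: mean of the
    samples at 7, 8, 9 s; 1-s blocks: the sample at 5 s).  This convention
    makes the simulator and the deconvolution/extraction stage mutually
    consistent, which is what makes noiseless parameter recovery exact.
    """
    n_lags = int(round(window_s / tr_s))
    t_hi = np.arange(0.0, window_s, tr_s / 10.0)  # fine grid for convolution
    box = ((t_hi >= 0) & (t_hi < duration_s)).astype(float)
    hrf = double_gamma_hrf(t_hi)
    conv = np.convolve(box, hrf)[: len(t_hi)] * (tr_s / 10.0)
    lags = np.arange(n_lags) * tr_s
    kernel = np.interp(lags, t_hi, conv)

    from .deconvolution import _extraction_value

    norm = _extraction_value(lags, kernel, duration_s)
    if norm <= 0:
        raise ValueError("degenerate response kernel: nonpositive window value")
    return kernel / norm


# --------------------------------------------------------------------------
# counterbalancing


def counterbalanced_sequence(n_blocks: int, n_types: int,
                             rng: np.random.Generator,
                             max_attempts: int = 200) -> list[int]:
    """Random block order with equal first-order transition counts.

    Every ordered pair of stimulus types (self-pairs included) occurs
    equally often among the ``n_blocks - 1`` transitions, i.e. each type is
    preceded by every type equally often.  Feasible iff ``n_blocks - 1`` is
    divisible by ``n_types**2``; built as a randomized Eulerian circuit of
    the complete transition multigraph and verified before returning.
    """
    n_trans = n_blocks - 1
    if n_trans % (n_types**2) != 0:
        raise ValueError(
            "first-order counterbalancing infeasible: n_blocks - 1 = "
            f"{n_trans} transitions cannot be split equally over "
            f"{n_types**2} ordered stimulus-type pairs"
        )
    reps = n_trans // (n_types**2)
    for _ in range(max_attempts):
        seq = _random_eulerian_circuit(n_types, reps, rng)
        counts = np.zeros((n_types, n_types), dtype=int)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
        if np.all(counts == reps):
            return seq
    raise ValueError(
        "counterbalancing search failed: no Eulerian circuit with equal "
        f"transition counts found in {max_attempts} attempts"
    )


def _random_eulerian_circuit(n_types: int, reps: int,
                             rng: np.random.Generator) -> list[int]:
    """Hierholzer's algorithm with shuffled edge order on the complete
    directed multigraph (self-loops included, each edge repeated ``reps``)."""
    adj: dict[int, list[int]] = {}
    for a in range(n_types):
        targets = [b for b in range(n_types) for _ in range(reps)]
        rng.shuffle(targets)
        adj[a] = targets
    start = int(rng.integers(n_types))
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(adj[v].pop())
        else:
            circuit.append(stack.pop())
    return circuit[::-1]


# --------------------------------------------------------------------------
# time-series simulation


def generate_timeseries(
    design: ExperimentDesign,
    crf: NeuralCRF,
    law: BvZLaw,
    window_s: float = 20.0,
    scans_per_contrast: int = 1,
) -> tuple[TimeSeriesDataset, EventSchedule]:
    """Simulate ROI time series (% signal change) with an event schedule.

    Each scan tests one contrast: a lead-in blank, then ``n_blocks``
    stimulus blocks (types A / B / A+B in a counterbalanced order) each
    followed by a blank.  The clean signal superposes, per event, the
    condition amplitude ``k Z^gamma`` (``Z`` doubled for A+B) times the
    normalized block-response kernel.  Unit 0 ("roi") carries the signal;
    ``ts_noise.n_pool_units`` stimulus-silent pool units share the global
    noise components.  Condition labels are ``"<type>@<contrast>"``.
    """
    tr = design.tr_s
    noise = design.ts_noise
    kernel = block_response_kernel(design.duration_s, tr, window_s)
    rng = np.random.default_rng(design.seed)

    scan_len = int(round((design.blank_s
                          + design.n_blocks * (design.duration_s + design.blank_s)) / tr))
    contrasts = design.contrast_array
    n_scans = len(contrasts) * scans_per_contrast
    total_len = scan_len * n_scans

    amp_by_type = {}
    for c in contrasts:
        z = naka_rushton_response(float(c), crf)
        amp_by_type[("single_A", c)] = float(law.bold(z))
        amp_by_type[("single_B", c)] = float(law.bold(z))
        amp_by_type[("double", c)] = float(law.bold(2.0 * z))

    n_units = 1 + (noise.n_pool_units if not noise.silent else 0)
    signal = np.zeros((n_units, total_len))
    events = []

    scan_starts = []
    pos = 0
    for c in contrasts:
        for _ in range(scans_per_contrast):
            scan_starts.append(pos)
            order = counterbalanced_sequence(design.n_blocks, len(STIM_TYPES), rng)
            t_block = design.blank_s
            for idx in order:
                stim = STIM_TYPES[idx]
                onset_s = pos * tr + t_block
                onset_i = int(round(onset_s / tr))
                amp = amp_by_type[(stim, c)]
                end = min(onset_i + len(kernel), total_len)
                signal[0, onset_i:end] += amp * kernel[: end - onset_i]
                events.append((f"{stim}@{c:g}", onset_s, design.duration_s))
                t_block += design.duration_s + design.blank_s
            pos += scan_len

    if not noise.silent:
        for s0 in scan_starts:
            sl = slice(s0, s0 + scan_len)
            t_scan = np.arange(scan_len) * tr
            shared = rng.normal(0.0, 1.0, size=(noise.n_shared, scan_len))
            loadings = rng.normal(0.0, noise.shared_sd,
                                  size=(n_units, noise.n_shared))
            for u in range(n_units):
                eps = rng.normal(0.0, noise.white_sd, size=scan_len)
                ar = np.empty(scan_len)
                prev = 0.0
                for i in range(scan_len):
                    prev = noise.ar1 * prev + eps[i]
                    ar[i] = prev
                phase = rng.uniform(0, 2 * np.pi)
                drift = noise.drift_amp * np.cos(
                    2 * np.pi * t_scan / (scan_len * tr) + phase)
                signal[u, sl] += ar + drift + loadings[u] @ shared

    labels = ["roi"] + [f"pool_{i}" for i in range(n_units - 1)]
    ts = TimeSeriesDataset(
        tr_s=tr,
        signal=signal,
        scan_boundaries=np.array(scan_starts, dtype=int),
        unit_labels=labels,
    )
    return ts, EventSchedule(events=events)


def noiseless(design: ExperimentDesign) -> ExperimentDesign:
    """Copy of ``design`` with all noise sources switched off."""
    return replace(
        design,
        amp_noise_sd=0.0,
        ts_noise=TimeSeriesNoise(white_sd=0.0, ar1=0.0, drift_amp=0.0,
                                 n_shared=0, shared_sd=0.0, n_pool_units=0),
    )
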