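"""Model-neutral stitching of paired BOLD amplitudes onto one monotone curve.

Given n pairs of BOLD amplitudes (B1_i from single-sided stimulation, B2_i
from double-sided stimulation of the same contrast) and the doubling
assumption — the double-sided stimulus evokes exactly twice the aggregate
neural response Z_i of the single-sided one — the 2n points

    (Z_1, B1_1), (2 Z_1, B2_1), ..., (Z_n, B1_n), (2 Z_n, B2_n)

must lie on a single smooth monotone curve.  Setting Z_1 = 1 (the units of
Z are arbitrary) leaves n-1 ordered unknowns 1 <= Z_2 <= ... <= Z_n, which
are estimated by nested least squares: an outer derivative-free search
over the latent levels, and an inner shape-constrained fit of a monotone
cubic (spline) to the stitched points.  The objective is the normalized
chi-square: residual sum of squares divided by the residual degrees of
freedom n + 1 - 2m, where m is the number of spline control points (2m
free parameters); m = 2 is the only admissible choice for n = 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "StitchConfig",
    "MonotoneCurve",
    "StitchResult",
    "fit_monotone_cubic",
    "normalized_chi_square",
    "stitch",
]


@dataclass(frozen=True)
class StitchConfig:
    """Settings of the stitching fit.

    ``fit_space`` selects the coordinates in which residuals are measured:
    ``"loglog"`` (log-x / log-y, default; a power law is then exactly a
    straight line, so noiseless power-law data are recovered exactly) or
    ``"logx"`` (log-x / linear-y).  Residuals are unweighted by default;
    ``weighted=True`` divides them by the measurement SEs.
    """

    m_control: int = 2
    fit_space: str = "loglog"
    monotonicity_grid: int = 101
    outer_tol: float = 1e-10
    inner_tol: float = 1e-12
    n_restarts: int = 8
    seed: int = 0
    max_outer_iter: int = 4000
    weighted: bool = False

    def __post_init__(self) -> None:
        if self.m_control < 2:
            raise ValueError("m_control must be >= 2")
        if self.fit_space not in ("loglog", "logx"):
            raise ValueError("fit_space must be 'loglog' or 'logx'")
        if self.outer_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.monotonicity_grid < 2:
            raise ValueError("monotonicity_grid must be >= 2")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class MonotoneCurve:
    """Nondecreasing piecewise-cubic Hermite curve in fit space.

    ``knots`` are the control-point abscissae (fit-space units); ``values``
    and ``slopes`` the fitted ordinate and derivative at each knot (2m free
    parameters for m knots).  The derivative is nonnegative at every
    monotonicity-grid point of the domain.
    """

    knots: np.ndarray
    values: np.ndarray
    slopes: np.ndarray
    fit_space: str = "loglog"

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def __call__(self, x) -> np.ndarray:
        """Evaluate the curve at fit-space abscissae ``x``."""
        A = _hermite_design(np.atleast_1d(np.asarray(x, dtype=float)),
                            self.knots, deriv=False)
        return A @ np.concatenate([self.values, self.slopes])

    def derivative(self, x) -> np.ndarray:
        A = _hermite_design(np.atleast_1d(np.asarray(x, dtype=float)),
                            self.knots, deriv=True)
        return A @ np.concatenate([self.values, self.slopes])


def _hermite_design(x: np.ndarray, knots: np.ndarray,
                    deriv: bool) -> np.ndarray:
    """Design matrix of the cubic Hermite basis: columns are the partial
    derivatives of the curve (or its slope) w.r.t. (values..., slopes...)."""
    m = len(knots)
    A = np.zeros((len(x), 2 * m))
    seg = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, m - 2)
    for j in range(m - 1):
        mask = seg == j
        if not np.any(mask):
            continue
        h = knots[j + 1] - knots[j]
        t = (x[mask] - knots[j]) / h
        if not deriv:
            A[mask, j] = 2 * t**3 - 3 * t**2 + 1          # h00 -> value_j
            A[mask, j + 1] = -2 * t**3 + 3 * t**2         # h01 -> value_{j+1}
            A[mask, m + j] = (t**3 - 2 * t**2 + t) * h    # h10 -> slope_j
            A[mask, m + j + 1] = (t**3 - t**2) * h        # h11 -> slope_{j+1}
        else:
            A[mask, j] = (6 * t**2 - 6 * t) / h
            A[mask, j + 1] = (-6 * t**2 + 6 * t) / h
            A[mask, m + j] = 3 * t**2 - 4 * t + 1
            A[mask, m + j + 1] = 3 * t**2 - 2 * t
    return A


def fit_monotone_cubic(
    points, config: StitchConfig | None = None,
    weights: np.ndarray | None = None,
) -> tuple[MonotoneCurve, float]:
    """Least-squares monotone cubic (spline) through fit-space points.

    ``points`` is an (N, 2) array of fit-space (x, y).  ``m_control`` knots
    are placed at the data extremes (and, for m > 2, equally spaced in
    between); the 2m Hermite parameters are fitted by least squares subject
    to a nonnegative derivative at ``monotonicity_grid`` points of the
    domain.  The unconstrained solution is accepted when it already
    satisfies the constraint; otherwise an SLSQP quadratic solve enforces
    it.  Returns the curve and the (possibly weighted) sum of squared
    residuals in fit space.
    """
    config = config or StitchConfig()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    x, y = pts[:, 0], pts[:, 1]
    m = config.m_control
    if len(np.unique(x)) < 2 * m:
        raise ValueError(
            f"need at least {2 * m} points with distinct x for "
            f"{m} control points (2m parameters)")
    knots = np.linspace(x.min(), x.max(), m)
    A = _hermite_design(x, knots, deriv=False)
    grid = np.linspace(knots[0], knots[-1], config.monotonicity_grid)
    C = _hermite_design(grid, knots, deriv=True)

    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    Aw, yw = A * sw[:, None], y * sw

    theta, _, _, _ = np.linalg.lstsq(Aw, yw, rcond=None)
    scale = max(np.abs(C @ theta).max(), 1.0)
    if np.min(C @ theta) < -config.inner_tol * scale:
        theta = _constrained_lsq(Aw, yw, C, theta)
    resid = Aw @ theta - yw
    sse = float(resid @ resid)
    curve = MonotoneCurve(knots, theta[:m], theta[m:], config.fit_space)
    return curve, sse


def _constrained_lsq(A: np.ndarray, y: np.ndarray, C: np.ndarray,
                     theta0: np.ndarray) -> np.ndarray:
    """Minimize ||A theta - y||^2 subject to C theta >= 0 (SLSQP)."""
    H = A.T @ A
    g = A.T @ y
    m = len(theta0) // 2
    start = theta0.copy()
    start[m:] = np.clip(start[m:], 0.0, None)  # feasible-ish start

    def obj(th):
        r = A @ th - y
        return float(r @ r)

    def jac(th):
        return 2.0 * (H @ th - g)

    res = minimize(
        obj, start, jac=jac, method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda th: C @ th,
                      "jac": lambda th: C}],
        options={"maxiter": 400, "ftol": 1e-14},
    )
    th = res.x
    # tiny negative derivatives from the QP tolerance: project slopes up
    viol = C @ th
    if viol.min() < 0 and viol.min() > -1e-8:
        return th
    if viol.min() < -1e-8:
        # fall back to a flat (always feasible) curve if SLSQP failed badly
        flat = np.zeros_like(th)
        flat[:m] = np.mean(y)
        if obj(flat) < obj(th) or np.isnan(obj(th)):
            return flat
    return th


def normalized_chi_square(sse: float, n_pairs: int, m_control: int) -> float:
    """Residual sum of squares per residual degree of freedom.

    A cubic spline with m control points has 2m free parameters; stitching
    n amplitude pairs adds n - 1 latent levels, leaving
    ``dof = n_pairs + 1 - 2 m_control`` residual degrees of freedom (2n
    points minus (n - 1) latent parameters minus 2m spline parameters).
    For n = 5 pairs the residual has no degrees of freedom unless m = 2.
    """
    dof = n_pairs + 1 - 2 * m_control
    if dof <= 0:
        raise ValueError(
            f"residual has no degrees of freedom: n_pairs + 1 - 2*m_control "
            f"= {n_pairs} + 1 - {2 * m_control} = {dof}; reduce m_control")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    return sse / dof


@dataclass
class StitchResult:
    """Outcome of the stitching fit.

    ``z_rel`` are the latent neural levels relative to the lowest contrast
    (``z_rel[0] == 1``, nondecreasing); ``stitched_points`` the 2n
    (Z, B) pairs {(z_i, B1_i)} U {(2 z_i, B2_i)} in data space; ``nchisq``
    the minimized normalized chi-square in fit space.
    """

    z_rel: np.ndarray
    curve: MonotoneCurve
    nchisq: float
    stitched_points: np.ndarray
    converged: bool
    restarts_used: int
    identifiable: bool = True

    def __post_init__(self) -> None:
        self.z_rel = np.asarray(self.z_rel, dtype=float)
        self.stitched_points = np.asarray(self.stitched_points, dtype=float)


def _stitched_xy(z: np.ndarray, b1: np.ndarray, b2: np.ndarray,
                 fit_space: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([z, 2.0 * z])
    y = np.concatenate([b1, b2])
    xf = np.log10(x)
    yf = np.log10(y) if fit_space == "loglog" else y
    return xf, yf


def _z_from_params(u: np.ndarray) -> np.ndarray:
    """Map n-1 unconstrained parameters to ordered levels via cumulative
    positive increments of log Z: z_1 = 1, log z_i = log z_{i-1} + e^{u_i}."""
    return np.exp(np.concatenate([[0.0], np.cumsum(np.exp(u))]))


def _params_from_z(z: np.ndarray) -> np.ndarray:
    incr = np.diff(np.log(z))
    return np.log(np.clip(incr, 1e-8, None))


def stitch(dataset, config: StitchConfig | None = None) -> StitchResult:
    """Estimate latent neural levels by nested least squares.

    Outer: derivative-free simplex search (with seeded multi-start) over
    n - 1 unconstrained parameters mapped to ordered levels
    1 = Z_1 <= ... <= Z_n.  Inner: monotone cubic fit to the 2n stitched
    points; objective is the normalized chi-square.  The first start is an
    informed guess from the pooled doubling-ratio exponent; the rest are
    seeded random perturbations of an equal-log-spacing start.
    """
    config = config or StitchConfig()
    b1 = np.asarray(dataset.b_single, dtype=float)
    b2 = np.asarray(dataset.b_double, dtype=float)
    n = len(b1)
    normalized_chi_square(0.0, n, config.m_control)  # surface the dof rule early
    if not (np.all(np.isfinite(b1)) and np.all(np.isfinite(b2))):
        raise ValueError("amplitudes must be finite")
    if config.fit_space == "loglog" and (np.any(b1 <= 0) or np.any(b2 <= 0)):
        raise ValueError("log-y fit space requires strictly positive amplitudes")

    weights = None
    if config.weighted:
        se = np.concatenate([np.asarray(dataset.se_single, dtype=float),
                             np.asarray(dataset.se_double, dtype=float)])
        if np.any(se <= 0):
            raise ValueError("weighted fit requires strictly positive SEs")
        if config.fit_space == "loglog":
            # delta method: sd(log10 B) = se / (B ln 10)
            b = np.concatenate([b1, b2])
            weights = (b * np.log(10.0) / se) ** 2
        else:
            weights = 1.0 / se**2

    all_b = np.concatenate([b1, b2])
    if np.ptp(all_b) <= 1e-12 * max(abs(all_b).max(), 1.0):
        # flat data: any ordered Z fits a flat curve equally well
        warnings.warn("all amplitudes identical: latent levels are not "
                      "identifiable", stacklevel=2)
        z = np.ones(n)
        xf, yf = _stitched_xy(z, b1, b2, config.fit_space)
        yv = np.log10(all_b[0]) if config.fit_space == "loglog" else all_b[0]
        knots = np.array([xf.min(), xf.max()])
        curve = MonotoneCurve(knots, np.full(2, yv), np.zeros(2),
                              config.fit_space)
        return StitchResult(z, curve, 0.0,
                            np.column_stack([np.concatenate([z, 2 * z]), all_b]),
                            converged=True, restarts_used=0, identifiable=False)

    def objective(u: np.ndarray) -> float:
        z = _z_from_params(u)
        if not np.all(np.isfinite(z)) or z[-1] > 1e12:
            return np.inf
        xf, yf = _stitched_xy(z, b1, b2, config.fit_space)
        try:
            _, sse = fit_monotone_cubic(np.column_stack([xf, yf]), config,
                                        weights=weights)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        return normalized_chi_square(sse, n, config.m_control)

    rng = np.random.default_rng(config.seed)
    starts = []
    # informed start: pooled ratio exponent -> Z_i ~ (B1_i / B1_1)^(1/gamma)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = b2 / b1
        valid = (b1 > 0) & (b2 > 0) & (ratios > 0)
    if np.any(valid):
        gamma0 = float(np.mean(np.log2(ratios[valid])))
        if gamma0 > 0.05 and np.all(b1 > 0):
            z0 = np.maximum.accumulate((b1 / b1[0]) ** (1.0 / gamma0))
            z0 = np.maximum(z0, np.exp(np.arange(n) * 1e-6))
            starts.append(_params_from_z(z0))
    base = _params_from_z(np.exp(np.linspace(0.0, np.log(4.0), n)))
    while len(starts) < config.n_restarts:
        starts.append(base + rng.normal(0.0, 1.0, size=n - 1))

    best, best_fun, best_ok, used = None, np.inf, False, 0
    for u0 in starts[: config.n_restarts]:
        used += 1
        res = minimize(
            objective, u0, method="Nelder-Mead",
            options={"xatol": config.outer_tol, "fatol": config.outer_tol,
                     "maxiter": config.max_outer_iter,
                     "maxfev": config.max_outer_iter},
        )
        if res.fun < best_fun:
            best, best_fun, best_ok = res.x, res.fun, bool(res.success)
        if best_fun < 1e-14:
            break

    if best is None or not np.isfinite(best_fun):
        raise RuntimeError("stitching optimizer failed from every start")
    if not best_ok:
        warnings.warn("stitching optimizer did not report convergence; "
                      "returning best solution found", stacklevel=2)

    z = _z_from_params(best)
    xf, yf = _stitched_xy(z, b1, b2, config.fit_space)
    curve, sse = fit_monotone_cubic(np.column_stack([xf, yf]), config,
                                    weights=weights)
    nchisq = normalized_chi_square(sse, n, config.m_control)
    points = np.column_stack([np.concatenate([z, 2.0 * z]),
                              np.concatenate([b1, b2])])
    return StitchResult(z, curve, nchisq, points, converged=best_ok,
                        restarts_used=used)
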