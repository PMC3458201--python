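"""Arterial plasma input-function modelling.

After an intravenous bolus the plasma concentration of the tracer falls in
two phases: a fast distribution (alpha) phase and a slower elimination
(beta) phase.  The input function is therefore modelled as a biexponential

    C_p(t) = A * [ f * exp(-l1 t) + (1 - f) * exp(-l2 t) ],   l_i = ln2 / t_half_i

with ``f`` the amplitude fraction of the fast phase.  Total plasma activity
is used directly, without metabolite correction.  For sampled plasma curves
interpolation is piecewise linear with zero activity assumed before the
first sample; the fitted biexponential provides the closed-form running
integral needed by the graphical analyses and the convolution kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .tac import TimeActivityCurve

__all__ = [
    "BiexpParams",
    "BiexpFitResult",
    "BiexponentialInput",
    "MonoexpFitResult",
    "fit_biexponential",
    "fit_monoexponential",
    "evaluate_input",
    "integrate_input",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class BiexpParams:
    """Parameters of a two-phase (biexponential) plasma clearance.

    ``frac_fast`` is the fraction of the t=0 amplitude in the fast phase,
    ``t_half_fast`` / ``t_half_slow`` the half-clearance times in minutes,
    and ``amplitude`` the concentration at t=0 in kBq/ml.
    """

    amplitude: float
    frac_fast: float
    t_half_fast: float
    t_half_slow: float

    def __post_init__(self):
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must be in [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.t_half_fast <= 0 or self.t_half_slow <= 0:
            raise ValueError("half-times must be > 0")
        if self.t_half_fast >= self.t_half_slow:
            raise ValueError("t_half_fast must be < t_half_slow")

    @property
    def lambda_fast(self) -> float:
        return LN2 / self.t_half_fast

    @property
    def lambda_slow(self) -> float:
        return LN2 / self.t_half_slow

    def exponential_terms(self):
        """Amplitude/decay-rate pairs [(A_i, lambda_i)] of the two phases."""
        return [
            (self.amplitude * self.frac_fast, self.lambda_fast),
            (self.amplitude * (1.0 - self.frac_fast), self.lambda_slow),
        ]

    def to_dict(self) -> dict:
        return {
            "amplitude_kBq_ml": self.amplitude,
            "frac_fast": self.frac_fast,
            "t_half_fast_min": self.t_half_fast,
            "t_half_slow_min": self.t_half_slow,
        }


@dataclass(frozen=True)
class BiexpFitResult:
    params: BiexpParams
    rss: float
    n_points: int
    converged: bool

    def to_dict(self) -> dict:
        return {**self.params.to_dict(), "rss": self.rss}


def evaluate_input(params: BiexpParams, t) -> np.ndarray:
    """Evaluate the biexponential input at times ``t`` (minutes, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    out = np.zeros_like(t, dtype=float)
    for amp, lam in params.exponential_terms():
        out += amp * np.exp(-lam * t)
    return out


def integrate_input(source, t) -> np.ndarray:
    """Running integral of the plasma concentration, in kBq*min/ml.

    ``source`` may be fitted :class:`BiexpParams` (closed form) or a sampled
    :class:`TimeActivityCurve` (trapezoid with linear interpolation and zero
    activity assumed before the first sample).  For a sampled curve, times
    beyond the last sample raise an error: no extrapolation policy exists.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("negative time")
    if isinstance(source, BiexpParams):
        out = np.zeros_like(t, dtype=float)
        for amp, lam in source.exponential_terms():
            out += amp * (1.0 - np.exp(-lam * t)) / lam
    elif isinstance(source, TimeActivityCurve):
        if np.any(t > source.times[-1] * (1 + 1e-12)):
            raise ValueError(
                f"time beyond last plasma sample ({source.times[-1]:g} min); "
                "no extrapolation policy"
            )
        grid = np.concatenate([[0.0], source.times]) if source.times[0] > 0 else source.times
        vals = np.concatenate([[0.0], source.values]) if source.times[0] > 0 else source.values
        from scipy.integrate import cumulative_trapezoid

        cumint = np.concatenate([[0.0], cumulative_trapezoid(vals, grid)])
        out = np.interp(t, grid, cumint)
        # correct the interior of a trapezoid panel: cumulative integral is
        # quadratic between samples, np.interp is linear; refine analytically
        idx = np.searchsorted(grid, t, side="right") - 1
        idx = np.clip(idx, 0, grid.size - 2)
        t0, t1 = grid[idx], grid[idx + 1]
        v0, v1 = vals[idx], vals[idx + 1]
        dt = t - t0
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(t1 > t0, (v1 - v0) / (t1 - t0), 0.0)
        out = cumint[idx] + v0 * dt + 0.5 * slope * dt**2
    else:
        raise TypeError("source must be BiexpParams or TimeActivityCurve")
    return float(out[0]) if scalar else out


def _biexp_model(theta, t):
    amp, frac, lam1, lam2 = theta
    return amp * (frac * np.exp(-lam1 * t) + (1 - frac) * np.exp(-lam2 * t))


def _peeling_init(t, y):
    """Exponential-peeling starting values: log-linear fit of the tail gives
    the slow phase, a log-linear fit of the peeled residual the fast phase."""
    n_tail = max(3, t.size // 2)
    tt, yt = t[-n_tail:], np.maximum(y[-n_tail:], 1e-12)
    slope, inter = np.polyfit(tt, np.log(yt), 1)
    lam2 = max(-slope, 1e-4)
    a2 = np.exp(inter)
    resid = y - a2 * np.exp(-lam2 * t)
    head = resid[: max(3, t.size // 3)]
    th = t[: max(3, t.size // 3)]
    pos = head > 0
    if pos.sum() >= 2:
        s1, i1 = np.polyfit(th[pos], np.log(head[pos]), 1)
        lam1 = max(-s1, lam2 * 3)
        a1 = max(np.exp(i1), 1e-12)
    else:
        lam1, a1 = lam2 * 10, max(y[0] - a2, 1e-12)
    amp = a1 + a2
    frac = np.clip(a1 / amp, 1e-6, 1 - 1e-6)
    return np.array([amp, frac, lam1, lam2])


def fit_biexponential(
    plasma: TimeActivityCurve, init: BiexpParams | None = None
) -> BiexpFitResult:
    """Fit a biexponential clearance model to a sampled plasma curve.

    Requires at least 5 samples spanning both phases.  The result is
    reported with phases ordered by half-time (fast first) regardless of
    optimizer ordering.  Non-convergence raises with diagnostics.
    """
    t, y = plasma.times, plasma.values
    if t.size < 5:
        raise ValueError(f"need >= 5 plasma samples, got {t.size}")
    if init is not None:
        theta0 = np.array(
            [init.amplitude, init.frac_fast, init.lambda_fast, init.lambda_slow]
        )
    else:
        theta0 = _peeling_init(t, y)
    scale = max(y.max(), 1e-12)
    lower = np.array([1e-9 * scale, 0.0, 1e-6, 1e-6])
    upper = np.array([1e6 * scale, 1.0, 1e4, 1e4])
    theta0 = np.clip(theta0, lower, upper)
    sol = least_squares(
        lambda th: _biexp_model(th, t) - y,
        theta0,
        bounds=(lower, upper),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=5000,
    )
    if not sol.success:
        raise RuntimeError(f"biexponential fit failed to converge: {sol.message}")
    amp, frac, lam1, lam2 = sol.x
    if lam1 < lam2:  # enforce fast-phase-first ordering
        lam1, lam2 = lam2, lam1
        frac = 1.0 - frac
    lam1 = max(lam1, lam2 * (1 + 1e-9))  # keep half-times strictly ordered
    params = BiexpParams(
        amplitude=amp, frac_fast=frac, t_half_fast=LN2 / lam1, t_half_slow=LN2 / lam2
    )
    rss = float(np.sum(sol.fun**2))
    return BiexpFitResult(params=params, rss=rss, n_points=t.size, converged=True)


class BiexponentialInput(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the biexponential plasma model.

    ``fit(X, y)`` takes sample times (minutes, shape (n,) or (n, 1)) and
    plasma concentrations; ``predict(X)`` evaluates the fitted clearance.

    Attributes (after fit): ``params_``, ``amplitude_``, ``frac_fast_``,
    ``t_half_fast_``, ``t_half_slow_``, ``rss_``.
    """

    def __init__(self, init: BiexpParams | None = None):
        self.init = init

    @staticmethod
    def _times(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-D array of times or column vector")
        return X

    def fit(self, X, y):
        t = self._times(X)
        curve = TimeActivityCurve(t, np.asarray(y, dtype=float), label="plasma")
        res = fit_biexponential(curve, init=self.init)
        self.params_ = res.params
        self.amplitude_ = res.params.amplitude
        self.frac_fast_ = res.params.frac_fast
        self.t_half_fast_ = res.params.t_half_fast
        self.t_half_slow_ = res.params.t_half_slow
        self.rss_ = res.rss
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return evaluate_input(self.params_, self._times(X))


@dataclass(frozen=True)
class MonoexpFitResult:
    amplitude: float
    t_half: float
    rss: float
    n_points: int


def fit_monoexponential(
    curve: TimeActivityCurve, start_from_peak: bool = True
) -> MonoexpFitResult:
    """Fit a single-phase washout A*exp(-l t) to a tissue curve.

    With ``start_from_peak`` only samples at and after the curve maximum are
    used, which is how a one-phase clearance half-time of a lesion curve is
    summarised.
    """
    t, y = curve.times, curve.values
    if start_from_peak:
        k = int(np.argmax(y))
        t, y = t[k:], y[k:]
    if t.size < 3:
        raise ValueError("need >= 3 post-peak samples for a mono-exponential fit")
    pos = y > 0
    if pos.sum() < 3:
        raise ValueError("curve has too few positive samples")
    slope, inter = np.polyfit(t[pos], np.log(y[pos]), 1)
    theta0 = np.array([np.exp(inter), max(-slope, 1e-6)])
    sol = least_squares(
        lambda th: th[0] * np.exp(-th[1] * t) - y,
        theta0,
        bounds=([1e-12, 1e-9], [np.inf, 1e4]),
        xtol=1e-14,
        ftol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"mono-exponential fit failed: {sol.message}")
    amp, lam = sol.x
    return MonoexpFitResult(
        amplitude=float(amp),
        t_half=float(LN2 / lam),
        rss=float(np.sum(sol.fun**2)),
        n_points=int(t.size),
    )
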