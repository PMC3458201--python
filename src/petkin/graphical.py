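"""Logan and Patlak graphical analyses.

Both methods linearise a tissue curve against the plasma input past a delay
time t*, then fit an ordinary least-squares line.  For a reversible tracer
the Logan plot

    y = int_0^t C_t ds / C_t(t)   vs   x = int_0^t C_p ds / C_t(t)

becomes linear with slope equal to the total distribution volume Vd.  For
an irreversible tracer the Patlak plot

    y = C_t(t) / C_p(t)           vs   x = int_0^t C_p ds / C_p(t)

becomes linear with slope equal to the net influx constant Ki.  Samples at
exactly t* are included (closed interval).  Running integrals use the
trapezoid rule on the sample grid with zero activity assumed before the
first sample; when the input is a fitted biexponential its integral is
evaluated in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .input_function import BiexpParams, evaluate_input, integrate_input
from .tac import TimeActivityCurve

__all__ = [
    "GraphicalResult",
    "LoganPlot",
    "PatlakPlot",
    "logan_analysis",
    "patlak_analysis",
    "choose_t_star",
]


@dataclass(frozen=True)
class GraphicalResult:
    """Linear fit of a graphical transform past the delay time t*.

    ``slope`` is Vd (unitless) for Logan and Ki (ml cm^-3 min^-1) for
    Patlak.  ``r_squared`` is the coefficient of determination of the
    transformed points.
    """

    method: str  # "Logan" | "Patlak"
    slope: float
    intercept: float
    r_squared: float
    t_star: float
    n_points_used: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "t_star_min": self.t_star,
            "n_points": self.n_points_used,
        }


def _input_on_grid(input_function, times):
    """Plasma concentration and its running integral at the tissue times."""
    if isinstance(input_function, BiexpParams):
        cp = evaluate_input(input_function, times)
        icp = integrate_input(input_function, times)
    elif isinstance(input_function, TimeActivityCurve):
        t_in, v_in = input_function.times, input_function.values
        if times[-1] > t_in[-1] * (1 + 1e-12):
            raise ValueError("tissue times extend beyond the sampled input")
        cp = np.interp(times, t_in, v_in, left=0.0)
        icp = integrate_input(input_function, times)
    else:
        raise TypeError("input must be BiexpParams or TimeActivityCurve")
    return cp, icp


def _cumint(curve: TimeActivityCurve):
    """Trapezoid running integral of a sampled curve, zero before t0."""
    t, v = curve.times, curve.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
        return cumulative_trapezoid(v, t)
    return np.concatenate([[0.0], cumulative_trapezoid(v, t)])


def _ols(x, y, method, t_star, n):
    fit = linregress(x, y)
    return GraphicalResult(
        method=method,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        t_star=float(t_star),
        n_points_used=int(n),
    )


def logan_analysis(
    tissue: TimeActivityCurve, input_function, t_star: float = 3.0
) -> GraphicalResult:
    """Logan graphical analysis; the slope estimates Vd.

    The default 3-min delay is the point past which the plot of a
    reversibly bound tracer is effectively linear.
    """
    t = tissue.times
    keep = t >= t_star
    if keep.sum() < 3:
        raise ValueError(f"fewer than 3 samples at or past t*={t_star:g} min")
    if np.any(tissue.values[keep] <= 0):
        raise ValueError("zero tissue activity inside the Logan fit window")
    ict = _cumint(tissue)
    cp, icp = _input_on_grid(input_function, t)
    y = ict[keep] / tissue.values[keep]
    x = icp[keep] / tissue.values[keep]
    return _ols(x, y, "Logan", t_star, keep.sum())


def patlak_analysis(
    tissue: TimeActivityCurve, input_function, t_star: float = 15.0
) -> GraphicalResult:
    """Patlak graphical analysis; the slope estimates the influx constant Ki.

    A longer default delay (15 min) is needed because the transform only
    linearises once the reversible compartments have equilibrated.
    """
    t = tissue.times
    keep = t >= t_star
    if keep.sum() < 3:
        raise ValueError(f"fewer than 3 samples at or past t*={t_star:g} min")
    cp, icp = _input_on_grid(input_function, t)
    if np.any(cp[keep] <= 0):
        raise ValueError("zero plasma activity inside the Patlak fit window")
    y = tissue.values[keep] / cp[keep]
    x = icp[keep] / cp[keep]
    return _ols(x, y, "Patlak", t_star, keep.sum())


def choose_t_star(
    tissue: TimeActivityCurve,
    input_function,
    method: str = "Logan",
    max_rel_residual: float = 0.10,
) -> float:
    """Smallest sample time past which the graphical fit is linear.

    Scans candidate delays over the sample times and returns the first one
    whose post-t* linear fit has a maximum relative residual below
    ``max_rel_residual``.  The residual is scaled by the span of the
    transformed ordinate (a scale-free measure that stays defined where the
    ordinate crosses zero).  Raises when no delay qualifies, reporting the
    best residual seen.
    """
    analyse = {"Logan": logan_analysis, "Patlak": patlak_analysis}.get(method)
    if analyse is None:
        raise ValueError("method must be 'Logan' or 'Patlak'")
    best = np.inf
    for t_star in tissue.times[:-2]:
        try:
            res = analyse(tissue, input_function, t_star=float(t_star))
        except ValueError:
            continue
        keep = tissue.times >= t_star
        ict = _cumint(tissue)
        cp, icp = _input_on_grid(input_function, tissue.times)
        if method == "Logan":
            y = ict[keep] / tissue.values[keep]
            x = icp[keep] / tissue.values[keep]
        else:
            y = tissue.values[keep] / cp[keep]
            x = icp[keep] / cp[keep]
        fitted = res.slope * x + res.intercept
        span = max(np.ptp(y), 1e-300)
        rel = np.max(np.abs(y - fitted)) / span
        best = min(best, rel)
        if rel < max_rel_residual:
            return float(t_star)
    raise ValueError(
        f"no t* satisfies max relative residual < {max_rel_residual:g} "
        f"(best achieved: {best:.3g})"
    )


class _GraphicalEstimator(BaseEstimator):
    """Common sklearn-style wrapper for the graphical transforms."""

    _method = ""

    def __init__(self, input_function=None, t_star=None):
        self.input_function = input_function
        self.t_star = t_star

    def fit(self, X, y):
        if self.input_function is None:
            raise ValueError("input_function must be provided")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        curve = TimeActivityCurve(t, np.asarray(y, dtype=float))
        analyse = logan_analysis if self._method == "Logan" else patlak_analysis
        kwargs = {} if self.t_star is None else {"t_star": self.t_star}
        res = analyse(curve, self.input_function, **kwargs)
        self.result_ = res
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.r_squared_ = res.r_squared
        self.n_features_in_ = 1
        return self


class LoganPlot(_GraphicalEstimator):
    """Logan graphical analysis as an estimator; ``slope_`` is Vd."""

    _method = "Logan"


class PatlakPlot(_GraphicalEstimator):
    """Patlak graphical analysis as an estimator; ``slope_`` is Ki."""

    _method = "Patlak"
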