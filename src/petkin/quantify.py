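"""SUV, cohort regression, and limit-of-detection statistics.

The standardized uptake value normalises a tissue concentration by the
injected dose per unit body weight:

    SUV = C_tissue (MBq/g) / [dose (MBq) / weight (g)]

Cohort-level correlations between a PET measure (SUV, Vd, BP) and the
number of CD25-positive cells in the lesion are simple linear regressions;
a correlation is flagged significant when R^2 > 0.5 and p < 0.05, with the
p-value from the regression F-test (equivalent to the slope t-test in
simple regression).

The limit of detection of the tracer is the mean binding potential in
control (uninflamed) tissue plus two sample standard deviations — the 95%
confidence bound against background variability — converted to a minimum
detectable cell number by inverting the BP-versus-cells regression line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "LodResult",
    "suv",
    "linear_regression",
    "limit_of_detection",
    "round_sig",
]


def suv(tissue_conc: float, dose: float, weight: float) -> float:
    """Standardized uptake value (unitless).

    ``tissue_conc`` in MBq/g, ``dose`` in MBq, ``weight`` in g.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if tissue_conc < 0:
        raise ValueError("tissue concentration must be >= 0")
    return tissue_conc / (dose / weight)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        """R^2 > 0.5 and p < 0.05."""
        return self.r_squared > 0.5 and self.p_value < 0.05

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "significant": self.significant,
        }


def linear_regression(x, y) -> RegressionResult:
    """OLS regression of a PET measure on cell count (x in 10^6 cells)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x (all values equal)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    # a numerically perfect fit can leave f_pvalue as nan; the F statistic
    # diverges, so the p-value is 0 to double precision
    p = float(model.f_pvalue)
    if not np.isfinite(p):
        p = 0.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=r2,
        p_value=p,
        n=int(x.size),
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class LodResult:
    """Limit of detection derived from control-tissue binding potentials.

    ``min_detectable_cells`` is in absolute cells (not 10^6), rounded to
    two significant figures for reporting; ``min_detectable_cells_exact``
    keeps full precision.
    """

    control_mean_bp: float
    control_sd_bp: float
    lod_bp: float
    min_detectable_cells: float
    min_detectable_cells_exact: float
    n_controls: int
    multiplier: float = 2.0

    def to_dict(self) -> dict:
        return {
            "control_mean_bp": self.control_mean_bp,
            "control_sd_bp": self.control_sd_bp,
            "lod_bp": self.lod_bp,
            "min_detectable_cells": self.min_detectable_cells,
            "n_controls": self.n_controls,
            "multiplier": self.multiplier,
        }


def limit_of_detection(
    control_bps, regression: RegressionResult, multiplier: float = 2.0
) -> LodResult:
    """LOD = mean control BP + ``multiplier`` * sample SD (n-1 denominator),
    inverted through the BP-versus-cells regression to a cell number.

    ``regression`` must have a positive slope (BP increasing with cells),
    otherwise the LOD cannot be inverted.
    """
    bps = np.asarray(control_bps, dtype=float)
    if bps.size < 2:
        raise ValueError("need at least 2 control BP values")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if regression.slope <= 0:
        raise ValueError("regression slope must be > 0 to invert the LOD")
    mean = float(np.mean(bps))
    sd = float(np.std(bps, ddof=1))
    lod_bp = mean + multiplier * sd
    cells_1e6 = (lod_bp - regression.intercept) / regression.slope
    cells = cells_1e6 * 1e6
    return LodResult(
        control_mean_bp=mean,
        control_sd_bp=sd,
        lod_bp=lod_bp,
        min_detectable_cells=round_sig(cells, 2),
        min_detectable_cells_exact=float(cells),
        n_controls=int(bps.size),
        multiplier=float(multiplier),
    )
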