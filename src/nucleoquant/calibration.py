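"""Weighted-least-squares calibration for LC-MS/MS quantitation.

A calibration line relates the nominal analyte concentration (µM) to the
relative response (quantifier peak area divided by the internal-standard
area).  Because chromatographic noise grows with signal, the fit is
weighted by ``1/x`` (nominal concentration) or ``1/y`` (observed
response), with weights normalized to mean one so that estimates and
their reported standard errors keep the units of the unweighted problem.

Sensitivity follows the standard convention based on the fitted slope
``b`` and the standard deviation of the intercept ``s_a``::

    LOD = 3.3 * s_a / b        LOQ = 10 * s_a / b

Confidence intervals use the two-sided t distribution with n - 2 degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, InsufficientDataError, SingularDesignError, WeightingError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "WeightedLinearCalibration",
    "fit_weighted_line",
    "compute_lod_loq",
    "back_calculate",
    "BackCalculated",
    "WEIGHTINGS",
]

WEIGHTINGS = ("none", "1/x", "1/y")

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: nominal concentration and relative response."""

    nominal_conc: float
    relative_response: float

    def __post_init__(self):
        if not self.nominal_conc > 0:
            raise ValueError("nominal concentration must be positive")
        if self.relative_response < 0:
            raise ValueError("relative response must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted calibration parameters and diagnostics for one analyte."""

    analyte_code: str
    weighting: str
    slope: float
    intercept: float
    sd_slope: float
    sd_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    correlation_r: float
    residual_sd_sxy: float
    n_points: int
    linear_range: tuple[float, float]
    lod_uM: float = float("nan")
    loq_uM: float = float("nan")

    def with_lod_loq(self) -> "CalibrationCurve":
        """Return a copy with LOD/LOQ filled from the fitted parameters."""
        lod, loq = compute_lod_loq(self.slope, self.sd_intercept)
        return replace(self, lod_uM=lod, loq_uM=loq)


def compute_lod_loq(slope: float, sd_intercept: float) -> tuple[float, float]:
    """Limit of detection and quantification from the calibration line.

    ``LOD = 3.3 * sd_intercept / slope`` and ``LOQ = 10 * sd_intercept /
    slope``, in the concentration units of the calibration (µM here).
    """
    if not slope > 0:
        raise DomainError("slope must be positive to derive LOD/LOQ")
    if sd_intercept < 0:
        raise DomainError("intercept SD must be non-negative")
    return LOD_MULTIPLIER * sd_intercept / slope, LOQ_MULTIPLIER * sd_intercept / slope


def _weights(kind: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if kind == "none":
        w = np.ones_like(x)
    elif kind == "1/x":
        w = 1.0 / x
    elif kind == "1/y":
        if np.any(y <= 0):
            raise WeightingError("1/y weighting requires strictly positive responses")
        w = 1.0 / y
    else:
        raise ValueError(f"unknown weighting {kind!r}; expected one of {WEIGHTINGS}")
    return w / w.mean()  # dimensionless weights, mean one


class WeightedLinearCalibration(RegressorMixin, BaseEstimator):
    """Weighted straight-line calibration estimator.

    Parameters
    ----------
    weighting : {"none", "1/x", "1/y"}, default="none"
        Weighting factor of the regression.  ``1/y`` uses the observed
        responses (single pass, no IRLS refinement), matching common
        chromatography-software behavior.

    Attributes
    ----------
    slope_, intercept_ : float
        Weighted-least-squares estimates.
    sd_slope_, sd_intercept_ : float
        Their standard errors.
    ci95_slope_, ci95_intercept_ : tuple of float
        Two-sided 95% confidence intervals (t, n - 2 df).
    correlation_r_ : float
        Weighted Pearson correlation between concentration and response.
    residual_sd_sxy_ : float
        sqrt(weighted SSE / (n - 2)).
    lod_uM_, loq_uM_ : float
        Detection and quantification limits from the fitted parameters.
    linear_range_ : tuple of float
        (min, max) of the calibration concentrations.
    """

    def __init__(self, weighting: str = "none"):
        self.weighting = weighting

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(x).size < 3:
            raise InsufficientDataError("calibration needs at least 3 distinct concentrations")
        if np.ptp(x) == 0:
            raise SingularDesignError("all calibration concentrations are identical")
        w = _weights(self.weighting, x, y)

        design = sm.add_constant(x)
        res = sm.WLS(y, design, weights=w).fit()
        n = x.size
        intercept, slope = res.params
        sd_intercept, sd_slope = res.bse
        tcrit = stats.t.ppf(0.975, n - 2)

        resid = y - (intercept + slope * x)
        sse_w = float(np.sum(w * resid**2))

        xm, ym = np.average(x, weights=w), np.average(y, weights=w)
        sxx = np.sum(w * (x - xm) ** 2)
        syy = np.sum(w * (y - ym) ** 2)
        sxy_cov = np.sum(w * (x - xm) * (y - ym))
        r = float(sxy_cov / np.sqrt(sxx * syy)) if sxx > 0 and syy > 0 else float("nan")

        self.n_points_ = n
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.sd_slope_ = float(sd_slope)
        self.sd_intercept_ = float(sd_intercept)
        self.ci95_slope_ = (float(slope - tcrit * sd_slope), float(slope + tcrit * sd_slope))
        self.ci95_intercept_ = (
            float(intercept - tcrit * sd_intercept),
            float(intercept + tcrit * sd_intercept),
        )
        self.correlation_r_ = r
        self.residual_sd_sxy_ = float(np.sqrt(sse_w / (n - 2)))
        self.linear_range_ = (float(x.min()), float(x.max()))
        if self.slope_ > 0:
            self.lod_uM_, self.loq_uM_ = compute_lod_loq(self.slope_, self.sd_intercept_)
        else:  # a non-positive slope has no meaningful sensitivity limits
            self.lod_uM_ = self.loq_uM_ = float("nan")
        return self

    def predict(self, X):
        """Predicted relative response at concentrations ``X``."""
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def inverse(self, responses):
        """Back-calculated concentrations for observed relative responses."""
        r = np.asarray(responses, dtype=float)
        if self.slope_ == 0:
            raise DomainError("cannot back-calculate with a zero slope")
        return (r - self.intercept_) / self.slope_

    def to_curve(self, analyte_code: str = "") -> CalibrationCurve:
        """Export the fitted state as a :class:`CalibrationCurve` record."""
        return CalibrationCurve(
            analyte_code=analyte_code,
            weighting=self.weighting,
            slope=self.slope_,
            intercept=self.intercept_,
            sd_slope=self.sd_slope_,
            sd_intercept=self.sd_intercept_,
            ci95_slope=self.ci95_slope_,
            ci95_intercept=self.ci95_intercept_,
            correlation_r=self.correlation_r_,
            residual_sd_sxy=self.residual_sd_sxy_,
            n_points=self.n_points_,
            linear_range=self.linear_range_,
            lod_uM=self.lod_uM_,
            loq_uM=self.loq_uM_,
        )


def fit_weighted_line(points, weighting: str = "none", analyte_code: str = "") -> CalibrationCurve:
    """Fit a weighted calibration line through ``points``.

    ``points`` is a sequence of :class:`CalibrationPoint` or (nominal,
    response) pairs; calibration replicates enter as separate points.
    """
    pts = [p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points]
    if len(pts) < 3:
        raise InsufficientDataError("calibration needs at least 3 points")
    x = np.array([p.nominal_conc for p in pts])
    y = np.array([p.relative_response for p in pts])
    est = WeightedLinearCalibration(weighting=weighting).fit(x, y)
    return est.to_curve(analyte_code)


@dataclass(frozen=True)
class BackCalculated:
    """A back-calculated concentration with its quantitation flags."""

    conc_uM: float
    flags: frozenset

    @property
    def below_lod(self) -> bool:
        return "below_lod" in self.flags

    @property
    def below_loq(self) -> bool:
        return "below_loq" in self.flags

    @property
    def above_range(self) -> bool:
        return "above_range" in self.flags


def back_calculate(response: float, curve: CalibrationCurve) -> BackCalculated:
    """Invert the calibration: concentration for an observed response.

    The result is never censored; instead it carries ``below_lod`` /
    ``below_loq`` / ``above_range`` flags relative to the curve's limits.
    """
    if curve.slope == 0:
        raise DomainError("cannot back-calculate with a zero slope")
    conc = (response - curve.intercept) / curve.slope
    flags = set()
    if np.isfinite(curve.loq_uM) and conc < curve.loq_uM:
        flags.add("below_loq")
    if np.isfinite(curve.lod_uM) and conc < curve.lod_uM:
        flags.add("below_lod")
    if conc > curve.linear_range[1]:
        flags.add("above_range")
    return BackCalculated(conc_uM=float(conc), flags=frozenset(flags))
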