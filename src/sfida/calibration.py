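"""Pixel-count → molar-concentration calibration and limit of detection.

Calibration uses a dilution series of Aβ-epitope-coated silica nanoparticle
(SiNaP) standards, a countable size-defined mimic of an aggregate. A
standard concentration enters the curve only if (a) its replicate pixel
counts differ significantly from the blank control (one-sided Mann–Whitney
U, standard > BC, alpha = 0.05) and (b) it lies within the linear range.
The curve itself is a weighted least-squares line of mean pixel count on
nominal concentration with weights 1/readout (1/ȳ per point), so the large
readouts at the top of the series do not dominate the fit.

The limit of detection follows the blank-plus-two-sigma convention:
LoD(pixel) = mean(BC) + 2·SD(BC) over the blank-control well readouts
(nominally 24 replicates), converted to femtomolar through the curve
inverse.

"Within linear range" is resolved algorithmically: starting from all
significant points, the highest concentration is dropped while its relative
residual from a refit on the remaining points exceeds 20% — this captures
the saturation roll-off at the top of a dilution series without touching
the linear portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._stats import mann_whitney
from .errors import CalibrationError, DataError, ParameterError
from .images import SampleReadout

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "LodEstimate",
    "CalibratedValue",
    "SinapCalibration",
    "select_calibration_points",
    "fit_calibration",
    "pixel_to_concentration",
    "compute_lod",
]


@dataclass
class CalibrationPoint:
    """One standard concentration with its replicate readouts and verdicts."""

    nominal_concentration_fM: float
    replicate_counts: list[float]
    mean_readout: float = field(init=False)
    inclusion_pvalue: float = float("nan")
    significant: bool = False
    in_linear_range: bool = False

    def __post_init__(self) -> None:
        self.replicate_counts = [float(c) for c in self.replicate_counts]
        self.mean_readout = float(np.mean(self.replicate_counts))

    @property
    def included(self) -> bool:
        return self.significant and self.in_linear_range


@dataclass
class CalibrationCurve:
    """Weighted linear pixel-count ↔ concentration relation."""

    slope: float  # pixel count per fM
    intercept: float  # pixel count
    r_squared: float
    alpha: float
    points: list[CalibrationPoint]

    @property
    def n_included(self) -> int:
        return sum(p.included for p in self.points)

    @property
    def valid(self) -> bool:
        return self.slope > 0 and self.n_included >= 2

    def predict(self, concentration_fM):
        """Expected pixel count at a concentration."""
        return self.intercept + self.slope * np.asarray(concentration_fM, dtype=float)

    def inverse(self, pixel_count):
        """Unclamped concentration (may be negative below the intercept)."""
        if self.slope <= 0:
            raise CalibrationError("curve slope must be positive for inversion")
        return (np.asarray(pixel_count, dtype=float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "alpha": self.alpha,
            "points": [
                {
                    "nominal_concentration_fM": p.nominal_concentration_fM,
                    "replicate_counts": p.replicate_counts,
                    "inclusion_pvalue": p.inclusion_pvalue,
                    "significant": p.significant,
                    "in_linear_range": p.in_linear_range,
                    "included": p.included,
                }
                for p in self.points
            ],
        }


@dataclass
class LodEstimate:
    """Blank + 2·SD limit of detection, in pixel counts and femtomolar."""

    bc_mean_pixel_count: float
    bc_sd: float
    n_bc_replicates: int
    lod_pixel: float
    lod_fM: float


@dataclass
class CalibratedValue:
    """A calibrated concentration; negative inversions are clamped to zero
    and flagged ``below_blank``."""

    concentration_fM: float
    below_blank: bool


def _point_inputs(
    standards: Sequence,
) -> list[CalibrationPoint]:
    points = []
    for s in standards:
        if isinstance(s, CalibrationPoint):
            points.append(s)
        else:
            conc, counts = s
            if isinstance(counts, SampleReadout):
                counts = counts.replicate_pixel_counts
            points.append(CalibrationPoint(float(conc), list(counts)))
    concs = [p.nominal_concentration_fM for p in points]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ParameterError("standards must be sorted by strictly increasing concentration")
    return points


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares used inside linear-range trimming."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise CalibrationError("singular design: all concentrations equal")
    slope = float((w * (x - xm) * (y - ym)).sum() / sxx)
    return slope, float(ym - slope * xm)


def select_calibration_points(
    standards: Sequence,
    bc_replicates: Sequence[float],
    alpha: float = 0.05,
    max_rel_residual: float = 0.2,
) -> list[CalibrationPoint]:
    """Apply the two inclusion criteria to a standard series.

    ``standards`` is a sequence of ``CalibrationPoint`` or ``(concentration,
    replicate_counts)`` pairs sorted by increasing concentration;
    ``bc_replicates`` are the blank-control well pixel counts (>= 4).

    Significance: one-sided Mann–Whitney U (standard > BC) at ``alpha``.
    Linear range: iteratively drop the highest significant concentration
    while its relative residual from a line refit on the remaining points
    exceeds ``max_rel_residual``.
    """
    bc = np.asarray(bc_replicates, dtype=float)
    if len(bc) < 4:
        raise DataError("need at least 4 blank-control replicate readouts")
    points = _point_inputs(standards)
    for p in points:
        _, pval, _ = mann_whitney(p.replicate_counts, bc, alternative="greater")
        p.inclusion_pvalue = pval
        p.significant = pval < alpha
        p.in_linear_range = False
    sig = [p for p in points if p.significant]
    if not sig:
        raise CalibrationError("no standard differs significantly from the blank control")
    keep = list(sig)  # sorted ascending by construction
    while len(keep) >= 3:
        lower = keep[:-1]
        x = np.array([p.nominal_concentration_fM for p in lower])
        y = np.array([p.mean_readout for p in lower])
        if np.any(y <= 0):
            break
        slope, intercept = _wls_line(x, y, 1.0 / y)
        top = keep[-1]
        pred = intercept + slope * top.nominal_concentration_fM
        if pred <= 0:
            break
        if abs(top.mean_readout - pred) / pred > max_rel_residual:
            keep = keep[:-1]
        else:
            break
    for p in keep:
        p.in_linear_range = True
    if not any(p.included for p in points):
        raise CalibrationError("all calibration points excluded")
    return points


def fit_calibration(points: Sequence[CalibrationPoint], alpha: float = 0.05) -> CalibrationCurve:
    """Weighted least-squares line through the included points.

    Weights are 1/readout (the observed mean pixel count per point); points
    with a non-positive mean readout are unweightable and are dropped.
    """
    import statsmodels.api as sm

    points = list(points)
    usable = [p for p in points if p.included and p.mean_readout > 0]
    if len(usable) < 2:
        raise CalibrationError("need at least 2 included points with positive readouts")
    x = np.array([p.nominal_concentration_fM for p in usable])
    y = np.array([p.mean_readout for p in usable])
    if np.all(x == x[0]):
        raise CalibrationError("singular design: all concentrations equal")
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / y).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rsquared),
        alpha=alpha,
        points=points,
    )


def pixel_to_concentration(pixel_count, curve: CalibrationCurve):
    """Convert pixel counts to femtomolar via the curve inverse.

    Values inverting below zero are clamped to 0 fM and flagged. Returns a
    :class:`CalibratedValue` for scalar input, or ``(values, below_blank)``
    arrays for array input.
    """
    raw = curve.inverse(pixel_count)
    below = raw < 0
    clamped = np.where(below, 0.0, raw)
    if np.ndim(raw) == 0:
        return CalibratedValue(float(clamped), bool(below))
    return clamped, below


def compute_lod(
    bc_readouts: Sequence[float], curve: CalibrationCurve | None = None
) -> LodEstimate:
    """Limit of detection: BC mean + 2·sample SD of the blank-control well
    readouts (nominally 24), calibrated to fM when a curve is given."""
    bc = np.asarray(bc_readouts, dtype=float)
    if len(bc) < 2:
        raise DataError("need at least 2 blank-control readouts for an SD")
    mean = float(bc.mean())
    sd = float(bc.std(ddof=1))
    lod_pixel = mean + 2.0 * sd
    lod_fM = float("nan")
    if curve is not None:
        lod_fM = max(0.0, float(curve.inverse(lod_pixel)))
    return LodEstimate(
        bc_mean_pixel_count=mean,
        bc_sd=sd,
        n_bc_replicates=len(bc),
        lod_pixel=lod_pixel,
        lod_fM=lod_fM,
    )


class SinapCalibration(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper binding point selection, the weighted fit, and
    the LoD into one estimator.

    ``fit(X, y)`` takes nominal concentrations ``X`` (n_points,) and the
    per-point replicate readout lists ``y``; blank-control replicates are
    passed as ``bc_replicates``. ``predict`` maps concentrations to expected
    pixel counts, ``inverse_transform`` maps pixel counts back to clamped
    concentrations.
    """

    def __init__(self, alpha: float = 0.05, max_rel_residual: float = 0.2):
        self.alpha = alpha
        self.max_rel_residual = max_rel_residual

    def fit(self, X, y, bc_replicates=None):
        if bc_replicates is None:
            raise ParameterError("bc_replicates (blank-control readouts) are required")
        concs = np.asarray(X, dtype=float).ravel()
        standards = list(zip(concs, y))
        self.points_ = select_calibration_points(
            standards, bc_replicates, alpha=self.alpha, max_rel_residual=self.max_rel_residual
        )
        curve = fit_calibration(self.points_, alpha=self.alpha)
        self.curve_ = curve
        self.slope_ = curve.slope
        self.intercept_ = curve.intercept
        self.r_squared_ = curve.r_squared
        self.lod_ = compute_lod(bc_replicates, curve) if len(bc_replicates) >= 2 else None
        return self

    def predict(self, X):
        return self.curve_.predict(np.asarray(X, dtype=float).ravel())

    def inverse_transform(self, pixel_counts):
        values, _ = pixel_to_concentration(np.asarray(pixel_counts, dtype=float), self.curve_)
        return values
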