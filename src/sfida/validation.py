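"""Analytical-validation metric suite.

Covers the metrics an assay validation campaign reports: percent signal
reduction of selectivity / immunodepletion controls, percent dilution
linearity against an 80–120% tolerance band, spike recovery, stability
under stress conditions against a ±25% tolerance band, and inter-assay
agreement by Spearman correlation (pass above rho = 0.9).

Tolerance bounds are inclusive: 75/125 and 80/120 pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import spearman
from .errors import DataError
from .images import SampleReadout

__all__ = [
    "ControlComparison",
    "DilutionLinearityResult",
    "RecoveryResult",
    "StabilityResult",
    "AgreementResult",
    "percent_signal_reduction",
    "dilution_linearity",
    "spike_recovery",
    "stability_check",
    "inter_assay_agreement",
]


def _mean(readout) -> float:
    if isinstance(readout, SampleReadout):
        return float(readout.mean)
    return float(readout)


@dataclass
class ControlComparison:
    remaining_percent: float
    signal_reduction_percent: float
    defined: bool = True


@dataclass
class DilutionLinearityResult:
    points: pd.DataFrame  # dilution_factor, readout, linearity_percent, within_tolerance
    mean_linearity: float
    mean_within_tolerance: bool
    tolerance: tuple[float, float]
    anchor_factor: float


@dataclass
class RecoveryResult:
    recovery_percent: float
    over_subtracted: bool  # negative net signal after blank/unspiked subtraction


@dataclass
class StabilityResult:
    condition: str
    normalized_percent: float
    within_tolerance: bool
    tolerance_percent: float


@dataclass
class AgreementResult:
    spearman_rho: float
    p_value: float
    n: int
    passed: bool
    defined: bool = True


def percent_signal_reduction(reference, control) -> ControlComparison:
    """Percent of the reference signal removed in a control condition.

    Used identically for selectivity controls (no capture antibody,
    no detection probe, off-target detection probe) and for
    immunodepletion effectivity versus the non-depleted sample.
    """
    ref = _mean(reference)
    ctl = _mean(control)
    if ref <= 0:
        return ControlComparison(float("nan"), float("nan"), defined=False)
    remaining = 100.0 * ctl / ref
    return ControlComparison(remaining, 100.0 - remaining)


def dilution_linearity(
    dilution_factors: Sequence[float],
    blank_corrected_readouts: Sequence[float],
    tolerance: tuple[float, float] = (80.0, 120.0),
) -> DilutionLinearityResult:
    """Percent dilution linearity of a blank-corrected dilution series.

    The anchor is the least-diluted point (smallest factor); linearity of
    point i is 100·(readout_i·factor_i/factor_0)/readout_0, i.e. the
    dilution-corrected readout relative to the anchor. The mean is taken
    over the non-anchor points. Pass requires the value inside the
    (inclusive) tolerance band.
    """
    factors = np.asarray(dilution_factors, dtype=float)
    readouts = np.asarray(blank_corrected_readouts, dtype=float)
    if factors.shape != readouts.shape or factors.ndim != 1 or len(factors) < 2:
        raise DataError("need >= 2 paired (factor, readout) points")
    if np.any(factors <= 0):
        raise DataError("dilution factors must be positive")
    if np.any(np.diff(factors) <= 0):
        raise DataError("dilution factors must be strictly increasing")
    if readouts[0] <= 0:
        raise DataError("anchor (least-diluted) blank-corrected readout must be positive")
    lo, hi = tolerance
    linearity = 100.0 * (readouts * factors / factors[0]) / readouts[0]
    within = (linearity >= lo) & (linearity <= hi)
    table = pd.DataFrame(
        {
            "dilution_factor": factors,
            "blank_corrected_readout": readouts,
            "linearity_percent": linearity,
            "within_tolerance": within,
        }
    )
    mean_lin = float(linearity[1:].mean())
    return DilutionLinearityResult(
        points=table,
        mean_linearity=mean_lin,
        mean_within_tolerance=bool(lo <= mean_lin <= hi),
        tolerance=(lo, hi),
        anchor_factor=float(factors[0]),
    )


def spike_recovery(measured_net: float, nominal_spike: float) -> RecoveryResult:
    """Percent recovery of a known spike: 100·(spiked − unspiked)/nominal.

    A negative net signal (over-subtraction) is reported as-is and flagged.
    """
    if nominal_spike <= 0:
        raise DataError("nominal spike concentration must be positive")
    recovery = 100.0 * measured_net / nominal_spike
    return RecoveryResult(recovery, over_subtracted=measured_net < 0)


def stability_check(
    baseline, condition, tolerance: float = 25.0, condition_label: str = ""
) -> StabilityResult:
    """Normalised signal of a stress condition (freeze-thaw cycle,
    transport temperature/time) as percent of baseline, with a ±tolerance
    verdict (inclusive bounds)."""
    base = _mean(baseline)
    if base <= 0:
        raise DataError("baseline readout must be positive")
    normalized = 100.0 * _mean(condition) / base
    within = (100.0 - tolerance) <= normalized <= (100.0 + tolerance)
    return StabilityResult(
        condition=condition_label,
        normalized_percent=normalized,
        within_tolerance=within,
        tolerance_percent=tolerance,
    )


def inter_assay_agreement(
    run1: Sequence[float], run2: Sequence[float], rho_pass: float = 0.9
) -> AgreementResult:
    """Spearman agreement of paired readouts from two independent runs.

    Pass when rho exceeds ``rho_pass`` (default 0.9). A constant vector in
    either run leaves rho undefined and the result flagged.
    """
    r1 = np.asarray(run1, dtype=float)
    r2 = np.asarray(run2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise DataError("runs must be 1-D arrays of equal length")
    if len(r1) < 5:
        raise DataError("need at least 5 paired samples")
    res = spearman(r1, r2)
    if not res.defined:
        return AgreementResult(float("nan"), float("nan"), res.n, False, defined=False)
    return AgreementResult(res.rho, res.p_value, res.n, passed=res.rho > rho_pass)
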