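"""Shared nonparametric statistics helpers.

Spearman correlation with midrank ties; the p-value uses the
t-approximation for n >= 10 and exact enumeration of all rank permutations
below (vectorised; at most 9! arrangements).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = ["SpearmanResult", "spearman", "mann_whitney"]

_EXACT_MAX_N = 9


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # 'exact' or 't-approx'
    defined: bool = True


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation (midranks) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise DataError("spearman requires at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), n, "undefined", defined=False)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n >= _EXACT_MAX_N + 1:
        res = stats.spearmanr(x, y)
        return SpearmanResult(rho, float(res.pvalue), n, "t-approx")
    perms = np.array(list(itertools.permutations(ry)))
    cx = rx - rx.mean()
    cp = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((cx**2).sum() * (cp**2).sum(axis=1))
    rhos = cp @ cx / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return SpearmanResult(rho, p, n, "exact")


def mann_whitney(
    x, y, alternative: str = "two-sided", exact_max_n: int = 8
) -> tuple[float, float, str]:
    """Mann–Whitney U of x vs y with midrank ties.

    Exact null distribution when both groups have at most ``exact_max_n``
    observations and the data are tie-free; tie-corrected normal
    approximation otherwise. Returns (U of x, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue), method
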