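"""Cohort-level diagnostic statistics on calibrated concentrations.

Distribution checks (Shapiro–Wilk, Lilliefors, Kolmogorov–Smirnov,
Anderson–Darling) decide the parametric/non-parametric route; the group
comparison is a Mann–Whitney U test; covariate screens (Bristol stool
score, age, fecal matrix biomarkers) use Spearman correlation; and the
diagnostic performance is summarised by a ROC curve with the
Youden-optimal operating point.

Orientation: AD is the positive class and is expected at higher
concentrations; the decision rule is "concentration >= threshold ⇒ AD".
The trapezoidal AUC of the threshold scan equals the tie-corrected
Mann–Whitney U/(n_AD·n_HC) for this orientation — a cross-module identity
exercised by the test suite. Youden ties are broken toward higher
specificity, the natural choice for a screening biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from ._stats import mann_whitney, spearman
from .errors import DataError

__all__ = [
    "NormalityReport",
    "GroupComparison",
    "RocResult",
    "YoudenClassifier",
    "normality_suite",
    "compare_groups",
    "covariate_correlations",
    "roc_youden",
    "plot_roc",
]

POSITIVE_GROUP = "AD"
NEGATIVE_GROUP = "HC"


@dataclass
class NormalityReport:
    table: pd.DataFrame  # test, statistic, p_value
    non_normal: bool  # any p < 0.05 → route to non-parametric tests
    n: int


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    n_ad: int
    n_hc: int
    median_ad: float
    median_hc: float
    method: str
    alternative: str = "two-sided"


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # percent
    specificity: np.ndarray  # percent
    auc: float
    youden_threshold: float
    youden_j: float
    sens_at_youden: float
    spec_at_youden: float
    n_ad: int
    n_hc: int
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_fM": self.thresholds,
                "sensitivity_percent": self.sensitivity,
                "specificity_percent": self.specificity,
            }
        )


def normality_suite(values: Sequence[float]) -> NormalityReport:
    """Four normality tests on one sample of concentrations.

    Shapiro–Wilk and the classical Kolmogorov–Smirnov test (against a
    normal with sample-estimated parameters — the naive variant, listed for
    completeness) come from scipy; Lilliefors (the KS variant with a null
    that accounts for estimated parameters) and Anderson–Darling p-values
    come from statsmodels. The summary flag is "non-normal" as soon as any
    test rejects at 0.05; constant input leaves the tests undefined and is
    flagged non-normal.
    """
    from statsmodels.stats.diagnostic import lilliefors, normal_ad

    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 4:
        raise DataError("normality tests need at least 4 observations")
    names = ["shapiro-wilk", "lilliefors", "kolmogorov-smirnov", "anderson-darling"]
    if np.all(x == x[0]):
        table = pd.DataFrame(
            {"test": names, "statistic": np.nan, "p_value": np.nan}
        )
        return NormalityReport(table=table, non_normal=True, n=n)
    sw_stat, sw_p = stats.shapiro(x)
    lf_stat, lf_p = lilliefors(x, dist="norm")
    ks_stat, ks_p = stats.kstest((x - x.mean()) / x.std(ddof=1), "norm")
    ad_stat, ad_p = normal_ad(x)
    table = pd.DataFrame(
        {
            "test": names,
            "statistic": [sw_stat, lf_stat, ks_stat, ad_stat],
            "p_value": [sw_p, lf_p, ks_p, ad_p],
        }
    )
    return NormalityReport(table=table, non_normal=bool((table.p_value < 0.05).any()), n=n)


def _split_groups(
    table: pd.DataFrame, value_col: str, group_col: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = table[[group_col, value_col]].dropna()
    ad = sub.loc[sub[group_col] == POSITIVE_GROUP, value_col].to_numpy(dtype=float)
    hc = sub.loc[sub[group_col] == NEGATIVE_GROUP, value_col].to_numpy(dtype=float)
    if len(ad) == 0 or len(hc) == 0:
        raise DataError("both diagnostic groups must be nonempty")
    return ad, hc


def compare_groups(
    table: pd.DataFrame,
    value_col: str = "concentration_fM",
    group_col: str = "group",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Mann–Whitney U comparison of AD vs HC concentrations.

    Two-sided by default (the conservative reading for a headline group
    difference); exact null for small tie-free groups, tie-corrected normal
    approximation otherwise. The U statistic reported is that of the AD
    group, so U/(n_AD·n_HC) is the probability that a random AD sample
    exceeds a random HC sample (the ROC AUC).
    """
    ad, hc = _split_groups(table, value_col, group_col)
    u, p, method = mann_whitney(ad, hc, alternative=alternative)
    return GroupComparison(
        u_statistic=u,
        p_value=p,
        n_ad=len(ad),
        n_hc=len(hc),
        median_ad=float(np.median(ad)),
        median_hc=float(np.median(hc)),
        method=method,
        alternative=alternative,
    )


def covariate_correlations(
    table: pd.DataFrame,
    variables: Sequence[str],
    value_col: str = "concentration_fM",
    group: str | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of the concentration against each covariate.

    Missing values are dropped pairwise; variables with fewer than
    ``min_n`` complete pairs (or no data at all) are skipped with a warning
    row (rho/p NaN). When ``group`` is given, the analysis is restricted to
    that diagnostic group (the per-group Bristol screens).
    """
    import warnings

    sub = table if group is None else table[table["group"] == group]
    rows = []
    for var in variables:
        if var not in sub.columns:
            warnings.warn(f"covariate {var!r} missing from table; skipped")
            rows.append({"variable": var, "rho": np.nan, "p_value": np.nan, "n": 0})
            continue
        pair = sub[[value_col, var]].apply(pd.to_numeric, errors="coerce").dropna()
        n = len(pair)
        if n < min_n:
            warnings.warn(f"covariate {var!r} has only {n} complete pairs; skipped")
            rows.append({"variable": var, "rho": np.nan, "p_value": np.nan, "n": n})
            continue
        res = spearman(pair[value_col].to_numpy(), pair[var].to_numpy())
        rows.append(
            {"variable": var, "rho": res.rho, "p_value": res.p_value, "n": res.n}
        )
    return pd.DataFrame(rows)


def roc_youden(
    table_or_values,
    labels: Sequence[str] | None = None,
    value_col: str = "concentration_fM",
    group_col: str = "group",
) -> RocResult:
    """ROC analysis with the Youden-optimal operating point.

    Candidate thresholds are the midpoints between consecutive distinct
    concentrations plus ±inf. At threshold t: sensitivity = %(AD >= t),
    specificity = %(HC < t). The AUC is the trapezoid under the resulting
    curve. The Youden threshold maximises J = sens/100 + spec/100 − 1, with
    ties broken toward higher specificity (then the higher threshold). A
    degenerate input (all concentrations identical) yields AUC 0.5 and is
    flagged.
    """
    if isinstance(table_or_values, pd.DataFrame):
        ad, hc = _split_groups(table_or_values, value_col, group_col)
    else:
        values = np.asarray(table_or_values, dtype=float)
        lab = np.asarray(labels)
        ad = values[lab == POSITIVE_GROUP]
        hc = values[lab != POSITIVE_GROUP]
        if len(ad) == 0 or len(hc) == 0:
            raise DataError("both diagnostic groups must be nonempty")
    distinct = np.unique(np.concatenate([ad, hc]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = 100.0 * (ad[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = 100.0 * (hc[None, :] < thresholds[:, None]).mean(axis=1)
    fpr = 1.0 - spec / 100.0
    tpr = sens / 100.0
    # fpr and tpr are both non-increasing in the threshold; reversing gives
    # the ROC staircase in ascending order for the trapezoid
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    degenerate = len(distinct) == 1
    j = tpr + spec / 100.0 - 1.0
    j_max = j.max()
    best = np.flatnonzero(np.isclose(j, j_max, rtol=0.0, atol=1e-12))
    best = best[spec[best] == spec[best].max()]
    idx = int(best[np.argmax(thresholds[best])])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thresholds[idx]),
        youden_j=float(j[idx]),
        sens_at_youden=float(sens[idx]),
        spec_at_youden=float(spec[idx]),
        n_ad=len(ad),
        n_hc=len(hc),
        degenerate=degenerate,
    )


class YoudenClassifier(BaseEstimator, ClassifierMixin):
    """Single-threshold diagnostic classifier at the Youden-optimal cut.

    ``fit(X, y)`` takes concentrations (n,) or (n, 1) and group labels with
    the positive class at higher values; ``predict`` applies the rule
    ``x >= threshold_ ⇒ positive``.

    Attributes: ``threshold_``, ``auc_``, ``sensitivity_``,
    ``specificity_``, ``youden_j_``, ``roc_``.
    """

    def __init__(self, positive_label: str = POSITIVE_GROUP):
        self.positive_label = positive_label

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        labels = np.where(y == self.positive_label, POSITIVE_GROUP, NEGATIVE_GROUP)
        roc = roc_youden(x, labels)
        self.classes_ = np.unique(y)
        self.roc_ = roc
        self.threshold_ = roc.youden_threshold
        self.auc_ = roc.auc
        self.sensitivity_ = roc.sens_at_youden
        self.specificity_ = roc.spec_at_youden
        self.youden_j_ = roc.youden_j
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        pos = x >= self.threshold_
        neg_label = next(
            (c for c in self.classes_ if c != self.positive_label), NEGATIVE_GROUP
        )
        return np.where(pos, self.positive_label, neg_label)


def plot_roc(roc: RocResult, path: str) -> None:
    """Write a ROC curve plot (the operating point highlighted) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = 1.0 - roc.specificity / 100.0
    tpr = roc.sensitivity / 100.0
    order = np.argsort(fpr, kind="stable")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr[order], tpr[order], drawstyle="steps-post", color="firebrick")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.scatter(
        [1 - roc.spec_at_youden / 100], [roc.sens_at_youden / 100], zorder=3, c="k", s=20
    )
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
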