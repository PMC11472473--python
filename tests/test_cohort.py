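"""Cohort statistics: normality routing, group comparison, covariate
screens, and ROC/Youden diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from sfida._stats import mann_whitney, spearman
from sfida.cohort import (
    YoudenClassifier,
    compare_groups,
    covariate_correlations,
    normality_suite,
    roc_youden,
)
from sfida.errors import DataError
from sfida.simulate import CohortSimParams, gen_cohort


def make_table(ad, hc):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(ad) + len(hc))],
            "group": ["AD"] * len(ad) + ["HC"] * len(hc),
            "concentration_fM": list(ad) + list(hc),
        }
    )


def brute_force_youden(values, labels):
    """Oracle: scan every observed value (and +/- inf) as a '>= threshold'
    cut and maximise J directly."""
    values = np.asarray(values, float)
    ad = values[labels == "AD"]
    hc = values[labels != "AD"]
    best = (-np.inf, None)
    for t in np.concatenate([values, [-np.inf, np.inf]]):
        sens = (ad >= t).mean()
        spec = (hc < t).mean()
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best[0]


class TestNormalitySuite:
    def test_typeI_calibration_per_test(self):
        """Each calibrated test rejects a truly normal sample at roughly its
        nominal 5% rate; the naive KS variant is conservative."""
        rng = np.random.default_rng(0)
        reps = 200
        rates = {n: 0 for n in ("shapiro-wilk", "lilliefors", "anderson-darling",
                                "kolmogorov-smirnov")}
        for _ in range(reps):
            t = normality_suite(rng.normal(10, 2, 500)).table
            for name, p in zip(t.test, t.p_value):
                rates[name] += p < 0.05
        for name in ("shapiro-wilk", "lilliefors", "anderson-darling"):
            assert 0.01 <= rates[name] / reps <= 0.09, name
        assert rates["kolmogorov-smirnov"] / reps <= 0.05

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rep = normality_suite(rng.lognormal(0.0, 1.0, 500))
            t = rep.table
            assert t.loc[t.test == "shapiro-wilk", "p_value"].iloc[0] < 0.05
            assert rep.non_normal  # routes downstream to non-parametric tests

    def test_constant_input_flagged_non_normal(self):
        rep = normality_suite([5.0] * 10)
        assert rep.non_normal and rep.table.p_value.isna().all()

    def test_minimum_n(self):
        with pytest.raises(DataError):
            normality_suite([1.0, 2.0, 3.0])


class TestCompareGroups:
    def test_exact_one_sided_enumeration(self):
        # AD {4,5,6} vs HC {1,2,3}: 1 of C(6,3)=20 arrangements is as extreme
        table = make_table([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        res = compare_groups(table, alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_null_permutation_calibration(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(3.0, 1.0, 57)
        ps = []
        for _ in range(300):
            perm = rng.permutation(base)
            ps.append(compare_groups(make_table(perm[:26], perm[26:])).p_value)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_u_over_n1n2_equals_auc(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 8, 40).astype(float)
        table = make_table(vals[:18], vals[18:])
        res = compare_groups(table)
        roc = roc_youden(table)
        assert res.u_statistic / (res.n_ad * res.n_hc) == pytest.approx(roc.auc)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            compare_groups(make_table([1.0], []))


class TestCovariateCorrelations:
    def test_self_correlation(self):
        table = gen_cohort(CohortSimParams(seed=5))
        table["self"] = table.concentration_fM
        out = covariate_correlations(table, ["self"])
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_independent_covariate_null_spread(self):
        """|rho| for an independent covariate at n=57 stays below the
        1.96/sqrt(n-1) bound at roughly the nominal 95% rate."""
        rng = np.random.default_rng(3)
        inside = 0
        reps = 300
        for _ in range(reps):
            x = rng.lognormal(3, 1.5, 57)
            z = rng.normal(size=57)
            inside += abs(spearman(x, z).rho) < 0.26
        assert 0.90 <= inside / reps <= 0.99

    def test_per_group_analysis(self):
        table = gen_cohort(CohortSimParams(seed=9))
        ad_only = covariate_correlations(table, ["bristol"], group="AD")
        assert ad_only.n.iloc[0] == 26
        both = covariate_correlations(table, ["bristol"])
        assert both.n.iloc[0] == 57

    def test_missing_variable_skipped_with_warning(self):
        table = gen_cohort(CohortSimParams(seed=2))
        table["broken"] = np.nan
        with pytest.warns(UserWarning):
            out = covariate_correlations(table, ["broken", "age"])
        assert np.isnan(out.loc[out.variable == "broken", "rho"]).all()
        assert np.isfinite(out.loc[out.variable == "age", "rho"]).all()


class TestRocYouden:
    def test_perfect_separation(self):
        roc = roc_youden(make_table([3.0, 4.0, 5.0], [1.0, 2.0]))
        assert roc.auc == 1.0
        assert roc.sens_at_youden == 100.0 and roc.spec_at_youden == 100.0
        assert 2.0 < roc.youden_threshold < 3.0

    def test_matches_brute_force_on_random_values(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            values = rng.choice(np.arange(12.0), size=12)
            labels = np.array(["AD"] * 5 + ["HC"] * 7)
            roc = roc_youden(values, labels)
            assert roc.youden_j == pytest.approx(brute_force_youden(values, labels))
            # returned threshold is optimal against every candidate threshold
            ad, hc = values[labels == "AD"], values[labels == "HC"]
            for t in np.concatenate([values, [-np.inf, np.inf]]):
                j_alt = (ad >= t).mean() + (hc < t).mean() - 1
                assert roc.youden_j >= j_alt - 1e-12

    def test_auc_equals_independent_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        values = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.4, "AD", "HC")
        assert roc_youden(values, labels).auc == pytest.approx(
            roc_auc_score(labels == "AD", values)
        )

    @given(seed=st.integers(0, 200))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(1.0, 1.0, 30)
        labels = np.array(["AD"] * 12 + ["HC"] * 18)
        base = roc_youden(values, labels).auc
        assert roc_youden(np.log(values), labels).auc == pytest.approx(base)
        assert roc_youden(values**2, labels).auc == pytest.approx(base)

    def test_tie_break_prefers_specificity(self):
        # J is maximal both at a cut between 1|2 (sens 100, spec 50) and
        # between 2|3 (sens 50, spec 100): the higher-specificity cut wins
        roc = roc_youden(np.array([2.0, 3.0, 1.0, 2.0]),
                        np.array(["AD", "AD", "HC", "HC"]))
        assert roc.spec_at_youden == 100.0 and roc.sens_at_youden == 50.0

    def test_degenerate_input_flagged(self):
        roc = roc_youden(make_table([1.0, 1.0], [1.0, 1.0]))
        assert roc.degenerate and roc.auc == pytest.approx(0.5)

    def test_auc_recovery_against_analytic_normal_model(self):
        """Mean AUC over simulated cohorts matches Phi(delta/(sigma*sqrt(2)))
        from the log-normal generative model."""
        p = CohortSimParams()
        expected = norm.cdf((p.log_mean_ad - p.log_mean_hc) / (p.log_sd * np.sqrt(2)))
        aucs = [roc_youden(gen_cohort(CohortSimParams(seed=s))).auc for s in range(500)]
        assert np.mean(aucs) == pytest.approx(expected, abs=0.03)


class TestYoudenClassifier:
    def test_fit_predict_and_clone(self):
        from sklearn.base import clone

        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        y = np.array(["HC", "HC", "HC", "AD", "AD", "AD"])
        clf = YoudenClassifier().fit(x, y)
        assert clf.auc_ == 1.0
        assert list(clf.predict([0.0, 20.0])) == ["HC", "AD"]
        assert clone(clf).get_params()["positive_label"] == "AD"

    def test_exact_small_sample_spearman_branch(self):
        # cross-check the exact-permutation p against scipy's t-approximation
        # direction on an n=6 sample without ties
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        res = spearman(x, y)
        assert res.method == "exact"
        # rho for three adjacent swaps at n=6: 1 - 6*3*2/(6*35)
        assert res.rho == pytest.approx(1 - 36 / (6 * 35))
        assert 0.0 < res.p_value <= 1.0
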