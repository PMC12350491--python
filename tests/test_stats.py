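"""Statistical layer: enumeration oracles, U-AUC identity, CCC, logistic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lungdce.errors import InvalidInputError, UndefinedStatisticError
from lungdce.features import FEATURE_COLUMNS
from lungdce.stats import (
    bivariable_logistic,
    kruskal_by_histology,
    kruskal_wallis,
    lin_ccc,
    mann_whitney_u,
    roc_analysis,
    run_stratification,
)


def exact_mw_p_by_enumeration(x, y):
    """Brute-force two-sided Mann-Whitney p: enumerate every assignment of
    the pooled tie-free values to the two groups and count U as extreme."""
    pooled = np.concatenate([x, y])
    n_x = len(x)

    def u_of(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    mean_u = n_x * len(y) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        total += 1
        if abs(u_of(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_multisets_give_central_u_and_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n^2 / 2
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_groups_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2.0 / 20.0)  # 2 of C(6,3)=20 assignments as extreme

    @pytest.mark.parametrize("n_x,n_y", [(3, 4), (4, 4), (2, 6), (3, 5)])
    def test_exact_p_matches_full_enumeration(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n_x + n_y + 1))  # tie-free
            x, y = pooled[:n_x], pooled[n_x:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(exact_mw_p_by_enumeration(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_groups_show_no_difference(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_group_case_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 30)
            _, p_kw = kruskal_wallis([x, y])
            _, p_mw = mann_whitney_u(x, y)
            assert abs(p_kw - p_mw) < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(InvalidInputError):
            kruskal_wallis([[1.0, 2.0]])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3, n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.accuracy == 1.0
        assert res.positive_class == "b"

    def test_uninformative_constant_feature(self):
        res = roc_analysis(np.ones(10), ["a"] * 5 + ["b"] * 5, n_boot=100, seed=0)
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_scaled_u_statistic_on_tie_free_data(self):
        """Trapezoid AUC over the empirical ROC equals U / (n1 n2)."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1, n2 = rng.integers(5, 15, 2)
            x = rng.normal(0.5, 1, n1)  # positive-leaning group
            y = rng.normal(0, 1, n2)
            feature = np.concatenate([x, y])
            labels = np.array(["pos"] * n1 + ["neg"] * n2)
            res = roc_analysis(feature, labels, n_boot=10, seed=1)
            pos = feature[labels == res.positive_class]
            neg = feature[labels != res.positive_class]
            u, _ = mann_whitney_u(pos, neg)
            assert res.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_bootstrap_ci_is_seeded_and_contains_point_estimate(self):
        feature = np.array([1.0, 2, 3, 4, 2.5, 5, 6, 7, 8, 6.5])
        labels = ["a"] * 5 + ["b"] * 5
        r1 = roc_analysis(feature, labels, n_boot=500, seed=42)
        r2 = roc_analysis(feature, labels, n_boot=500, seed=42)
        assert r1.ci95 == r2.ci95
        assert r1.ci95[0] <= r1.auc <= r1.ci95[1]

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_analysis([1.0, 2.0], ["a", "a"])


class TestCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert lin_ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_is_penalized(self):
        x = np.linspace(0, 1, 20)
        shifted = lin_ccc(x, x + 10.0)
        assert shifted < 0.01  # Pearson r would be 1 here

    def test_moment_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.1, 2.1, 2.9, 4.2]
        # independent hand computation of the population moments
        mx, my = sum(x) / 4, sum(y) / 4
        vx = sum((a - mx) ** 2 for a in x) / 4
        vy = sum((b - my) ** 2 for b in y) / 4
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / 4
        expected = 2 * cov / (vx + vy + (mx - my) ** 2)
        assert lin_ccc(x, y) == pytest.approx(expected, abs=1e-15)

    def test_ccc_bounded_by_absolute_pearson(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            x = rng.normal(0, 1, 25)
            y = 0.5 * x + rng.normal(1.0, 0.7, 25)
            r = np.corrcoef(x, y)[0, 1]
            assert lin_ccc(x, y) <= abs(r) + 1e-12

    def test_double_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lin_ccc(np.ones(5), np.ones(5))


class TestLogistic:
    def test_constant_covariate_reduces_to_univariable(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 120)
        y = (rng.random(120) < 1 / (1 + np.exp(-1.5 * x))).astype(int)
        with_cov = bivariable_logistic(x, y, nodal=np.repeat("N1-N3", 120))
        alone = bivariable_logistic(x, y)
        assert with_cov.loc["nodal", "feature_coef"] == pytest.approx(
            alone.loc["none", "feature_coef"]
        )

    def test_known_coefficient_recovered_within_two_standard_errors(self):
        rng = np.random.default_rng(6)
        beta = 1.2
        x = rng.normal(0, 1, 500)
        nodal = rng.choice(["N0", "N1-N3"], 500)
        y = (rng.random(500) < 1 / (1 + np.exp(-(0.2 + beta * x)))).astype(int)
        res = bivariable_logistic(x, y, nodal=nodal)
        coef = res.loc["nodal", "feature_coef"]
        assert abs(coef - beta) < 0.3  # ~2 SE at n=500
        assert res.loc["nodal", "feature_significant"]

    def test_complete_separation_flagged_not_reported(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)
        res = bivariable_logistic(x, y)
        assert res.loc["none", "complete_separation"]
        assert np.isnan(res.loc["none", "feature_p"])


def _toy_features_and_labels(seed=0, n=30, effect=1.0):
    rng = np.random.default_rng(seed)
    tps = np.r_[rng.uniform(50, 100, n // 3), rng.uniform(0, 50, n - n // 3)]
    labels = pd.DataFrame(
        {
            "tps_percent": tps,
            "histology": rng.choice(["adeno", "squamous", "poorly_differentiated"], n),
            "nodal_status": rng.choice(["N0", "N1-N3"], n),
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
    )
    feats = pd.DataFrame(
        {c: rng.normal(0, 1, n) for c in FEATURE_COLUMNS},
        index=labels.index,
    )
    # impose the group contrast on the transfer-rate features only
    lo = tps < 50
    for c in ("median_ktrans", "p90_ktrans", "sd_ktrans", "median_kep"):
        feats.loc[lo, c] += effect
    return feats, labels


class TestStratification:
    def test_produces_one_row_per_first_order_feature(self):
        feats, labels = _toy_features_and_labels()
        table = run_stratification(feats, labels, 50, n_boot=50, seed=0)
        assert list(table.index) == FEATURE_COLUMNS
        assert len(table) == 12
        assert table["roc_auc"].between(0, 1).all()
        assert (table["auc_ci_lo"] <= table["roc_auc"]).all()
        assert (table["roc_auc"] <= table["auc_ci_hi"]).all()

    def test_detects_imposed_effect_with_correct_direction(self):
        feats, labels = _toy_features_and_labels(effect=2.0)
        table = run_stratification(feats, labels, 50, n_boot=50, seed=0)
        row = table.loc["median_ktrans"]
        assert row["significant_uncorrected"]
        assert row["median_lt50"] > row["median_ge50"]

    def test_single_class_threshold_rejected(self):
        feats, labels = _toy_features_and_labels()
        labels["tps_percent"] = 80.0
        with pytest.raises(InvalidInputError):
            run_stratification(feats, labels, 50, n_boot=10, seed=0)

    def test_kruskal_report_covers_all_features(self):
        feats, labels = _toy_features_and_labels()
        table = kruskal_by_histology(feats, labels)
        assert len(table) == 12
        assert table["p_value"].between(0, 1).all()
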