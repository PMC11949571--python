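"""Correlation screening, ANOVA+LSD, regression metrics, RF importance."""

import numpy as np
import pandas as pd
import pytest

from karst_gep.drivers import (
    INDEPENDENT_VARS, anova_lsd, correlation_matrix, regression_metrics, rf_importance,
)
from karst_gep.synthetic import driver_study_spec, generate_villages


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())


class TestCorrelation:
    def test_self_and_negation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0, 3.0]})
        df["neg"] = -df["x"]
        mat = correlation_matrix(df)
        assert mat["r"].loc["x", "x"] == 1.0
        assert mat["r"].loc["x", "neg"] == pytest.approx(-1.0)

    def test_known_pair(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 4, 6, 9]})
        mat = correlation_matrix(df)
        assert mat["r"].loc["x", "y"] == pytest.approx(brute_pearson(df.x, df.y), rel=1e-12)
        # closed form: 11.5 / sqrt(5 × 26.75)
        assert mat["r"].loc["x", "y"] == pytest.approx(11.5 / np.sqrt(133.75), rel=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            df = pd.DataFrame(rng.normal(size=(rng.integers(4, 12), 3)), columns=list("abc"))
            mat = correlation_matrix(df)
            for i in "abc":
                for j in "abc":
                    assert mat["r"].loc[i, j] == pytest.approx(
                        brute_pearson(df[i], df[j]), rel=1e-9, abs=1e-9
                    )

    def test_constant_column_flagged_not_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        mat = correlation_matrix(df)
        assert "c" in mat["r"].columns
        assert np.isnan(mat["r"].loc["x", "c"])

    def test_stars_thresholds(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(scale=0.1, size=50)})
        assert correlation_matrix(df)["stars"].loc["x", "y"] == "**"


def hand_anova_f(groups):
    """Textbook one-way ANOVA F from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnovaLsd:
    def labelled(self, groups):
        values = np.concatenate(groups)
        labels = np.concatenate([[f"g{i}"] * len(g) for i, g in enumerate(groups)])
        return values, labels

    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0])
        values, labels = self.labelled([g, g.copy()])
        res = anova_lsd(values, labels)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert not res.pairwise["significant"].any()

    def test_separated_groups_significant(self):
        a = np.array([0.0, 0.01, -0.01])
        b = np.array([10.0, 10.01, 9.99])
        values, labels = self.labelled([a, b])
        res = anova_lsd(values, labels)
        assert res.p_value < 1e-6
        assert res.pairwise["significant"].all()
        assert res.letters["g0"] != res.letters["g1"]

    def test_f_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            groups = [rng.normal(loc=rng.uniform(-2, 2), size=rng.integers(3, 9))
                      for _ in range(rng.integers(2, 5))]
            values, labels = self.labelled(groups)
            res = anova_lsd(values, labels)
            assert res.f_stat == pytest.approx(hand_anova_f(groups), rel=1e-9)

    def test_overlapping_groups_share_a_letter(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.1, 1.0, 10)  # indistinguishable from a
        c = rng.normal(15.0, 1.0, 10)
        values, labels = self.labelled([a, b, c])
        res = anova_lsd(values, labels)
        assert set(res.letters["g0"]) & set(res.letters["g1"])
        assert not set(res.letters["g2"]) & set(res.letters["g0"])

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r2"] == pytest.approx(1.0)
        assert m["mae"] == m["mse"] == m["rmse"] == 0.0

    def test_direct_evaluation(self):
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["mse"] == pytest.approx(2 / 3)
        assert m["rmse"] == pytest.approx(np.sqrt(2 / 3))

    def test_rmse_squared_equals_mse(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            yt = rng.normal(size=20)
            yp = yt + rng.normal(size=20)
            m = regression_metrics(yt, yp)
            assert m["rmse"] ** 2 == pytest.approx(m["mse"], rel=1e-9, abs=1e-12)

    def test_mape_excludes_zero_truth(self):
        m = regression_metrics([0.0, 2.0, 4.0], [1.0, 1.0, 2.0])
        assert m["mape"] == pytest.approx(np.mean([0.5, 0.5]))

    def test_mape_is_a_fraction(self):
        m = regression_metrics([100.0, 200.0], [99.0, 202.0])
        assert m["mape"] == pytest.approx(np.mean([0.01, 0.01]))


@pytest.fixture(scope="module")
def villages():
    return generate_villages(driver_study_spec(314))


class TestRfImportance:

    def test_deterministic_given_seed(self, villages):
        a = rf_importance(villages, seed=5)
        b = rf_importance(villages, seed=5)
        assert a.importances == b.importances
        assert a.metrics == b.metrics

    def test_importances_sum_to_one(self, villages):
        rep = rf_importance(villages, seed=5)
        assert sum(rep.importances.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in rep.importances.values())
        assert rep.metrics["rmse"] ** 2 == pytest.approx(rep.metrics["mse"], rel=1e-9)

    def test_copy_of_feature_dominates(self, villages):
        df = villages.copy()
        df["VRR"] = df["AAP"]
        rep = rf_importance(df, target="VRR", seed=0)
        assert rep.importances["AAP"] > 0.9

    def test_pure_noise_has_no_dominant_feature(self, villages):
        # importance of every feature should hover near the uniform 1/13
        rng = np.random.default_rng(99)
        means = np.zeros(len(INDEPENDENT_VARS))
        n_rep = 8
        for s in range(n_rep):
            df = villages.copy()
            df["VRR"] = rng.normal(size=len(df))
            rep = rf_importance(df, target="VRR", seed=s)
            means += np.array([rep.importances[f] for f in INDEPENDENT_VARS])
        means /= n_rep
        assert means.max() < 2.5 / 13

    def test_importance_invariant_to_feature_order(self, villages):
        perm = tuple(reversed(INDEPENDENT_VARS))
        a = rf_importance(villages, seed=5)
        b = rf_importance(villages, seed=5, features=perm)
        for f in INDEPENDENT_VARS:
            assert b.importances[f] == pytest.approx(a.importances[f], abs=0.02)

    def test_degenerate_target_rejected(self, villages):
        df = villages.copy()
        df["VRR"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            rf_importance(df, target="VRR", seed=0)
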