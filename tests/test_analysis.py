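"""Impact statistics: classification, clustering, eta2, drought types, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from traitscreen.analysis import (
    DroughtThresholds,
    classify_traits,
    cluster_impactful,
    drought_type,
    drought_type_from_trajectory,
    eta_squared,
    stress_regression,
)


class TestClassification:
    def test_three_way_partition_with_inclusive_boundary(self):
        mu = pd.DataFrame(
            {"e1": [0.0, 0.01, 0.02, 0.08], "e2": [0.0, 0.03, 0.02, 0.02]},
            index=["inert", "weak", "boundary", "strong"])
        groups = classify_traits(mu)
        assert groups["inert"] == "null"  # zero in every environment
        assert groups["weak"] == "low"  # mean 0.02 exactly: boundary inclusive
        assert groups["boundary"] == "low"
        assert groups["strong"] == "impactful"  # mean 0.05

    def test_partition_is_complete(self):
        rng = np.random.default_rng(0)
        mu = pd.DataFrame(rng.uniform(0, 0.1, size=(30, 8)))
        groups = classify_traits(mu)
        assert set(groups.unique()) <= {"null", "low", "impactful"}
        assert len(groups) == 30

    def test_negative_mu_star_rejected(self):
        with pytest.raises(ValueError):
            classify_traits(pd.DataFrame({"e": [-0.1]}))


class TestClustering:
    def test_identical_rows_merge_first_at_zero_height(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [8.0, -3.0]],
                           index=["a", "b", "c"], columns=["o1", "o2"])
        res = cluster_impactful(mat, k=2)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0.0] * 8, [50.0] * 8, [-60.0] * 8])
        rows, truth = [], []
        for b, c in enumerate(centers):
            for _ in range(5):
                rows.append(c + rng.normal(0, 0.5, 8))
                truth.append(b)
        mat = pd.DataFrame(rows, index=[f"t{i}" for i in range(15)])
        res = cluster_impactful(mat, k=3)
        # same-block pairs share labels, cross-block pairs never do
        labels = res.labels.to_numpy()
        truth = np.array(truth)
        for i, j in itertools.combinations(range(15), 2):
            assert (labels[i] == labels[j]) == (truth[i] == truth[j])

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(rng.normal(size=(12, 8)))
        res = cluster_impactful(mat, k=3)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_larger_than_traits_rejected(self):
        with pytest.raises(ValueError):
            cluster_impactful(pd.DataFrame(np.eye(3)), k=4)

    def test_newick_export_is_well_formed(self):
        mat = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                           index=["w", "x", "y", "z"])
        text = cluster_impactful(mat, k=2).to_newick()
        assert text.endswith(";")
        assert text.count("(") == text.count(")") == 3  # n-1 internal nodes
        for name in "wxyz":
            assert name in text


def balanced_grid(n_rep: int = 3) -> pd.DataFrame:
    levels = {"site": ["A", "B", "C", "D"], "sowing": ["s1", "s2", "s3"],
              "co2": ["lo", "hi"], "nitrogen": ["n1", "n2", "n3"]}
    rows = [dict(zip(levels, combo))
            for combo in itertools.product(*levels.values())
            for _ in range(n_rep)]
    return pd.DataFrame(rows)


class TestEtaSquared:
    def test_constant_impacts_flagged_degenerate(self):
        factors = balanced_grid(1)
        dec = eta_squared(pd.Series(2.0, index=factors.index), factors)
        assert dec.degenerate
        assert all(v == 0.0 for v in dec.shares().values())

    def test_pure_site_effect(self):
        factors = balanced_grid(1)
        y = factors["site"].map({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        dec = eta_squared(y, factors)
        assert dec.eta2["site"] == pytest.approx(1.0, abs=1e-12)
        assert dec.residual == pytest.approx(0.0, abs=1e-12)

    def test_recovers_prescribed_variance_shares(self):
        """Additive model built with orthogonal contrasts carrying exact
        sums of squares in ratio 0.4 / 0.3 / 0.2 / 0.1 (no noise)."""
        factors = balanced_grid(2)
        n = len(factors)
        shares = {"site": 0.4, "sowing": 0.3, "co2": 0.2, "nitrogen": 0.1}
        contrasts = {
            "site": {"A": 1.0, "B": -1.0, "C": 1.0, "D": -1.0},
            "sowing": {"s1": 1.0, "s2": 0.0, "s3": -1.0},
            "co2": {"lo": 1.0, "hi": -1.0},
            "nitrogen": {"n1": 1.0, "n2": 0.0, "n3": -1.0},
        }
        y = pd.Series(0.0, index=factors.index)
        for col, contrast in contrasts.items():
            effect = factors[col].map(contrast).astype(float)
            effect -= effect.mean()
            ss = (effect ** 2).sum()
            y = y + effect * np.sqrt(shares[col] * n / ss)
        dec = eta_squared(y, factors)
        for col, share in shares.items():
            expected = share * n / ((y - y.mean()) ** 2).sum()
            assert dec.eta2[col] == pytest.approx(expected, abs=1e-6)
        # by construction TSS = sum of the factor SS, so shares are exact
        assert dec.eta2["site"] / dec.eta2["sowing"] == pytest.approx(4 / 3, abs=1e-6)
        assert dec.residual == pytest.approx(0.0, abs=1e-9)

    def test_shares_sum_to_one_with_noise(self):
        rng = np.random.default_rng(8)
        factors = balanced_grid(3)
        y = pd.Series(rng.normal(size=len(factors)), index=factors.index)
        dec = eta_squared(y, factors)
        assert sum(dec.eta2.values()) + dec.residual == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in dec.eta2.values())

    def test_matches_statsmodels_anova(self):
        """Independent route: sequential ANOVA from statsmodels on a balanced
        grid gives the same eta-squared shares."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(9)
        factors = balanced_grid(2)
        y = (factors["site"].map({"A": 0.0, "B": 1.0, "C": 2.0, "D": 0.5})
             + factors["co2"].map({"lo": 0.0, "hi": 0.8})
             + rng.normal(0, 0.4, len(factors)))
        df = factors.assign(y=y)
        fit = ols("y ~ C(site) + C(sowing) + C(co2) + C(nitrogen)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        tss = table["sum_sq"].sum()
        dec = eta_squared(df["y"], factors)
        for col, label in [("site", "C(site)"), ("sowing", "C(sowing)"),
                           ("co2", "C(co2)"), ("nitrogen", "C(nitrogen)")]:
            assert dec.eta2[col] == pytest.approx(
                table.loc[label, "sum_sq"] / tss, abs=1e-10)

    def test_unbalanced_grid_rejected(self):
        factors = balanced_grid(1).iloc[:-1]
        with pytest.raises(ValueError):
            eta_squared(pd.Series(1.0, index=factors.index), factors)


class TestDroughtTypes:
    def test_rule_examples(self):
        assert drought_type(0.0, 0.0) == "ET1"
        assert drought_type(0.7, 0.8) == "ET4"
        assert drought_type(0.05, 0.35) == "ET2"  # stress only after flowering
        assert drought_type(0.55, 0.25) == "ET3"  # early stress, relieved later

    def test_every_pattern_gets_exactly_one_label(self):
        for veg in np.linspace(0, 1, 21):
            for gf in np.linspace(0, 1, 21):
                assert drought_type(veg, gf) in {"ET1", "ET2", "ET3", "ET4"}

    def test_trajectory_windows(self):
        rising = np.r_[np.zeros(50), np.full(40, 0.4)]
        assert drought_type_from_trajectory(rising, 50) == "ET2"
        relieved = np.r_[np.full(50, 0.6), np.full(40, 0.1)]
        assert drought_type_from_trajectory(relieved, 50) == "ET3"
        with pytest.raises(ValueError):
            drought_type_from_trajectory(rising, 0)

    def test_custom_thresholds(self):
        t = DroughtThresholds(low=0.1, severe=0.3)
        assert drought_type(0.35, 0.35, t) == "ET4"

    def test_invalid_stress_rejected(self):
        with pytest.raises(ValueError):
            drought_type(1.2, 0.0)


class TestStressRegression:
    def test_exact_linear_data(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"mu_star_std": 2.0 * x + 1.0, "stress": x,
                           "env_type": "ET1"})
        fit = stress_regression(df)
        assert fit.loc["ET1", "slope"] == pytest.approx(2.0)
        assert fit.loc["ET1", "intercept"] == pytest.approx(1.0)
        assert fit.loc["ET1", "r"] == pytest.approx(1.0)

    def test_pure_noise_has_negligible_correlation(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"mu_star_std": rng.normal(size=1000),
                           "stress": rng.uniform(size=1000), "env_type": "ET2"})
        assert abs(stress_regression(df).loc["ET2", "r"]) < 0.1

    def test_matches_closed_form_ols(self):
        x = np.array([0.1, 0.4, 0.5, 0.9, 1.0])
        y = np.array([1.0, 0.4, 0.8, 0.1, 0.3])
        df = pd.DataFrame({"mu_star_std": y, "stress": x, "env_type": "ET3"})
        fit = stress_regression(df)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        assert fit.loc["ET3", "slope"] == pytest.approx(slope, abs=1e-12)
        assert fit.loc["ET3", "intercept"] == pytest.approx(
            y.mean() - slope * x.mean(), abs=1e-12)

    def test_small_or_degenerate_groups_rejected(self):
        df = pd.DataFrame({"mu_star_std": [1.0, 2.0], "stress": [0.1, 0.2],
                           "env_type": "ET1"})
        with pytest.raises(ValueError):
            stress_regression(df)
        df = pd.DataFrame({"mu_star_std": [1.0, 2.0, 3.0],
                           "stress": [0.5, 0.5, 0.5], "env_type": "ET1"})
        with pytest.raises(ValueError):
            stress_regression(df)
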