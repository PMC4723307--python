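"""Morris engine: OAT structure, oracle equivalence, index aggregation."""

import numpy as np
import pandas as pd
import pytest

from traitscreen.morris import (
    ElementaryEffects,
    MorrisDesign,
    aggregate_indices,
    build_design,
    elementary_effects,
    standardize_by_environment,
)


def brute_force_indices(design: MorrisDesign, y: np.ndarray):
    """Independent oracle: enumerate transitions straight from the row list.

    Finds the single changed coordinate of each consecutive row pair itself
    (no use of the design's bookkeeping), divides the output difference by
    the signed coordinate change, and aggregates with textbook formulas.
    """
    effects = {i: [] for i in range(design.g)}
    for t in range(design.r):
        block = design.rows[t * (design.g + 1): (t + 1) * (design.g + 1)]
        for a, b, ya, yb in zip(block[:-1], block[1:],
                                y[t * (design.g + 1): -1], y[t * (design.g + 1) + 1:]):
            changed = np.flatnonzero(a != b)
            assert len(changed) == 1
            i = int(changed[0])
            effects[i].append((yb - ya) / (b[i] - a[i]))
    mu_star = np.array([np.mean(np.abs(effects[i])) for i in range(design.g)])
    sigma = np.array([np.std(effects[i], ddof=1) if len(effects[i]) > 1 else 0.0
                      for i in range(design.g)])
    return mu_star, sigma


class TestDesignStructure:
    def test_paper_scale_row_count(self):
        d = build_design(g=90, n_levels=6, r=100, seed=0)
        assert d.rows.shape == (9100, 90)
        assert d.delta == pytest.approx(0.6)

    def test_single_trajectory_oat_shape(self):
        d = build_design(g=2, n_levels=6, r=1, seed=3)
        assert d.rows.shape == (3, 2)
        moved = [int(np.flatnonzero(d.rows[k] != d.rows[k + 1])[0]) for k in range(2)]
        assert sorted(moved) == [0, 1]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("g, n_levels", [(1, 2), (3, 6), (7, 4)])
    def test_oat_structural_validity(self, g, n_levels, seed):
        """Each step moves exactly one factor by +/-delta; each factor once;
        every coordinate stays on the level grid."""
        d = build_design(g=g, n_levels=n_levels, r=4, seed=seed)
        grid = np.linspace(0.0, 1.0, n_levels)
        assert np.all(np.isclose(d.rows[..., None], grid, atol=1e-12).any(axis=-1))
        for t in range(d.r):
            block = d.trajectory(t)
            moved = []
            for a, b in zip(block[:-1], block[1:]):
                diff = np.flatnonzero(~np.isclose(a, b))
                assert len(diff) == 1
                i = int(diff[0])
                assert abs(b[i] - a[i]) == pytest.approx(d.delta)
                moved.append(i)
            assert sorted(moved) == list(range(g))

    def test_dispersion_selection_is_optimal_for_tiny_pool(self):
        """Greedy 2-of-4 selection attains the true max-dispersion pair."""
        from itertools import combinations

        from traitscreen.morris import _trajectory_distance_matrix

        seed = 12
        full = build_design(g=2, n_levels=6, r=4, seed=seed)
        stack = full.rows.reshape(4, 3, 2)
        dist = _trajectory_distance_matrix(stack)
        best = max(combinations(range(4), 2), key=lambda ij: dist[ij])
        picked = build_design(g=2, n_levels=6, r=2, n_candidates=4, seed=seed)
        chosen = {tuple(map(tuple, picked.trajectory(t))) for t in range(2)}
        expected = {tuple(map(tuple, stack[i])) for i in best}
        assert chosen == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_design(g=0, r=1)
        with pytest.raises(ValueError):
            build_design(g=2, n_levels=5, r=1)
        with pytest.raises(ValueError):
            build_design(g=2, r=4, n_candidates=2)

    def test_reproducible_and_frame_round_trip(self):
        a = build_design(g=4, r=3, seed=42)
        b = build_design(g=4, r=3, seed=42)
        assert np.array_equal(a.rows, b.rows)
        back = MorrisDesign.from_frame(a.to_frame(["a", "b", "c", "d"]))
        assert np.allclose(back.rows, a.rows)
        assert np.array_equal(back.moved_factor, a.moved_factor)
        assert np.allclose(back.signed_step, a.signed_step)


class TestElementaryEffects:
    @pytest.mark.parametrize("g", [1, 2, 3])
    def test_oracle_equivalence_random_function(self, g):
        """mu*/sigma match brute-force enumeration to 1e-10 on g<=3."""
        design = build_design(g=g, n_levels=6, r=8, seed=g)
        rng = np.random.default_rng(7)
        coef = rng.normal(size=(g, g))

        def f(x):
            return float(x @ coef @ x + x.sum())

        y = np.array([f(row) for row in design.rows])
        idx = aggregate_indices(elementary_effects(design, y))
        mu_ref, sigma_ref = brute_force_indices(design, y)
        np.testing.assert_allclose(idx.mu_star, mu_ref, atol=1e-10)
        np.testing.assert_allclose(idx.sigma, sigma_ref, atol=1e-10)

    def test_linear_function_gives_exact_effects_and_zero_sigma(self):
        design = build_design(g=2, n_levels=6, r=10, seed=0)
        y = 2.0 * design.rows[:, 0] + 3.0 * design.rows[:, 1]
        idx = aggregate_indices(elementary_effects(design, y))
        np.testing.assert_allclose(idx.mu_star, [2.0, 3.0], atol=1e-12)
        assert np.all(idx.sigma / idx.mu_star <= 1e-10)

    def test_constant_function_gives_zero_effects(self):
        design = build_design(g=3, n_levels=6, r=5, seed=1)
        idx = aggregate_indices(elementary_effects(design, np.ones(design.n_rows)))
        np.testing.assert_allclose(idx.mu_star, 0.0, atol=1e-14)
        np.testing.assert_allclose(idx.sigma, 0.0, atol=1e-14)

    def test_interaction_function_flags_sigma(self):
        design = build_design(g=2, n_levels=6, r=20, seed=5)
        y = design.rows[:, 0] * design.rows[:, 1]
        idx = aggregate_indices(elementary_effects(design, y))
        assert np.all(idx.sigma > 0)

    def test_product_effect_equals_partner_level(self):
        """For y = x1*x2, the effect of factor 0 equals the concurrent x2."""
        design = build_design(g=2, n_levels=6, r=6, seed=0)
        y = design.rows[:, 0] * design.rows[:, 1]
        ee = elementary_effects(design, y)
        for t in range(design.r):
            block = design.trajectory(t)
            for k in range(2):
                i = design.moved_factor[t, k]
                partner = block[k, 1 - i]  # unchanged during this transition
                assert ee.matrix[i, t] == pytest.approx(partner, abs=1e-12)

    def test_missing_outputs_warn_and_propagate(self):
        design = build_design(g=2, n_levels=6, r=3, seed=2)
        y = design.rows.sum(axis=1)
        y[1] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            ee = elementary_effects(design, y)
        assert np.isnan(ee.matrix).sum() > 0
        idx = aggregate_indices(ee)
        assert np.all(np.isfinite(idx.mu_star))
        assert idx.n_effects.min() >= 1

    def test_no_effects_for_a_factor_is_an_error(self):
        ee = ElementaryEffects(matrix=np.array([[1.0, 2.0], [np.nan, np.nan]]))
        with pytest.raises(ValueError):
            aggregate_indices(ee)


class TestAggregation:
    def test_constant_effects(self):
        idx = aggregate_indices(ElementaryEffects(np.array([[2.0, 2.0, 2.0]])))
        assert idx.mu_star[0] == pytest.approx(2.0)
        assert idx.sigma[0] == pytest.approx(0.0)

    def test_signed_cancellation(self):
        idx = aggregate_indices(ElementaryEffects(np.array([[-1.0, 1.0]])))
        assert idx.mu_star[0] == pytest.approx(1.0)
        assert idx.sigma[0] == pytest.approx(np.sqrt(2.0))

    def test_matches_textbook_moments(self):
        rng = np.random.default_rng(0)
        eff = rng.normal(size=(1, 50))
        idx = aggregate_indices(ElementaryEffects(eff))
        assert idx.mu_star[0] == pytest.approx(np.abs(eff).mean())
        assert idx.sigma[0] == pytest.approx(eff.std(ddof=1))


class TestStandardization:
    def test_three_point_example(self):
        df = pd.DataFrame({"environment": ["e"] * 3, "y": [1.0, 2.0, 3.0]})
        out = standardize_by_environment(df, ["y"])
        np.testing.assert_allclose(out["y"], [-1.0, 0.0, 1.0])

    def test_constant_outputs_standardize_to_zero(self):
        df = pd.DataFrame({"environment": ["e"] * 4, "y": [5.0] * 4})
        out = standardize_by_environment(df, ["y"])
        np.testing.assert_allclose(out["y"], 0.0)

    def test_environments_standardized_independently(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "environment": ["a"] * 40 + ["b"] * 40,
            "y": np.r_[rng.normal(10, 2, 40), rng.normal(-4, 0.5, 40)],
        })
        out = standardize_by_environment(df, ["y"])
        for _, sub in out.groupby("environment"):
            assert sub["y"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["y"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_single_genotype_environment_rejected(self):
        df = pd.DataFrame({"environment": ["a", "b", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            standardize_by_environment(df, ["y"])
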