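"""Pairwise correlation screen: statistics, grid layout, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from remethyl import correlations, synthetic, tanh_fit
from remethyl.correlations import (
    aggregate_by_cell_line,
    headline_tests,
    p_value_grid,
    pairwise_correlations,
    spearman_exact_p,
)


def frame(**cols):
    return pd.DataFrame(cols)


class TestPairwise:
    def test_perfect_affine_relation(self):
        x = np.arange(10.0)
        res = pairwise_correlations(frame(a=x, b=2 * x + 1), ["a", "b"])
        off = next(r for r in res if r.pair == ("a", "b"))
        assert off.pearson_r == pytest.approx(1.0)
        assert off.spearman_rho == pytest.approx(1.0)
        assert off.slope == pytest.approx(2.0)
        assert off.intercept == pytest.approx(1.0)

    def test_spearman_hand_computed_rank_formula(self):
        # d^2 sums to 4: rho = 1 - 6*4/(5*24) = 0.8
        res = pairwise_correlations(
            frame(x=[1, 2, 3, 4, 5], y=[2, 1, 4, 3, 5]), ["x", "y"], include_diagonal=False
        )[0]
        assert res.spearman_rho == pytest.approx(0.8)

    def test_monotone_nonlinear_relation(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = pairwise_correlations(frame(x=x, y=x**3), ["x", "y"], include_diagonal=False)[0]
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.pearson_r < 1.0

    def test_diagonal_pairs(self):
        res = pairwise_correlations(frame(a=np.arange(5.0)), ["a"])
        assert res[0].pearson_r == 1.0 and res[0].p_pearson == 0.0

    def test_pvalues_match_t_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=18), rng.normal(size=18)
        res = pairwise_correlations(frame(x=x, y=y), ["x", "y"], include_diagonal=False)[0]
        r, p_ref = stats.pearsonr(x, y)
        assert res.pearson_r == pytest.approx(r)
        assert res.p_pearson == pytest.approx(p_ref, rel=1e-10)

    def test_constant_column_flagged_missing(self):
        res = pairwise_correlations(
            frame(a=np.arange(6.0), c=np.ones(6)), ["a", "c"], include_diagonal=False
        )[0]
        assert not res.defined
        assert np.isnan(res.p_pearson)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pearson_affine_and_spearman_monotone_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = pairwise_correlations(frame(x=x, y=y), ["x", "y"], include_diagonal=False)[0]
        aff = pairwise_correlations(
            frame(x=scale * x + shift, y=y), ["x", "y"], include_diagonal=False
        )[0]
        mono = pairwise_correlations(
            frame(x=np.exp(x / 5.0), y=y), ["x", "y"], include_diagonal=False
        )[0]
        assert aff.pearson_r == pytest.approx(base.pearson_r, abs=1e-9)
        assert mono.spearman_rho == pytest.approx(base.spearman_rho, abs=1e-12)

    def test_exact_spearman_permutation_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        p = spearman_exact_p(x, y)
        # enumerated null: P(|rho| >= observed) over all 720 permutations
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        import itertools
        hits = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert p == pytest.approx(hits / 720)


class TestGrid:
    def test_symmetric_zero_diagonal_with_signs(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        table = frame(a=x, b=-3 * x + rng.normal(size=20) * 0.1, c=rng.normal(size=20))
        res = pairwise_correlations(table, ["a", "b", "c"])
        grid, signs = p_value_grid(res, ["a", "b", "c"])
        assert np.allclose(grid.values, grid.values.T, equal_nan=True)
        assert np.all(np.diag(grid.values) == 0.0)
        assert signs.loc["a", "b"] == "-" and signs.loc["b", "a"] == "-"

    def test_planted_panels_make_rate_baseline_cell_significant_negative(self):
        """Monte-Carlo over seeded panels: the screen detects the planted
        negative rate-baseline association in the (m, B) cell in the
        clear majority of panels, and always with a negative sign when
        significant."""
        detected = 0
        for seed in range(10):
            panel = synthetic.generate_methylation_panel(synthetic.PanelConfig(seed=seed))
            analyzed = tanh_fit.analyze_panel(panel)
            table = pd.DataFrame([s.__dict__ for *_, s in analyzed if s is not None])
            res = pairwise_correlations(table, ["m", "B"])
            grid, signs = p_value_grid(res, ["m", "B"])
            if grid.loc["m", "B"] < 0.05:
                assert signs.loc["m", "B"] == "-"
                detected += 1
        assert detected >= 7


class TestAggregation:
    def test_singleton_and_arithmetic_means(self):
        table = frame(cell_line=["A", "B", "B"], m=[0.5, 0.1, 0.3], B=[10.0, 20.0, 40.0])
        agg = aggregate_by_cell_line(table, ["m", "B"]).set_index("cell_line")
        assert agg.loc["A", "m"] == pytest.approx(0.5)
        assert agg.loc["B", "m"] == pytest.approx(0.2)
        assert agg.loc["B", "B"] == pytest.approx(30.0)
        assert agg.loc["A", "n_runs"] == 1 and agg.loc["B", "n_runs"] == 2


class TestHeadline:
    def test_planted_negative_rate_baseline_and_induced_rate_onset(self):
        panel = synthetic.generate_methylation_panel(synthetic.PanelConfig(seed=42))
        analyzed = tanh_fit.analyze_panel(panel)
        table = pd.DataFrame([s.__dict__ for *_, s in analyzed if s is not None])
        hl = headline_tests(table)
        assert hl["m_vs_B"].pearson_r < 0           # planted negative correlation
        assert hl["m_vs_b"].pearson_r > 0           # b = m*b' induces co-variation
        assert hl["b_vs_B"].pearson_r < 0
        assert set(hl) == {"m_vs_B", "b_vs_B", "m_vs_b", "b_prime_vs_B"}

    def test_null_quantities_give_small_r(self):
        rng = np.random.default_rng(9)
        n = 200
        table = frame(
            m=rng.normal(size=n), b=rng.normal(size=n), b_prime=rng.normal(size=n),
            B=rng.normal(size=n),
        )
        hl = headline_tests(table)
        assert all(abs(r.pearson_r) < 0.2 for r in hl.values())


class TestCalibration:
    def test_type_one_error_near_alpha(self):
        """Under independence, the Pearson test rejects at ~5%."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(size=18), rng.normal(size=18)
            res = pairwise_correlations(frame(x=x, y=y), ["x", "y"], include_diagonal=False)[0]
            rejections += res.p_pearson < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_power_matches_fisher_z_approximation(self):
        """Power at rho = -0.5, n = 18 agrees with the Fisher-z estimate."""
        rho, n, alpha = -0.5, 18, 0.05
        z = np.arctanh(abs(rho)) * np.sqrt(n - 3)
        power_fisher = stats.norm.sf(stats.norm.isf(alpha / 2) - z)  # ~0.57
        rng = np.random.default_rng(99)
        cov = [[1.0, rho], [rho, 1.0]]
        rejections = 0
        reps = 2000
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = pairwise_correlations(
                frame(x=xy[:, 0], y=xy[:, 1]), ["x", "y"], include_diagonal=False
            )[0]
            rejections += res.p_pearson < alpha
        assert abs(rejections / reps - power_fisher) < 0.05
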