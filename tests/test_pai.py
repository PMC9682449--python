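"""PAI arithmetic, moderation inference, recommendation zones, percentile
translation, and the single-predictor comparison model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paikit import pai
from paikit.pai import (
    assign_zones,
    bootstrap_intersection,
    comparison_model_pai,
    compute_pai,
    intersection_point,
    johnson_neyman,
    percentile_translation,
    pooled_sd,
    recommend,
)

moderation_fit = pai.test_moderation  # avoid pytest collecting the library name


def interaction_data(rng, n=400, a=0.0, g=1.0, b=2.0, b_int=3.0, noise=0.01):
    x = rng.standard_normal(n)
    grp = rng.integers(0, 2, n).astype(float)
    y = a + g * grp + b * x + b_int * grp * x + noise * rng.standard_normal(n)
    return y, grp, x


class TestScores:
    def test_worked_example_difference(self):
        # predicted slopes -0.049 (treatment) and 0.047 (control) -> -0.10
        pai_score = compute_pai([-0.049], [0.047])[0]
        assert pai_score == pytest.approx(-0.096)
        assert round(pai_score, 2) == -0.10

    def test_antisymmetry_and_zero(self):
        a, b = np.array([0.1, -0.2]), np.array([0.0, 0.3])
        assert np.allclose(compute_pai(a, b), -compute_pai(b, a))
        assert np.allclose(compute_pai(a, a), 0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_pai([1.0], [1.0, 2.0])

    def test_recommendations(self):
        assert recommend([-0.07])[0] == "treatment"
        assert recommend([0.0])[0] == "control"  # tie -> conservative
        assert recommend([-0.1, 0.01]).tolist() == ["treatment", "control"]


class TestModeration:
    def test_recovers_constructed_coefficients(self):
        rng = np.random.default_rng(0)
        y, grp, x = interaction_data(rng, a=0.0, g=1.0, b=2.0, b_int=3.0, noise=0.05)
        rep = moderation_fit(y, grp, x)
        assert rep.coef["group"] == pytest.approx(1.0, abs=0.05)
        assert rep.coef["pai"] == pytest.approx(2.0, abs=0.05)
        assert rep.coef["group_x_pai"] == pytest.approx(3.0, abs=0.05)
        assert rep.interaction_p < 1e-10

    def test_matches_normal_equations_on_hand_example(self):
        # 6-row design solved directly via textbook matrix formulas
        y = np.array([0.1, 0.4, -0.2, 0.3, 0.8, -0.5])
        grp = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        x = np.array([0.5, -0.3, 1.2, 0.0, -1.0, 0.7])
        X = np.column_stack([np.ones(6), grp, x, grp * x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        cov = (resid @ resid) / 2 * np.linalg.inv(X.T @ X)
        rep = moderation_fit(y, grp, x)
        for i, nm in enumerate(["intercept", "group", "pai", "group_x_pai"]):
            assert rep.coef[nm] == pytest.approx(beta[i], abs=1e-10)
            assert rep.se[nm] == pytest.approx(np.sqrt(cov[i, i]), rel=1e-10)
        assert rep.df_resid == 2

    def test_type_one_error_calibrated_with_exogenous_moderator(self):
        rng = np.random.default_rng(42)
        rej = 0
        reps = 1000
        for _ in range(reps):
            n = 100
            y = rng.standard_normal(n)
            grp = np.repeat([0.0, 1.0], n // 2)
            x = rng.standard_normal(n)
            rej += moderation_fit(y, grp, x).interaction_p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.015)

    def test_constant_pai_and_single_group_rejected(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30)
        grp = np.repeat([0.0, 1.0], 15)
        with pytest.raises(ValueError, match="constant"):
            moderation_fit(y, grp, np.ones(30))
        with pytest.raises(ValueError, match="group"):
            moderation_fit(y, np.zeros(30), rng.standard_normal(30))

    def test_covariate_adjustment_accepted(self):
        rng = np.random.default_rng(2)
        y, grp, x = interaction_data(rng, noise=0.1)
        z = rng.standard_normal(len(y))
        rep = moderation_fit(y, grp, x, covariates=z)
        assert "cov1" in rep.coef
        assert rep.df_resid == len(y) - 5


class TestIntersection:
    def _report(self, a_c, b_c, a_t, b_t):
        rep = moderation_fit(*interaction_data(np.random.default_rng(0), noise=0.01))
        rep.coef = {
            "intercept": a_c, "group": a_t - a_c, "pai": b_c, "group_x_pai": b_t - b_c,
        }
        return rep

    def test_symmetric_lines_cross_at_zero(self):
        assert intersection_point(self._report(0, 1, 0, -1)) == pytest.approx(0.0)

    def test_hand_solved_crossing(self):
        # y = 1 + 2x vs y = 3x cross at x = 1
        assert intersection_point(self._report(1, 2, 0, 3)) == pytest.approx(1.0)

    def test_parallel_lines_error(self):
        with pytest.raises(ValueError, match="parallel"):
            intersection_point(self._report(0, 1, 1, 1))


class TestBootstrap:
    def test_degenerate_exact_data_gives_point_interval(self):
        # exact lines, balanced single-type rows per group/level: every
        # resample that retains both groups refits the same lines
        x = np.tile([-1.0, 1.0], 40)
        grp = np.repeat([0.0, 1.0], 40)
        y = 1.0 * grp + 2.0 * x + 3.0 * grp * x
        out = bootstrap_intersection(y, grp, x, B=200, rng=0)
        assert out["lower"] == pytest.approx(out["upper"], abs=1e-8)
        assert out["lower"] == pytest.approx(-1 / 3, abs=1e-8)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        y, grp, x = interaction_data(rng, noise=0.5)
        rep = moderation_fit(y, grp, x)
        out = bootstrap_intersection(y, grp, x, B=500, rng=1)
        assert out["lower"] <= rep.intersection <= out["upper"]
        assert not out["unreliable"]

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_intersection([1.0], [0.0], [0.0], B=10)


class TestJohnsonNeyman:
    def test_boundaries_match_grid_scan(self):
        rng = np.random.default_rng(4)
        y, grp, x = interaction_data(rng, g=0.3, b=0.5, b_int=0.8, noise=1.0)
        rep = moderation_fit(y, grp, x)
        jn = johnson_neyman(rep, alpha=0.05)

        grid = np.linspace(rep.pai_range[0], rep.pai_range[1], 10_001)
        diff = rep.coef["group"] + rep.coef["group_x_pai"] * grid
        se = np.sqrt(
            rep.se["group"] ** 2
            + 2 * grid * rep.cov_g_int
            + grid**2 * rep.se["group_x_pai"] ** 2
        )
        tcrit = stats.t.ppf(0.975, rep.df_resid)
        sig = np.abs(diff / se) > tcrit
        crossings = grid[:-1][np.diff(sig.astype(int)) != 0]
        assert len(jn["boundaries"]) == len(crossings)
        step = grid[1] - grid[0]
        for b, c in zip(jn["boundaries"], crossings):
            assert abs(b - c) <= 2 * step

    def test_no_effect_flags_nowhere_significant(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(200)
        grp = np.repeat([0.0, 1.0], 100)
        x = rng.standard_normal(200)
        rep = moderation_fit(y, grp, x)
        if abs(rep.coef["group"] / rep.se["group"]) < 1:  # typical draw
            jn = johnson_neyman(rep, alpha=0.05)
            assert jn["boundaries"] == [] or all(
                f == "nonsignificant" for f in jn["interval_flags"]
            )

    def test_boundary_lies_on_treatment_favoring_side(self):
        # geometry of a typical recommendation plot: strong moderation, treatment
        # better at negative PAI; the JN cut sits left of the intersection
        rng = np.random.default_rng(6)
        n = 600
        x = rng.normal(-0.07, 0.04, n)
        grp = rng.integers(0, 2, n).astype(float)
        y = 0.01 + 0.02 * grp + 0.3 * x + 1.0 * grp * x + 0.08 * rng.standard_normal(n)
        rep = moderation_fit(y, grp, x)
        jn = johnson_neyman(rep, alpha=0.05)
        left = [b for i, b in enumerate(jn["boundaries"]) if jn["interval_flags"][i] == "significant"]
        assert left, "expected a significant region at negative PAI"
        assert left[0] < rep.intersection


class TestZones:
    def test_worked_example_layout(self):
        # PAI -0.10 with intersection -0.004, CI margin -0.03, JN -0.02
        zones = assign_zones([-0.10], -0.004, -0.03, -0.02)
        assert zones[0] == "green"

    def test_tie_and_between_rules(self):
        zones = assign_zones([-0.004, -0.01, 0.5], -0.004, -0.03, -0.02)
        assert zones.tolist() == ["red", "yellow", "red"]

    def test_partition_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(7)
        pai_vals = rng.normal(0, 1, 1000)
        zones = assign_zones(pai_vals, 0.1, -0.2, -0.3)
        assert set(zones) <= {"green", "yellow", "red"}
        green = pai_vals < -0.3
        red = pai_vals >= 0.1
        assert (zones[green] == "green").all()
        assert (zones[red] == "red").all()
        assert (zones[~green & ~red] == "yellow").all()

    def test_missing_jn_degrades_to_yellow_red(self):
        zones = assign_zones([-10.0, 0.5], 0.0, -0.5, None)
        assert zones.tolist() == ["yellow", "red"]


class TestPercentiles:
    def test_reference_worked_examples(self):
        sd = pooled_sd([0.88, 0.91], [342, 315])
        assert sd == pytest.approx(0.895, abs=0.001)
        assert percentile_translation(-0.049, 4, sd, 50) == 41
        assert percentile_translation(0.047, 4, sd, 50) == 58

    def test_zero_slope_identity(self):
        assert percentile_translation(0.0, 4, 0.9, 37) == 37

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percentile_translation(0.1, 4, 0.0, 50)
        with pytest.raises(ValueError):
            percentile_translation(0.1, 4, 1.0, 100)


class TestComparisonModel:
    def test_null_predictor_mean_pai_matches_arm_difference(self):
        rng = np.random.default_rng(8)
        n = 2000
        grp = np.repeat([0, 1], n // 2)
        y = -0.05 * grp + 0.1 * rng.standard_normal(n)
        x = rng.standard_normal(n)
        table, _ = comparison_model_pai(x, y, grp, k=10, repeats=5, rng=1)
        arm_diff = y[grp == 1].mean() - y[grp == 0].mean()
        assert table["pai"].mean() == pytest.approx(arm_diff, abs=0.01)

    def test_opposite_arm_slopes_recovered(self):
        # higher predictor -> better treatment outcome, worse control outcome
        rng = np.random.default_rng(9)
        n = 600
        grp = np.repeat([0, 1], n // 2)
        x = rng.standard_normal(n)
        y = np.where(grp == 1, -0.03 * x, 0.02 * x) + 0.05 * rng.standard_normal(n)
        table, report = comparison_model_pai(x, y, grp, repeats=10, rng=2)
        assert report["treatment"]["slope"] < 0 < report["control"]["slope"]
        assert report["treatment"]["p"] < 0.01 and report["control"]["p"] < 0.01
        # recommendation follows predictor ordering
        assert table.loc[np.argmax(x), "pai"] < table.loc[np.argmin(x), "pai"]

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        grp = np.repeat([0, 1], 50)
        t1, _ = comparison_model_pai(x, y, grp, k=5, repeats=3, rng=7)
        t2, _ = comparison_model_pai(x, y, grp, k=5, repeats=3, rng=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_k_exceeding_arm_size_rejected(self):
        with pytest.raises(ValueError, match="k="):
            comparison_model_pai(
                np.arange(8.0), np.arange(8.0), np.repeat([0, 1], 4), k=10, repeats=1, rng=0
            )


class TestPlot:
    def test_zone_figure_written(self, tmp_path):
        rng = np.random.default_rng(11)
        y, grp, x = interaction_data(rng, n=120, noise=0.5)
        rep = moderation_fit(y, grp, x)
        rep.ci_lower = rep.intersection - 0.2
        rep.jn_boundaries = [rep.intersection - 0.1]
        out = pai.plot_zones(rep, x, y, grp, tmp_path / "zones.png")
        assert (tmp_path / "zones.png").stat().st_size > 0
        assert str(out).endswith("zones.png")


class TestBuildTable:
    def test_own_and_counterfactual_orientation(self):
        preds = pd.DataFrame(
            {
                "id": ["a", "b"],
                "arm": ["treatment", "control"],
                "pred_own_arm": [-0.05, 0.02],
                "pred_other_arm": [0.01, -0.03],
            }
        )
        table = pai.build_pai_table(preds)
        assert table.loc[0, "pred_treat"] == -0.05 and table.loc[0, "pred_control"] == 0.01
        assert table.loc[1, "pred_treat"] == -0.03 and table.loc[1, "pred_control"] == 0.02
        assert np.allclose(table["pai"], table["pred_treat"] - table["pred_control"])
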