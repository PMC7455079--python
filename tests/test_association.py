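"""Stepwise logistic odds-ratio framework: serology grouping, collinearity
screen, logistic/score/Hosmer–Lemeshow machinery, OR edge mapping, OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lupusmod.association import (
    PREDICTOR_COLUMNS,
    autoantibody_group,
    build_predictor_matrix,
    hosmer_lemeshow,
    logistic_fit,
    or_to_edge,
    simple_linear_fit,
    spearman_screen,
    stepwise_select,
)


class TestSerologyGroups:
    @pytest.mark.parametrize("flags,expected", [
        ((1, 1, 0, 1, 0), "rnp_pos_dsdna_pos"),
        ((1, 0, 1, 0, 0), "rnp_pos_dsdna_neg"),
        ((0, 1, 0, 0, 1), "rnp_neg_dsdna_pos"),
        ((0, 0, 1, 0, 0), "sm_ssa_ssb_only"),
        ((0, 0, 0, 1, 1), "sm_ssa_ssb_only"),
        ((0, 0, 0, 0, 0), "seronegative"),
        ((1, 1, 1, 1, 1), "rnp_pos_dsdna_pos"),
    ])
    def test_mapping(self, flags, expected):
        rnp, dsdna, sm, ssa, ssb = flags
        assert autoantibody_group(rnp, dsdna, sm, ssa, ssb) == expected

    def test_predictor_matrix_has_26_exclusive_columns(self, small_cohort):
        metadata, _, _ = small_cohort
        X = build_predictor_matrix(metadata)
        assert list(X.columns) == list(PREDICTOR_COLUMNS)
        assert X.shape[1] == 26
        assert set(np.unique(X.to_numpy())) <= {0, 1}
        sero = X[[c for c in X.columns if c.startswith("sero_")]]
        assert (sero.sum(axis=1) <= 1).all()
        # controls excluded
        assert not set(metadata.index[metadata["is_control"] == 1]) & \
            set(X.index)


class TestSpearmanScreen:
    def test_monotone_transform_gives_rho_one(self):
        x = np.arange(30, dtype=float)
        X = pd.DataFrame({"x": x, "y": np.exp(x / 10)})
        rho, drops = spearman_screen(X)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert drops == ["y"]

    def test_independent_binaries_not_flagged(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, (2000, 6)).astype(float),
                         columns=[f"c{i}" for i in range(6)])
        _, drops = spearman_screen(X)
        assert drops == []

    def test_engineered_rho_above_half_flagged(self, rng):
        # a pair built to sit near rho ~ 0.54, just over the 0.5 threshold
        n = 4000
        a = rng.integers(0, 2, n)
        flip = rng.random(n) < 0.23
        b = np.where(flip, 1 - a, a)
        X = pd.DataFrame({"naa": a.astype(float), "hispanic": b.astype(float),
                          "other": rng.integers(0, 2, n).astype(float)})
        rho, drops = spearman_screen(X)
        assert 0.5 < rho.loc["naa", "hispanic"] < 0.6
        assert drops == ["hispanic"]

    def test_constant_column_warns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 1, 1, 1]})
        with pytest.warns(UserWarning, match="constant"):
            spearman_screen(X)


class TestLogisticFit:
    def test_saturated_two_by_two_equals_cross_product_or(self):
        # counts [[40,10],[20,30]] -> OR = 40*30/(10*20) = 6
        y = np.r_[np.ones(40), np.zeros(10), np.ones(20), np.zeros(30)]
        x = np.r_[np.ones(50), np.zeros(50)]
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        assert fit.table.loc["x", "or"] == pytest.approx(6.0, rel=1e-6)
        assert fit.table.loc["x", "ci_low"] < 6.0 < fit.table.loc["x", "ci_high"]

    def test_independent_outcome_gives_uniform_p(self, rng):
        pvals = []
        for _ in range(200):
            y = rng.integers(0, 2, 300)
            x = rng.integers(0, 2, 300).astype(float)
            pvals.append(logistic_fit(y, pd.DataFrame({"x": x}))
                         .table.loc["x", "p"])
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.04)

    def test_intercept_only_balanced(self):
        y = np.r_[np.ones(25), np.zeros(25)]
        fit = logistic_fit(y, None)
        assert fit.table.loc["const", "coef"] == pytest.approx(0.0, abs=1e-8)

    def test_perfect_separation_rejected(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()
        with pytest.raises(ValueError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestStepwise:
    def test_planted_predictor_recovered(self, rng):
        hits, cover = 0, 0
        n_rep = 20
        for _ in range(n_rep):
            n = 2000
            X = pd.DataFrame(
                rng.integers(0, 2, (n, 10)).astype(float),
                columns=[f"x{i}" for i in range(10)],
            )
            logit = -1.0 + 1.5 * X["x0"]
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
            res = stepwise_select(pd.Series(y), X)
            if "x0" in res.selected:
                hits += 1
                lo = res.table.loc["x0", "ci_low"]
                hi = res.table.loc["x0", "ci_high"]
                cover += lo < np.exp(1.5) < hi
        assert hits == n_rep
        assert cover / hits >= 0.9

    def test_duplicate_column_enters_once(self, rng):
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        logit = -0.5 + 1.2 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = pd.DataFrame({"a": x, "a_copy": x.copy()})
        res = stepwise_select(pd.Series(y), X)
        assert len(res.selected) == 1
        assert res.selected[0] in ("a", "a_copy")

    def test_no_candidate_enters_flags_intercept_only(self, rng):
        y = pd.Series(rng.integers(0, 2, 200))
        X = pd.DataFrame({"x": rng.integers(0, 2, 200).astype(float)})
        res = stepwise_select(y, X, p_enter=1e-9)  # nothing can enter
        assert res.intercept_only and res.selected == []

    def test_entry_with_p_enter_one_ranks_by_score_p(self, rng):
        n = 800
        X = pd.DataFrame({
            "strong": rng.integers(0, 2, n).astype(float),
            "weak": rng.integers(0, 2, n).astype(float),
        })
        logit = -0.5 + 1.5 * X["strong"] + 0.3 * X["weak"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int))
        res = stepwise_select(y, X, p_enter=1.0, p_remove=1.0)
        assert res.selected[0] == "strong"


class TestHosmerLemeshow:
    def test_calibrated_fits_reject_near_nominal(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 500
            x = rng.normal(0, 1, n)
            p_true = 1 / (1 + np.exp(-(0.2 + 0.8 * x)))
            y = (rng.random(n) < p_true).astype(float)
            fit = logistic_fit(y, pd.DataFrame({"x": x}))
            _, _, p = hosmer_lemeshow(y, fit.fitted.to_numpy())
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.045)

    def test_miscalibrated_fits_rejected(self, rng):
        n = 800
        x = rng.normal(0, 1, n)
        p_true = 1 / (1 + np.exp(-(1.5 * x)))
        y = (rng.random(n) < p_true).astype(float)
        _, _, p = hosmer_lemeshow(y, 1 - p_true)  # inverted probabilities
        assert p < 1e-6

    def test_df_is_groups_minus_two(self, rng):
        n = 300
        p_fit = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < p_fit).astype(float)
        stat, df, p = hosmer_lemeshow(y, p_fit, g=10)
        assert df == 8
        assert p == pytest.approx(stats.chi2.sf(stat, 8))

    def test_too_few_groups_rejected(self, rng):
        y = np.array([0, 1] * 10, dtype=float)
        p = np.linspace(0.1, 0.9, 20)
        with pytest.raises(ValueError, match="g >= 3"):
            hosmer_lemeshow(y, p, g=2)


class TestOrEdges:
    @pytest.mark.parametrize("or_value,width,direction", [
        (31.6, 20, "positive"),   # strongest printed serology association
        (4.8, 10, "positive"),    # AZA to low NK signatures
        (3.8, 10, "positive"),
        (0.394, 5, "negative"),   # 1/0.394 = 2.538 -> [2,3) band
        (0.211, 10, "negative"),  # 1/0.211 = 4.74
        (1.0, 1, "positive"),
        (1.99, 1, "positive"),
        (2.0, 5, "positive"),
        (9.999, 10, "positive"),
        (10.0, 20, "positive"),
    ])
    def test_interval_rule(self, or_value, width, direction):
        e = or_to_edge("pred", "out", or_value)
        assert e.width_pt == width
        assert e.direction == direction
        assert e.display_or >= 1

    def test_display_or_reciprocal(self):
        e = or_to_edge("p", "o", 0.394)
        assert e.display_or == pytest.approx(1 / 0.394)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_reciprocal_symmetry(self, or_value):
        a = or_to_edge("p", "o", or_value)
        b = or_to_edge("p", "o", 1.0 / or_value)
        assert a.width_pt == b.width_pt
        if not np.isclose(or_value, 1.0):
            assert a.direction != b.direction

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            or_to_edge("p", "o", 0.0)
        with pytest.raises(ValueError):
            or_to_edge("p", "o", -2.0)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        fit = simple_linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_three_point_hand_case(self):
        fit = simple_linear_fit([1, 2, 3], [1, 3, 2])
        assert fit.slope == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(0.25)

    def test_independent_data_r2_near_zero(self, rng):
        fit = simple_linear_fit(rng.normal(0, 1, 5000), rng.normal(0, 1, 5000))
        assert fit.r_squared < 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
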