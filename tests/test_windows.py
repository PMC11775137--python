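"""Window construction, OLS, posterior simulation, Spearman, classing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sedarange as sr
from sedarange.windows import (EmptyWindowError, SingularFitError,
                               UndefinedCorrelationError, Window,
                               classify_relationship, fit_linear,
                               make_windows, posterior_sim, spearman,
                               window_points)


class TestMakeWindows:
    def test_default_count_is_26(self):
        assert len(make_windows(30, 5)) == 26

    def test_age_span_label(self):
        assert Window((19, 20, 21, 22, 23)).label == "23–19ka"
        assert Window((18, 19, 20, 21, 22)).label == "22–18ka"

    def test_full_width_single_window(self):
        assert len(make_windows(30, 30)) == 1

    def test_width_exceeding_slices_raises(self):
        with pytest.raises(ValueError):
            make_windows(5, 6)

    def test_membership_order_stable(self):
        wins = make_windows(8, 3, 2)
        assert [w.slices for w in wins] == [(1, 2, 3), (3, 4, 5), (5, 6, 7)]


class TestWindowPoints:
    def test_complete_window_has_iterations_times_slices_points(self, default_run):
        cfg, rs, summ = default_run
        x, y = window_points(summ, make_windows(30, 5)[0])
        assert len(x) == 5 * cfg.n_iterations == 500

    def test_missing_slice_reduces_points(self, default_run):
        cfg, rs, summ = default_run
        drop = summ[summ.slice_index != 3]
        x, _ = window_points(drop, make_windows(30, 5)[0])
        assert len(x) == 400

    def test_all_missing_raises(self, default_run):
        cfg, rs, summ = default_run
        empty = summ[summ.slice_index > 5]
        with pytest.raises(EmptyWindowError):
            window_points(empty, make_windows(30, 5)[0])


def ols_oracle(x, y):
    """Normal equations evaluated in extended precision."""
    x = np.asarray(x, np.longdouble)
    y = np.asarray(y, np.longdouble)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


class TestFitLinear:
    def test_collinear_points_interpolated(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_cross_has_zero_slope(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([-1.0, 1.0, -1.0, 1.0])
        assert fit_linear(x, y).slope == pytest.approx(0.0, abs=1e-14)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=50)
            y = 1.5 * x + rng.normal(size=50)
            fit = fit_linear(x, y)
            slope, intercept = ols_oracle(x, y)
            assert abs(fit.slope - slope) <= 1e-10 * max(1, abs(slope))
            assert abs(fit.intercept - intercept) <= 1e-10 * max(1, abs(intercept))

    def test_constant_predictor_raises(self):
        with pytest.raises(SingularFitError):
            fit_linear(np.ones(5), np.arange(5.0))


class TestPosteriorSim:
    def test_perfect_fit_degenerates_to_point_mass(self, rng):
        x = np.arange(10.0)
        fit = fit_linear(x, 3 * x - 2)
        assert posterior_sim(fit, 50, rng) == pytest.approx(fit.slope, abs=1e-9)

    def test_draw_mean_unbiased(self, rng):
        x = rng.normal(size=200)
        fit = fit_linear(x, 2 * x + rng.normal(size=200))
        draws = posterior_sim(fit, 10_000, rng)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - fit.slope) < 3 * se

    def test_fixed_seed_reproducible(self):
        x = np.arange(20.0)
        fit = fit_linear(x, x + np.sin(x))
        a = posterior_sim(fit, 100, np.random.default_rng(5))
        b = posterior_sim(fit, 100, np.random.default_rng(5))
        assert (a == b).all()

    def test_rejects_nonpositive_draws(self, rng):
        fit = fit_linear(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            posterior_sim(fit, 0, rng)


def rank_by_hand(values):
    """Average-rank assignment computed by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(8.0)
        assert spearman(x, np.exp(x)) == (1.0, 0.0)
        assert spearman(x, -x ** 3) == (-1.0, 0.0)

    def test_tied_example_matches_hand_ranks(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5]
        y = [2, 1, 3, 3, 3, 5, 4, 6]
        r, _ = spearman(np.array(x, float), np.array(y, float))
        rx, ry = np.array(rank_by_hand(x)), np.array(rank_by_hand(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman(np.ones(5), np.arange(5.0))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=20, unique=True))
    def test_invariant_under_strictly_monotone_transforms(self, xs):
        x = np.asarray(xs)
        y = np.sin(x) + x / 50
        tx = np.exp(x / 100)
        # transforms must stay strictly monotone at float precision
        if np.ptp(y) == 0 or len(np.unique(tx)) < len(x) or len(np.unique(y)) < len(y):
            return
        r0, _ = spearman(x, y)
        r1, _ = spearman(tx, y)                        # monotone in x
        r2, _ = spearman(x, 5 * y + 2)                 # affine in y
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert r0 == pytest.approx(r2, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize("r,expected", [
        (0.5, "positive"), (-0.5, "negative"),
        (0.2, "indeterminate"), (-0.2, "indeterminate"), (0.0, "indeterminate"),
    ])
    def test_threshold_rule_is_strict(self, r, expected):
        assert classify_relationship(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_relationship(1.5)


def test_analyze_windows_sign_consistency(default_run):
    cfg, rs, summ = default_run
    for res in sr.analyze_windows(summ, cfg, n_draws=20):
        assert res.sign_class == classify_relationship(res.spearman_r,
                                                       cfg.r_class_threshold)
        assert res.n == 500
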