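"""Group abundances and the logistic-regression machinery."""

import numpy as np
import pandas as pd
import pytest

import sedarange as sr
from sedarange.interactions import (DegenerateResponseError, LogisticFit,
                                    SeparationError, fit_logistic_irls,
                                    group_abundance_series,
                                    interaction_analysis,
                                    window_group_medians)

from conftest import make_occurrence


def small_resample(rows, registry, base, n_slices=1):
    cfg = sr.RunConfig(base_count=base, n_iterations=1, n_slices=n_slices,
                       window_width_slices=min(5, n_slices))
    return sr.rarefy_dataset(make_occurrence(rows, registry), cfg)


class TestGroupAbundance:
    traits = sr.TraitTable({"Saxifragaceae": "cushion", "Pinaceae": "tree"})

    def test_all_cushion_reads_is_100_percent(self, toy_registry):
        rows = [("L1", 1, "A", "Saxifragaceae", 40)]
        rs = small_resample(rows, toy_registry, 40)
        out = group_abundance_series(rs, self.traits)
        assert out.cushion_pct.iloc[0] == 100.0
        assert out.tree_pct.iloc[0] == 0.0

    def test_quarter_cushion(self, toy_registry):
        rows = [("L1", 1, "A", "Saxifragaceae", 3),
                ("L1", 1, "B", "Poaceae", 9)]
        rs = small_resample(rows, toy_registry, 12)
        out = group_abundance_series(rs, self.traits)
        assert out.cushion_pct.iloc[0] == pytest.approx(25.0)

    def test_incidence_variant_counts_presences(self, toy_registry):
        rows = [("L1", 1, "A", "Saxifragaceae", 30),
                ("L1", 1, "B", "Poaceae", 30),
                ("L2", 1, "B", "Poaceae", 60)]
        cfg = sr.RunConfig(base_count=60, n_iterations=1, n_slices=1,
                           window_width_slices=1)
        rs = sr.rarefy_dataset(make_occurrence(rows, toy_registry), cfg)
        out = group_abundance_series(rs, self.traits, incidence=True)
        # 1 cushion presence of 3 presence records
        assert out.cushion_pct.iloc[0] == pytest.approx(100 / 3)

    def test_window_medians_shape(self, small_run, default_dataset):
        cfg, rs, _ = small_run
        _, _, traits, _ = default_dataset
        med = window_group_medians(group_abundance_series(rs, traits), cfg)
        assert set(med.window.unique()) == {w.label for w in
                                            sr.make_windows(30, 5)}
        assert len(med) == 26 * cfg.n_iterations


def grid_mle_oracle(y, x, span=8.0, passes=6, width=41):
    """Brute-force likelihood maximiser on a shrinking 2-D grid."""
    def ll(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    c0, c1, half = 0.0, 0.0, span
    for _ in range(passes):
        b0s = np.linspace(c0 - half, c0 + half, width)
        b1s = np.linspace(c1 - half, c1 + half, width)
        vals = np.array([[ll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        half *= 2.2 / (width - 1)  # keep a margin around the best cell
    return c0, c1


class TestLogisticIrls:
    def test_near_intercept_only_matches_grid_oracle(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < 0.3).astype(float)   # zero slope truth
        fit = fit_logistic_irls(y, x)
        b0, b1 = grid_mle_oracle(y, x)
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.slope == pytest.approx(b1, abs=1e-3)
        # and the intercept sits near logit of the base rate
        assert fit.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                              abs=0.5)

    def test_random_instance_matches_grid_oracle(self, rng):
        n = 100
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        fit = fit_logistic_irls(y, x)
        b0, b1 = grid_mle_oracle(y, x)
        assert fit.intercept == pytest.approx(b0, abs=1e-4)
        assert fit.slope == pytest.approx(b1, abs=1e-4)

    def test_perfect_separation_detected(self):
        with pytest.raises(SeparationError):
            fit_logistic_irls(np.array([0., 0., 1., 1.]),
                              np.array([-1., -1., 1., 1.]))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateResponseError):
            fit_logistic_irls(np.zeros(10), np.arange(10.0))

    def test_label_flip_negates_coefficients(self, rng):
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-x))).astype(float)
        f1 = fit_logistic_irls(y, x)
        f2 = fit_logistic_irls(1 - y, x)
        assert f2.slope == pytest.approx(-f1.slope, abs=1e-6)
        assert f2.intercept == pytest.approx(-f1.intercept, abs=1e-6)

    def test_predictor_rescaling_equivariance(self, rng):
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-x))).astype(float)
        f1 = fit_logistic_irls(y, x)
        f2 = fit_logistic_irls(y, 0.01 * x)
        assert f2.slope == pytest.approx(100 * f1.slope, rel=1e-6)
        assert f2.intercept == pytest.approx(f1.intercept, abs=1e-6)

    def test_final_gradient_norm_small(self, rng):
        x = rng.normal(size=150)
        y = (rng.uniform(size=150) < 1 / (1 + np.exp(-0.3 * x))).astype(float)
        fit = fit_logistic_irls(y, x)
        eta = fit.intercept + fit.slope * x
        p = 1 / (1 + np.exp(-eta))
        X = np.column_stack([np.ones_like(x), x])
        assert np.linalg.norm(X.T @ (y - p)) < 1e-6

    def test_matches_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm
        x = rng.normal(size=120)
        y = (rng.uniform(size=120) < 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(float)
        fit = fit_logistic_irls(y, x)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)


class TestInteractionAnalysis:
    def _units(self, sep=False):
        rng = np.random.default_rng(0)
        n = 60
        cls = np.where(rng.uniform(size=n) < 0.5, "positive", "negative")
        cushion = np.where(cls == "positive", 40.0, 15.0)
        if not sep:
            cushion = cushion + rng.normal(0, 15, n)  # overlapping classes
        tree = 60.0 - cushion + rng.normal(0, 5, n)
        win = [f"w{i}" for i in range(n)]
        classes = pd.DataFrame({"window": win, "iteration": 1,
                                "sign_class": cls})
        ab = pd.DataFrame({"window": win, "iteration": 1,
                           "cushion_pct": cushion, "tree_pct": tree})
        return classes, ab

    def test_sign_recovery_on_overlapping_units(self):
        classes, ab = self._units()
        fc, ft = interaction_analysis(classes, ab)
        assert fc.converged and ft.converged
        assert fc.slope > 0 and ft.slope < 0

    def test_separated_units_reported_with_determined_sign(self):
        classes, ab = self._units(sep=True)
        fc, ft = interaction_analysis(classes, ab)
        assert not fc.converged and fc.slope == np.inf
        assert not ft.converged and ft.slope == -np.inf
        with pytest.raises(SeparationError):
            interaction_analysis(classes, ab, allow_separation=False)

    def test_single_class_units_rejected(self):
        classes, ab = self._units()
        classes["sign_class"] = "positive"
        with pytest.raises(DegenerateResponseError):
            interaction_analysis(classes, ab)
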