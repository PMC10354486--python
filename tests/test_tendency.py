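import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from kitepeck.errors import DegenerateDesignError, FitError
from kitepeck.tendency import (
    TendencyGAM,
    classify_pattern,
    fit_tendency_model,
    predict_tendency_curves,
    split_side,
)


def _frame(delta, biomass, phase="1", brood=None, n_broods=3):
    n = len(delta)
    if brood is None:
        brood = [f"B{i % n_broods}" for i in range(n)]
    return pd.DataFrame(
        {
            "delta_days": delta,
            "biomass_g": biomass,
            "phase": phase,
            "brood_id": brood,
        }
    )


def _fit(X, y, **kw):
    return TendencyGAM(**kw).fit(X, y)


class TestTendencyGAM:
    def test_all_zero_response_predicts_zero(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.integers(-4, 1, 200), rng.uniform(20, 120, 200))
        model = _fit(X, np.zeros(200))
        pred = model.predict(_frame(np.arange(-4, 1), np.full(5, 60.0)))
        assert np.all(np.abs(pred) < 1e-6)

    def test_recovers_known_step_function(self):
        # deviation = 2 for |delta| <= 1, -1 for |delta| >= 3, with small noise
        rng = np.random.default_rng(1)
        delta = rng.integers(-5, 1, size=900)
        f = np.where(np.abs(delta) <= 1, 2.0, np.where(np.abs(delta) >= 3,
                                                       -1.0, 0.5))
        y = f + rng.normal(0, 0.1, size=delta.size)
        X = _frame(delta, np.full(delta.size, 50.0))
        model = _fit(X, y)
        grid = _frame(np.array([-5, -4, -3, -1, 0]), np.full(5, 50.0))
        pred = model.predict(grid)
        truth = np.array([-1.0, -1.0, -1.0, 2.0, 2.0])
        assert np.all(np.abs(pred - truth) < 0.3)

    def test_monotone_in_biomass_when_generated_so(self):
        rng = np.random.default_rng(2)
        delta = rng.integers(-4, 0, size=600)
        biomass = rng.uniform(10, 200, size=600)
        y = 0.05 * biomass + rng.normal(0, 0.5, size=600)
        model = _fit(_frame(delta, biomass), y)
        lo = model.predict(_frame([-2], [15.0]))
        hi = model.predict(_frame([-2], [190.0]))
        assert hi[0] > lo[0]

    def test_refit_reproduces_predictions(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.integers(-4, 1, 100), rng.uniform(20, 120, 100))
        y = rng.normal(size=100)
        grid = _frame([-3, -1], [50.0, 50.0])
        p1 = _fit(X, y).predict(grid)
        p2 = _fit(X, y).predict(grid)
        assert np.allclose(p1, p2)

    def test_degenerate_design_raises(self):
        X = _frame(np.full(30, -2), np.linspace(10, 100, 30))
        with pytest.raises(DegenerateDesignError):
            _fit(X, np.zeros(30))

    def test_sklearn_clone_compatible(self):
        model = TendencyGAM(delta_df=4)
        cloned = clone(model)
        assert cloned.get_params()["delta_df"] == 4

    def test_residual_mean_near_zero(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.integers(-4, 1, 300), rng.uniform(20, 120, 300))
        y = rng.normal(1.5, 1.0, size=300)
        model = _fit(X, y)
        assert abs(model.residual_mean_) < 0.2


def _dev_frame(delta, attacker, recipient, brood=None, deviation=0.0):
    n = len(delta)
    return pd.DataFrame(
        {
            "brood_id": brood if brood is not None else ["B1"] * n,
            "date": pd.NaT,
            "attacker_rank": attacker,
            "recipient_rank": recipient,
            "delta_days": delta,
            "biomass_g": 50.0,
            "phase": "1",
            "deviation": deviation,
        }
    )


class TestSplitSide:
    def test_zero_delta_assigned_by_hatch_order(self):
        dev = _dev_frame([0, 0], ["S", "M"], ["M", "S"])
        older = split_side(dev, "attacker_older")
        younger = split_side(dev, "attacker_younger")
        assert list(older["attacker_rank"]) == ["S"]
        assert list(younger["attacker_rank"]) == ["M"]

    def test_sides_partition_rows(self):
        rng = np.random.default_rng(0)
        delta = rng.integers(-4, 5, 50)
        dev = _dev_frame(delta, ["S"] * 50, ["M"] * 50)
        a = split_side(dev, "attacker_older")
        b = split_side(dev, "attacker_younger")
        assert len(a) + len(b) == 50

    def test_unknown_side(self):
        with pytest.raises(ValueError):
            split_side(_dev_frame([1], ["S"], ["M"]), "sideways")


class TestFitTendencyModel:
    def test_requires_two_broods_and_enough_rows(self):
        dev = _dev_frame([-1] * 30, ["S"] * 30, ["M"] * 30)
        with pytest.raises(FitError, match="brood"):
            fit_tendency_model(dev, "attacker_older")
        dev2 = _dev_frame([-1, -2], ["S", "S"], ["M", "J"],
                          brood=["B1", "B2"])
        with pytest.raises(FitError, match="20"):
            fit_tendency_model(dev2, "attacker_older")


class TestPredictTendencyCurves:
    def _fits(self, responses, n=4):
        rng = np.random.default_rng(0)
        fits = []
        for r in responses:
            X = _frame(rng.integers(-4, 1, 80), rng.uniform(20, 120, 80))
            fits.append(_fit(X, np.full(80, r)))
        return fits

    def test_identical_fits_zero_width(self):
        fits = self._fits([1.5, 1.5, 1.5])
        curves = predict_tendency_curves(fits, {"median": 60.0},
                                         np.arange(-4, 1))
        assert np.allclose(curves["lo95"], curves["hi95"])
        assert np.allclose(curves["mean"], curves["lo95"])

    def test_percentile_rule(self):
        # bootstrap predictions 1..100 at a point: mean 50.5 and, by linear
        # interpolation at the 2.5/97.5 percentiles, CI [3.475, 97.525]
        preds = np.arange(1, 101, dtype=float)
        lo, hi = np.percentile(preds, [2.5, 97.5])
        assert preds.mean() == pytest.approx(50.5)
        assert lo == pytest.approx(1 + 0.025 * 99)
        assert hi == pytest.approx(1 + 0.975 * 99)
        fits = self._fits(preds)
        curves = predict_tendency_curves(fits, {"median": 60.0}, [-2])
        assert curves["mean"].iloc[0] == pytest.approx(50.5, abs=0.01)
        assert curves["lo95"].iloc[0] == pytest.approx(3.475, abs=0.01)
        assert curves["hi95"].iloc[0] == pytest.approx(97.525, abs=0.01)

    def test_scale_factor_widens_symmetrically(self):
        fits = self._fits(np.arange(1, 101, dtype=float))
        plain = predict_tendency_curves(fits, {"median": 60.0}, [-2])
        wide = predict_tendency_curves(fits, {"median": 60.0}, [-2],
                                       scale_factor=2.0)
        m = plain["mean"].iloc[0]
        assert wide["lo95"].iloc[0] == pytest.approx(
            m + 2 * (plain["lo95"].iloc[0] - m)
        )

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            predict_tendency_curves([], {"median": 60.0}, [-2])

    def test_three_biomass_levels_emitted(self):
        fits = self._fits([0.0, 1.0, 2.0])
        levels = {"min": 20.0, "median": 60.0, "max": 110.0}
        curves = predict_tendency_curves(fits, levels, np.arange(-4, 1))
        assert set(curves["biomass_level"]) == {"min", "median", "max"}


def _curve(delta, lo, hi, side="attacker_older"):
    return pd.DataFrame(
        {
            "side": side,
            "delta_days": delta,
            "mean": (np.asarray(lo) + np.asarray(hi)) / 2,
            "lo95": lo,
            "hi95": hi,
        }
    )


class TestClassifyPattern:
    def test_all_zero_curve_is_downward_heuristic(self):
        curve = _curve([-4, -3, -2, -1], [-0.5] * 4, [0.5] * 4)
        assert classify_pattern(curve) == "downward_heuristic"

    def test_close_competitor_shape(self):
        # positive at delta -1, negative at the most negative delta
        curve = _curve([-4, -3, -2, -1], [-3, -1, -0.5, 1.0],
                       [-1, 0.5, 0.5, 3.0])
        assert classify_pattern(curve) == "close_competitor"

    def test_bullying_shape(self):
        curve = _curve([-4, -3, -2, -1], [1.0, -0.5, -0.5, -0.5],
                       [3.0, 0.5, 0.5, 0.5])
        assert classify_pattern(curve) == "bullying"

    def test_mixed_shape(self):
        curve = _curve([-4, -3, -2, -1], [1.0, -0.5, 1.0, -0.5],
                       [3.0, 0.5, 3.0, 0.5])
        assert classify_pattern(curve) == "mixed"

    def test_attacker_younger_rejected(self):
        curve = _curve([1, 2], [0, 0], [1, 1], side="attacker_younger")
        with pytest.raises(ValueError, match="attacker_older"):
            classify_pattern(curve)
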