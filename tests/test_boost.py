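"""Boosting: offset models, shrinkage, selection, early stopping, prediction."""

import numpy as np
import pandas as pd
import pytest

from savannagrad.boost import (
    BaseLearnerSpec,
    BoostModel,
    boost_fit,
    build_base_learners,
    cv_tune,
    predict,
)
from savannagrad.families import family_from_name


def _gaussian_toy(rng, n=300, slope=2.0, intercept=1.5, noise=1.0):
    x = rng.normal(size=n)
    y = intercept + slope * x + rng.normal(0, noise, n)
    return pd.DataFrame({"x": x, "y": y})


def _toy_specs(extra=()):
    return [
        BaseLearnerSpec("mu", "intercept"),
        BaseLearnerSpec("sigma", "intercept"),
        BaseLearnerSpec("mu", "linear", "x"),
        *extra,
    ]


class TestBuildBaseLearners:
    def test_counts_per_cell(self, rng):
        df = pd.DataFrame({
            "a": rng.normal(size=40), "b": rng.normal(size=40),
            "flag": rng.integers(0, 2, 40), "year": np.repeat([1999, 2002], 20),
        })
        fam = family_from_name("gaussian")
        specs = build_base_learners(df, fam, metric_predictors=["a", "b"],
                                    binary_predictors=["flag"], grouping=["year"])
        splines = [s for s in specs if s.kind == "pspline"]
        linears = [s for s in specs if s.kind == "linear"]
        intercepts = [s for s in specs if s.kind == "intercept"]
        assert len(splines) == 4  # 2 metric x 2 cells, mu only
        assert len(linears) == 2
        assert len(intercepts) == 2  # one per distribution parameter

    def test_constant_predictor_dropped(self, rng):
        df = pd.DataFrame({"a": np.ones(30), "y": rng.normal(size=30)})
        specs = build_base_learners(df, family_from_name("gaussian"),
                                    metric_predictors=["a"])
        assert all(s.predictor != "a" for s in specs)


class TestBoostFit:
    def test_zero_iterations_equals_offset_model(self, rng):
        df = _gaussian_toy(rng)
        fam = family_from_name("gaussian")
        model = boost_fit(df, "y", fam, _toy_specs(), n_iter=0)
        pred = predict(model, df)
        assert np.allclose(pred["mu"], model.offsets["mu"])
        assert model.offsets["mu"] == pytest.approx(df["y"].mean(), abs=1e-4)

    def test_converges_to_least_squares(self, rng):
        """2000 iterations at step 0.1 reach the closed-form OLS fit to 1e-4."""
        df = _gaussian_toy(rng)
        fam = family_from_name("gaussian")
        model = boost_fit(df, "y", fam, _toy_specs(), n_iter=2000, step=0.1)
        pred = predict(model, pd.DataFrame({"x": [0.0, 1.0]}))
        slope = pred["mean"][1] - pred["mean"][0]
        beta = np.polyfit(df["x"], df["y"], 1)
        assert slope == pytest.approx(beta[0], abs=1e-4)
        assert pred["mean"][0] == pytest.approx(beta[1], abs=1e-4)

    def test_training_risk_monotone_nonincreasing(self, rng):
        df = _gaussian_toy(rng)
        model = boost_fit(df, "y", family_from_name("gaussian"), _toy_specs(),
                          n_iter=500)
        assert np.all(np.diff(model.risks) <= 1e-9)

    def test_shrinkage_at_small_mstop(self, rng):
        df = _gaussian_toy(rng)
        fam = family_from_name("gaussian")
        small = boost_fit(df, "y", fam, _toy_specs(), n_iter=10)
        full = np.polyfit(df["x"], df["y"], 1)[0]

        def slope_of(model):
            p = predict(model, pd.DataFrame({"x": [0.0, 1.0]}))
            return p["mean"][1] - p["mean"][0]

        assert abs(slope_of(small)) < abs(full)

    def test_informative_beats_noise_learner(self, rng):
        """Effect of 1 sd against pure noise: selected in > 80% of iterations."""
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2,
                           "y": x1 + rng.normal(0, 1.0, n)})
        specs = [BaseLearnerSpec("mu", "intercept"), BaseLearnerSpec("sigma", "intercept"),
                 BaseLearnerSpec("mu", "linear", "x1"), BaseLearnerSpec("mu", "linear", "x2")]
        model = boost_fit(df, "y", family_from_name("gaussian"), specs, n_iter=50)
        chosen = [model.learners[i]["predictor"] for i in model.path]
        informative = chosen.count("x1")
        noise = chosen.count("x2")
        assert informative / max(informative + noise, 1) > 0.8

    def test_grouped_learners_touch_only_their_cell(self, rng):
        n = 200
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "year": np.repeat([1999, 2002], n // 2),
        })
        df["y"] = np.where(df["year"] == 1999, 3.0 * df["x"], 0.0) + rng.normal(0, 0.3, n)
        fam = family_from_name("gaussian")
        specs = [BaseLearnerSpec("mu", "intercept"), BaseLearnerSpec("sigma", "intercept"),
                 BaseLearnerSpec("mu", "linear", "x", (("year", 1999),)),
                 BaseLearnerSpec("mu", "linear", "x", (("year", 2002),))]
        model = boost_fit(df, "y", fam, specs, n_iter=400)
        p99 = predict(model, pd.DataFrame({"x": [0.0, 1.0], "year": [1999, 1999]}))
        p02 = predict(model, pd.DataFrame({"x": [0.0, 1.0], "year": [2002, 2002]}))
        assert p99["mean"][1] - p99["mean"][0] == pytest.approx(3.0, abs=0.2)
        assert p02["mean"][1] - p02["mean"][0] == pytest.approx(0.0, abs=0.2)

    def test_predictions_reproduce_training_fit(self, rng):
        df = _gaussian_toy(rng)
        fam = family_from_name("gaussian")
        model, ev = boost_fit(df, "y", fam, _toy_specs(), n_iter=100,
                              eval_data=df)
        # eval risk on the training data equals the training risk per obs
        assert ev[-1] == pytest.approx(model.risks[-1] / len(df), rel=1e-9)

    def test_pspline_recovers_smooth_nonlinearity(self, rng):
        n = 500
        x = rng.uniform(-3, 3, n)
        df = pd.DataFrame({"x": x, "y": np.sin(x) * 2 + rng.normal(0, 0.3, n)})
        specs = [BaseLearnerSpec("mu", "intercept"), BaseLearnerSpec("sigma", "intercept"),
                 BaseLearnerSpec("mu", "pspline", "x")]
        model = boost_fit(df, "y", family_from_name("gaussian"), specs, n_iter=400)
        grid = pd.DataFrame({"x": np.linspace(-2.5, 2.5, 41)})
        pred = predict(model, grid)["mean"]
        rmse = np.sqrt(np.mean((pred - 2 * np.sin(grid["x"])) ** 2))
        assert rmse < 0.25


class TestSerialization:
    def test_round_trip_preserves_predictions(self, rng):
        df = _gaussian_toy(rng)
        model = boost_fit(df, "y", family_from_name("gaussian"), _toy_specs(), n_iter=60)
        clone = BoostModel.from_dict(model.to_dict())
        np.testing.assert_allclose(predict(model, df)["mean"], predict(clone, df)["mean"])


class TestCvTune:
    def test_pure_noise_selects_near_zero_mstop(self, rng):
        """Null predictors: mstop <= 5% of the budget in >= 90% of runs.

        Candidate learners are the noise covariates themselves; the
        distribution-parameter intercepts are part of the offset, so any
        selected iteration would have to pretend the noise is informative.
        """
        specs = [BaseLearnerSpec("mu", "linear", "x"),
                 BaseLearnerSpec("mu", "linear", "x2")]
        max_iter = 400
        hits = 0
        runs = 10
        for rep in range(runs):
            df = pd.DataFrame({"x": rng.normal(size=300), "x2": rng.normal(size=300),
                               "y": rng.normal(size=300)})
            cv = cv_tune(df, "y", family_from_name("gaussian"), specs,
                         max_iter=max_iter, n_resamples=10, seed=rep)
            if cv.mstop <= 0.05 * max_iter:
                hits += 1
        assert hits >= 9

    def test_signal_is_used(self, rng):
        df = _gaussian_toy(rng, noise=0.3)
        cv = cv_tune(df, "y", family_from_name("gaussian"), _toy_specs(),
                     max_iter=150, n_resamples=10, seed=0)
        assert cv.mstop > 0
        curve = cv.mean_curve()
        assert curve[cv.mstop] < curve[0]

    def test_same_seed_same_result(self, rng):
        df = _gaussian_toy(rng)
        a = cv_tune(df, "y", family_from_name("gaussian"), _toy_specs(),
                    max_iter=50, n_resamples=5, seed=3)
        b = cv_tune(df, "y", family_from_name("gaussian"), _toy_specs(),
                    max_iter=50, n_resamples=5, seed=3)
        assert a.mstop == b.mstop
        np.testing.assert_allclose(a.risks, b.risks)
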