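"""Base-learner contract: library grid, fitting, predictions, penalties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sudlearn.learners import (
    FAMILIES,
    REGRESSION_FAMILIES,
    FitError,
    LearnerSpec,
    build_default_library,
    coefficients,
    fit,
    predict_proba,
)
from sudlearn.schema import Dataset, Predictor, PredictorSchema
from sudlearn.simulate import generate

from conftest import make_uniform_config


# --- library grid -----------------------------------------------------------

def test_default_library_is_the_16_plus_sl_grid(toy_schema):
    specs = build_default_library(toy_schema, ("b", "c"), [("a", "b")])
    assert len(specs) == 16  # the super learner over these is the 17th model
    labels = [s.label for s in specs]
    assert len(set(labels)) == 16
    with_interactions = [s for s in specs if s.include_interactions]
    assert {s.family for s in with_interactions} == set(REGRESSION_FAMILIES)
    all_preds = [s for s in specs if s.predictors is None and not s.include_interactions]
    top = [s for s in specs if s.predictors is not None]
    assert {s.family for s in all_preds} == set(FAMILIES)
    assert {s.family for s in top} == set(FAMILIES)
    for s in top:
        assert s.predictors == ("b", "c")  # exactly the screened top-k
    for s in with_interactions:
        assert s.interactions == (("a", "b"),)


def test_interaction_flag_restricted_to_regression_families():
    with pytest.raises(ValueError):
        LearnerSpec(family="random_forest", label="rf", include_interactions=True)


def test_empty_top_k_rejected(toy_schema):
    with pytest.raises(ValueError):
        build_default_library(toy_schema, (), [])


# --- fitting and predicting -------------------------------------------------

def test_separable_data_gives_perfect_training_auc(toy_schema):
    frame = pd.DataFrame(
        {"a": ["a0"] * 30 + ["a1"] * 30, "b": ["b0"] * 60, "c": ["c0"] * 60}
    )
    y = np.array([0] * 30 + [1] * 30, dtype=np.int8)
    data = Dataset(frame=frame, outcome=y, schema=toy_schema)
    model = fit(LearnerSpec("logistic", "lr"), data, seed=0)
    p = predict_proba(model, data)
    from sudlearn.auc import auc_mann_whitney

    assert auc_mann_whitney(p, y) == 1.0


@pytest.mark.parametrize("family", FAMILIES)
def test_predictions_are_probabilities_for_every_family(family, toy_dataset, fast_hyperparameters):
    spec = LearnerSpec(
        family, f"{family} test", hyperparameters=fast_hyperparameters.get(family, {})
    )
    model = fit(spec, toy_dataset, seed=3)
    p = predict_proba(model, toy_dataset)
    assert p.shape == (toy_dataset.n,)
    assert (p >= 0).all() and (p <= 1).all()


def test_fit_is_deterministic_given_seed(toy_dataset, fast_hyperparameters):
    spec = LearnerSpec(
        "random_forest", "rf", hyperparameters=fast_hyperparameters["random_forest"]
    )
    p1 = predict_proba(fit(spec, toy_dataset, seed=5), toy_dataset)
    p2 = predict_proba(fit(spec, toy_dataset, seed=5), toy_dataset)
    np.testing.assert_array_equal(p1, p2)


def test_single_class_outcome_rejected(toy_schema):
    frame = pd.DataFrame({"a": ["a0"] * 10, "b": ["b1"] * 10, "c": ["c1"] * 10})
    data = Dataset(frame=frame, outcome=np.ones(10, dtype=np.int8), schema=toy_schema)
    with pytest.raises(ValueError, match="single class"):
        fit(LearnerSpec("logistic", "lr"), data, seed=0)


def test_intercept_only_learner_predicts_training_prevalence(toy_dataset):
    spec = LearnerSpec("logistic", "intercept only", predictors=())
    model = fit(spec, toy_dataset, seed=0)
    p = predict_proba(model, toy_dataset)
    assert np.allclose(p, toy_dataset.outcome.mean())


def test_empty_record_list_and_identical_records(toy_dataset):
    model = fit(LearnerSpec("logistic", "lr"), toy_dataset, seed=0)
    assert predict_proba(model, toy_dataset.subset([])).shape == (0,)
    twice = toy_dataset.subset([4, 4])
    p = predict_proba(model, twice)
    assert p[0] == p[1]


def test_schema_mismatch_rejected(toy_dataset):
    other = PredictorSchema((Predictor("z", ("u", "v")),))
    frame = pd.DataFrame({"z": ["u", "v"]})
    stranger = Dataset(frame=frame, outcome=np.array([0, 1], dtype=np.int8), schema=other)
    model = fit(LearnerSpec("logistic", "lr"), toy_dataset, seed=0)
    with pytest.raises(ValueError, match="schema"):
        predict_proba(model, stranger)


# --- penalization behavior --------------------------------------------------

@pytest.fixture(scope="module")
def penalty_data():
    config = make_uniform_config(
        n_predictors=4, n_levels=3,
        main_effects={"p0": {"l1": 0.8, "l2": -0.5}, "p1": {"l1": 0.4, "l2": 0.9}},
    )
    return generate(config, 800, seed=17)


def test_elastic_net_limits_reproduce_lasso_and_ridge(penalty_data):
    """Elastic net at mixing 1 matches lasso and at mixing 0 matches ridge
    (same fixed penalty, same data) to numerical tolerance."""
    common = {"C": 0.8, "max_iter": 5000, "tol": 1e-10}
    p_lasso = predict_proba(
        fit(LearnerSpec("lasso", "lasso", hyperparameters=common), penalty_data, 1),
        penalty_data,
    )
    p_enet1 = predict_proba(
        fit(
            LearnerSpec("elastic_net", "enet1", hyperparameters={**common, "l1_ratio": 1.0}),
            penalty_data, 1,
        ),
        penalty_data,
    )
    np.testing.assert_allclose(p_enet1, p_lasso, atol=5e-3)
    p_ridge = predict_proba(
        fit(LearnerSpec("ridge", "ridge", hyperparameters=common), penalty_data, 1),
        penalty_data,
    )
    p_enet0 = predict_proba(
        fit(
            LearnerSpec("elastic_net", "enet0", hyperparameters={**common, "l1_ratio": 0.0}),
            penalty_data, 1,
        ),
        penalty_data,
    )
    np.testing.assert_allclose(p_enet0, p_ridge, atol=5e-3)


def test_vanishing_ridge_penalty_approaches_unpenalized_and_keeps_all_terms(penalty_data):
    p_logistic = predict_proba(
        fit(LearnerSpec("logistic", "lr"), penalty_data, 1), penalty_data
    )
    spec = LearnerSpec("ridge", "ridge weak", hyperparameters={"C": 1e6, "max_iter": 5000})
    model = fit(spec, penalty_data, 1)
    np.testing.assert_allclose(predict_proba(model, penalty_data), p_logistic, atol=1e-3)
    coefs, _ = coefficients(model)
    assert all(abs(v) > 1e-8 for v in coefs.values())  # ridge zeroes nothing


def test_lasso_zeroes_a_duplicated_predictor():
    """Two perfectly collinear predictors: the L1 penalty keeps one and
    zeroes (at least) the other's copy."""
    rng = np.random.default_rng(8)
    levels = rng.choice(["l0", "l1"], size=500)
    frame = pd.DataFrame({"p0": levels, "p1": levels.copy()})
    schema = PredictorSchema(
        (Predictor("p0", ("l0", "l1")), Predictor("p1", ("l0", "l1")))
    )
    y = (rng.random(500) < np.where(levels == "l1", 0.8, 0.3)).astype(np.int8)
    data = Dataset(frame=frame, outcome=y, schema=schema)
    model = fit(
        LearnerSpec("lasso", "lasso", hyperparameters={"C": 0.5, "tol": 1e-10}), data, 1
    )
    coefs, _ = coefficients(model)
    # one copy carries the signal, the other is driven to (numerical) zero
    assert min(abs(coefs["p0=l1"]), abs(coefs["p1=l1"])) < 0.01
    assert max(abs(coefs["p0=l1"]), abs(coefs["p1=l1"])) > 1.0
    # ridge, by contrast, shares the weight equally between the copies
    ridge = fit(
        LearnerSpec("ridge", "ridge", hyperparameters={"C": 0.5, "max_iter": 5000}), data, 1
    )
    rc, _ = coefficients(ridge)
    assert abs(rc["p0=l1"] - rc["p1=l1"]) < 1e-4
    assert min(abs(rc["p0=l1"]), abs(rc["p1=l1"])) > 0.5


def test_coefficients_only_for_regression_families(toy_dataset, fast_hyperparameters):
    model = fit(
        LearnerSpec(
            "random_forest", "rf",
            hyperparameters=fast_hyperparameters["random_forest"],
        ),
        toy_dataset, 1,
    )
    with pytest.raises(ValueError):
        coefficients(model)


def test_fit_error_carries_family_and_label(toy_dataset):
    spec = LearnerSpec("neural_net", "ann bad", hyperparameters={"hidden_layer_sizes": [0]})
    with pytest.raises(FitError, match="neural_net.*ann bad"):
        fit(spec, toy_dataset, seed=1)
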