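"""Stacking engine: folds, out-of-fold predictions, metalearner, SL fit."""

from __future__ import annotations

import numpy as np
import pytest

from sudlearn.auc import auc_mann_whitney
from sudlearn.learners import LearnerSpec, predict_proba
from sudlearn.schema import Dataset
from sudlearn.superlearner import (
    CVPredictions,
    MetaWeights,
    cross_validated_predictions,
    cv_auc_per_learner,
    fit_metalearner,
    fit_super_learner,
    make_folds,
    predict_super_learner,
    select_discrete_sl,
)


# --- folds ------------------------------------------------------------------

def test_fold_sizes_are_balanced():
    assert np.bincount(make_folds(10, 2, seed=1).fold_ids).tolist() == [5, 5]
    sizes = np.bincount(make_folds(11, 2, seed=1).fold_ids)
    assert sorted(sizes.tolist()) == [5, 6]
    sizes = np.bincount(make_folds(23, 5, seed=3).fold_ids)
    assert sizes.max() - sizes.min() <= 1


def test_folds_deterministic_and_seed_sensitive():
    np.testing.assert_array_equal(
        make_folds(50, 2, seed=9).fold_ids, make_folds(50, 2, seed=9).fold_ids
    )
    assert not np.array_equal(
        make_folds(50, 2, seed=9).fold_ids, make_folds(50, 2, seed=10).fold_ids
    )


def test_stratified_folds_balance_classes():
    y = np.array([1] * 6 + [0] * 30)
    folds = make_folds(36, 2, seed=2, stratify=y)
    for v in (0, 1):
        assert y[folds.fold_ids == v].sum() == 3


def test_fold_bounds_enforced():
    for n, v in ((5, 1), (5, 6)):
        with pytest.raises(ValueError):
            make_folds(n, v, seed=0)


# --- CV predictions ---------------------------------------------------------

@pytest.fixture(scope="module")
def small_library(fast_hyperparameters):
    return [
        LearnerSpec("logistic", "lr"),
        LearnerSpec(
            "random_forest", "rf",
            hyperparameters=fast_hyperparameters["random_forest"],
        ),
        LearnerSpec("logistic", "intercept only", predictors=()),
    ]


def test_z_matrix_dimensions_and_range(small_library, toy_dataset):
    folds = make_folds(toy_dataset.n, 2, seed=1)
    cvp = cross_validated_predictions(small_library, toy_dataset, folds, seed=1)
    assert cvp.Z.shape == (toy_dataset.n, 3)
    assert cvp.Z.min() >= 0 and cvp.Z.max() <= 1


def test_constant_learner_column_is_piecewise_constant_by_fold(small_library, toy_dataset):
    """The intercept-only learner predicts each fold's complement
    prevalence: constant within a fold, differing across folds."""
    folds = make_folds(toy_dataset.n, 2, seed=1)
    cvp = cross_validated_predictions(small_library, toy_dataset, folds, seed=1)
    col = cvp.Z[:, 2]
    y = toy_dataset.outcome
    for v in (0, 1):
        mask = folds.fold_ids == v
        expected = y[~mask].mean()
        assert np.allclose(col[mask], expected)


def test_out_of_fold_rows_ignore_their_own_outcomes(small_library, toy_dataset):
    """Permuting outcomes inside fold 0 leaves fold-0 rows of Z unchanged:
    no entry depends on its own record's outcome."""
    folds = make_folds(toy_dataset.n, 2, seed=4)
    cvp = cross_validated_predictions(small_library, toy_dataset, folds, seed=4)
    mask = folds.fold_ids == 0
    rng = np.random.default_rng(0)
    y2 = toy_dataset.outcome.copy()
    idx = np.flatnonzero(mask)
    y2[idx] = y2[rng.permutation(idx)]
    permuted = Dataset(frame=toy_dataset.frame, outcome=y2, schema=toy_dataset.schema)
    cvp2 = cross_validated_predictions(small_library, permuted, folds, seed=4)
    np.testing.assert_array_equal(cvp.Z[mask], cvp2.Z[mask])


def test_single_class_complement_is_reported(toy_schema):
    import pandas as pd

    frame = pd.DataFrame({"a": ["a0"] * 4, "b": ["b0"] * 4, "c": ["c0"] * 4})
    y = np.array([1, 1, 0, 0], dtype=np.int8)
    data = Dataset(frame=frame, outcome=y, schema=toy_schema)
    # force folds where one complement is single-class
    folds = make_folds(4, 2, seed=0)
    bad = Dataset(frame=frame, outcome=np.array([1, 1, 1, 0], dtype=np.int8), schema=toy_schema)
    try:
        cross_validated_predictions([LearnerSpec("logistic", "lr")], bad, folds, seed=0)
    except ValueError as exc:
        assert "single outcome class" in str(exc)


# --- CV AUC and discrete SL -------------------------------------------------

def test_cv_auc_is_fold_average():
    """Fold AUCs of 0.7 and 0.8 average to 0.75 (not pooled)."""
    fold_ids = np.array([0] * 10 + [1] * 10)
    folds = make_folds(20, 2, seed=0)
    object.__setattr__(folds, "fold_ids", fold_ids)
    rng = np.random.default_rng(1)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0] * 2)
    z = np.zeros((20, 1))
    # engineer exact fold AUCs by enumeration
    z[:10, 0] = [0.9, 0.8, 0.7, 0.3, 0.6, 0.5, 0.2, 0.1, 0.05, 0.0]
    z[10:, 0] = [0.9, 0.8, 0.7, 0.6, 0.65, 0.5, 0.2, 0.1, 0.05, 0.0]
    cvp = CVPredictions(Z=z, labels=("l",), folds=folds)
    auc0 = auc_mann_whitney(z[:10, 0], y[:10])
    auc1 = auc_mann_whitney(z[10:, 0], y[10:])
    assert cv_auc_per_learner(cvp, y)[0] == pytest.approx((auc0 + auc1) / 2)


def test_cv_auc_composes_with_mann_whitney(small_library, toy_dataset):
    folds = make_folds(toy_dataset.n, 3, seed=2)
    cvp = cross_validated_predictions(small_library, toy_dataset, folds, seed=2)
    aucs = cv_auc_per_learner(cvp, toy_dataset.outcome)
    manual = np.mean(
        [
            auc_mann_whitney(
                cvp.Z[folds.fold_ids == v, 0], toy_dataset.outcome[folds.fold_ids == v]
            )
            for v in range(3)
        ]
    )
    assert aucs[0] == pytest.approx(manual)


def test_perfect_learner_scores_one(toy_dataset):
    folds = make_folds(toy_dataset.n, 2, seed=0)
    z = toy_dataset.outcome.astype(float).reshape(-1, 1)
    cvp = CVPredictions(Z=z, labels=("oracle",), folds=folds)
    assert cv_auc_per_learner(cvp, toy_dataset.outcome)[0] == 1.0


@pytest.mark.parametrize(
    "aucs, expected",
    [((0.6, 0.9, 0.7), 1), ((0.42,), 0), ((0.8, 0.8), 0)],
)
def test_discrete_sl_picks_best_with_first_tiebreak(aucs, expected):
    assert select_discrete_sl(aucs) == expected


def test_discrete_sl_rejects_empty():
    with pytest.raises(ValueError):
        select_discrete_sl([])


# --- metalearner ------------------------------------------------------------

def test_single_learner_gets_unit_weight():
    rng = np.random.default_rng(0)
    z = rng.random((50, 1))
    y = (rng.random(50) < z[:, 0]).astype(float)
    w = fit_metalearner(z, y)
    assert w.weights.tolist() == [1.0]


def test_perfect_predictor_dominates_noise_column():
    rng = np.random.default_rng(42)
    y = rng.integers(0, 2, 1000).astype(float)
    z = np.column_stack([y, rng.random(1000)])
    w = fit_metalearner(z, y, method="nnls")
    assert w.weights[0] >= 0.95


def test_weights_form_a_simplex_for_both_methods():
    rng = np.random.default_rng(7)
    z = rng.random((200, 4))
    y = rng.integers(0, 2, 200).astype(float)
    for method in ("nnls", "logistic"):
        w = fit_metalearner(z, y, method=method)
        assert (w.weights >= -1e-12).all()
        assert w.weights.sum() == pytest.approx(1.0)


def test_all_zero_solution_falls_back_to_uniform():
    # anti-correlated single column: NNLS zeroes it
    y = np.array([1.0, 1, 1, 0, 0, 0])
    z = (1 - y).reshape(-1, 1) * 0.9
    with pytest.warns(UserWarning, match="uniform"):
        w = fit_metalearner(z[:, :1] * 0 + z, y - y)  # y all zero -> w all zero
    assert np.allclose(w.weights, 1.0)


def test_metaweights_invariant():
    with pytest.raises(ValueError):
        MetaWeights(weights=np.array([0.5, 0.2]), method="nnls")


# --- full super learner -----------------------------------------------------

@pytest.fixture(scope="module")
def sl_fit(small_library, toy_dataset):
    return fit_super_learner(small_library, toy_dataset, V=2, seed=6)


def test_super_learner_prediction_is_convex_combination(sl_fit, toy_dataset):
    preds = np.column_stack(
        [predict_proba(m, toy_dataset) for m in sl_fit.full_fits]
    )
    sl = predict_super_learner(sl_fit, toy_dataset)
    assert (sl >= preds.min(axis=1) - 1e-12).all()
    assert (sl <= preds.max(axis=1) + 1e-12).all()
    # recomposition: manual weighted sum reproduces the prediction exactly
    np.testing.assert_allclose(sl, preds @ sl_fit.weights.weights, atol=1e-12)


def test_degenerate_weights_reduce_to_single_learner(sl_fit, toy_dataset):
    from dataclasses import replace

    w = np.zeros(len(sl_fit.full_fits))
    w[0] = 1.0
    forced = replace(sl_fit, weights=MetaWeights(weights=w, method="nnls"))
    np.testing.assert_allclose(
        predict_super_learner(forced, toy_dataset),
        predict_proba(sl_fit.full_fits[0], toy_dataset),
        atol=1e-12,
    )


def test_uniform_weights_average_two_learners(small_library, toy_dataset):
    from dataclasses import replace

    slf = fit_super_learner(small_library[:2], toy_dataset, V=2, seed=1)
    forced = replace(slf, weights=MetaWeights(weights=np.array([0.5, 0.5]), method="nnls"))
    expected = 0.5 * (
        predict_proba(slf.full_fits[0], toy_dataset)
        + predict_proba(slf.full_fits[1], toy_dataset)
    )
    np.testing.assert_allclose(predict_super_learner(forced, toy_dataset), expected, atol=1e-12)


def test_empty_records_give_empty_predictions(sl_fit, toy_dataset):
    assert predict_super_learner(sl_fit, toy_dataset.subset([])).shape == (0,)


def test_fit_is_bitwise_reproducible(small_library, toy_dataset, sl_fit):
    again = fit_super_learner(small_library, toy_dataset, V=2, seed=6)
    np.testing.assert_array_equal(sl_fit.cv_predictions.Z, again.cv_predictions.Z)
    np.testing.assert_array_equal(sl_fit.weights.weights, again.weights.weights)
    np.testing.assert_array_equal(sl_fit.cv_aucs, again.cv_aucs)
    assert sl_fit.discrete_index == again.discrete_index


def test_stage_failures_name_the_stage(small_library, toy_dataset):
    with pytest.raises(RuntimeError, match="fold construction"):
        fit_super_learner(small_library, toy_dataset, V=1, seed=0)
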