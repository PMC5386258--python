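"""Cross-validated stacking: the super learner over a base-learner library.

The training set is partitioned into V folds (V=2 by default).  Each
library member is fitted on every fold complement and predicts the
held-out fold, giving an n x L matrix Z of out-of-fold success
probabilities.  Per-learner CV AUC is the fold-wise AUC averaged across
folds; the discrete super learner is the single best member by CV AUC.
The metalearner regresses the observed outcome on Z — by default
non-negative least squares with the weights renormalized to sum to one —
and the super learner's prediction function is the corresponding convex
combination of the members refitted on the full training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import expit

from .auc import auc_mann_whitney
from .learners import FittedLearner, LearnerSpec, fit, predict_proba
from .schema import Dataset

__all__ = [
    "FoldAssignment",
    "CVPredictions",
    "MetaWeights",
    "SuperLearnerFit",
    "make_folds",
    "cross_validated_predictions",
    "cv_auc_per_learner",
    "select_discrete_sl",
    "fit_metalearner",
    "fit_super_learner",
    "predict_super_learner",
]


@dataclass(frozen=True)
class FoldAssignment:
    fold_ids: np.ndarray
    V: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold_ids, minlength=self.V)
        if sizes.size != self.V or sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    @property
    def n(self) -> int:
        return self.fold_ids.size


@dataclass(frozen=True)
class CVPredictions:
    """Out-of-fold probability matrix Z (n x L): entry (i, l) comes from
    learner l trained on the folds excluding record i's fold."""

    Z: np.ndarray
    labels: tuple[str, ...]
    folds: FoldAssignment

    def __post_init__(self) -> None:
        if self.Z.shape != (self.folds.n, len(self.labels)):
            raise ValueError("Z must be n x L")
        if self.Z.size and (self.Z.min() < 0 or self.Z.max() > 1):
            raise ValueError("Z entries must be probabilities in [0, 1]")


@dataclass(frozen=True)
class MetaWeights:
    weights: np.ndarray
    method: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be nonnegative and sum to one")


@dataclass(frozen=True)
class SuperLearnerFit:
    library: tuple[LearnerSpec, ...]
    weights: MetaWeights
    full_fits: tuple[FittedLearner, ...]
    cv_aucs: np.ndarray
    discrete_index: int
    cv_predictions: CVPredictions
    seed: int

    @property
    def discrete_label(self) -> str:
        return self.library[self.discrete_index].label


def make_folds(n: int, V: int, seed: int, stratify=None) -> FoldAssignment:
    """Random balanced partition of n records into V folds.

    With ``stratify`` (a binary vector), folds are balanced within each
    class — useful at small n to avoid single-class fold complements.
    Deterministic given the seed.
    """
    if V < 2 or V > n:
        raise ValueError("need 2 <= V <= n")
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(n, dtype=np.int64)
    if stratify is None:
        perm = rng.permutation(n)
        fold_ids[perm] = np.arange(n) % V
    else:
        y = np.asarray(stratify)
        order = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            order.append(rng.permutation(idx))
        order = np.concatenate(order)
        fold_ids[order] = np.arange(n) % V
        # re-balance check is enforced by FoldAssignment's invariant
    return FoldAssignment(fold_ids=fold_ids, V=V, seed=seed)


def cross_validated_predictions(
    library: list[LearnerSpec],
    train: Dataset,
    folds: FoldAssignment,
    seed: int,
) -> CVPredictions:
    """Fit every learner on each fold complement; predict the held-out fold."""
    if folds.n != train.n:
        raise ValueError("fold assignment does not match dataset size")
    n, L = train.n, len(library)
    Z = np.empty((n, L), dtype=float)
    y = np.asarray(train.outcome)
    for v in range(folds.V):
        holdout = np.flatnonzero(folds.fold_ids == v)
        complement = np.flatnonzero(folds.fold_ids != v)
        if np.unique(y[complement]).size < 2:
            raise ValueError(
                f"fold {v}'s training complement has a single outcome class; "
                "use a larger n or stratified folds"
            )
        fit_data = train.subset(complement)
        predict_data = train.subset(holdout)
        for l, spec in enumerate(library):
            model = fit(spec, fit_data, seed)
            Z[holdout, l] = predict_proba(model, predict_data)
    return CVPredictions(Z=Z, labels=tuple(s.label for s in library), folds=folds)


def cv_auc_per_learner(cvp: CVPredictions, y) -> np.ndarray:
    """Per-learner CV AUC: AUC within each fold, averaged across folds."""
    y = np.asarray(y)
    fold_ids = cvp.folds.fold_ids
    aucs = np.empty((cvp.folds.V, cvp.Z.shape[1]))
    for v in range(cvp.folds.V):
        mask = fold_ids == v
        if np.unique(y[mask]).size < 2:
            raise ValueError(f"fold {v} contains a single outcome class")
        for l in range(cvp.Z.shape[1]):
            aucs[v, l] = auc_mann_whitney(cvp.Z[mask, l], y[mask])
    return aucs.mean(axis=0)


def select_discrete_sl(cv_aucs) -> int:
    """Index of the best CV AUC (ties break to the lowest index)."""
    values = np.asarray(cv_aucs, dtype=float)
    if values.size == 0:
        raise ValueError("empty CV AUC vector")
    return int(np.argmax(values))


def fit_metalearner(Z, y, method: str = "nnls") -> MetaWeights:
    """Combination weights from the out-of-fold prediction matrix.

    ``nnls``: non-negative least squares of y on the columns of Z, weights
    renormalized to sum to one.  ``logistic``: nonnegative-constrained
    logistic regression (no intercept) of y on Z, normalized coefficients
    reported as weights.  An all-zero solution falls back to uniform
    weights with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    L = Z.shape[1]
    if method == "nnls":
        w, _ = nnls(Z, y)
    elif method == "logistic":
        def negloglik(beta):
            lp = Z @ beta
            # log(1+exp) stable via logaddexp
            return float(np.logaddexp(0.0, lp).sum() - y @ lp)

        def grad(beta):
            return Z.T @ (expit(Z @ beta) - y)

        res = minimize(
            negloglik,
            x0=np.full(L, 1.0 / L),
            jac=grad,
            bounds=[(0.0, None)] * L,
            method="L-BFGS-B",
        )
        w = res.x
    else:
        raise ValueError(f"unknown metalearner method {method!r}")
    total = w.sum()
    if total <= 0:
        warnings.warn("metalearner returned an all-zero solution; using uniform weights")
        w = np.full(L, 1.0 / L)
    else:
        w = w / total
    return MetaWeights(weights=w, method=method)


def fit_super_learner(
    library: list[LearnerSpec],
    train: Dataset,
    V: int = 2,
    seed: int = 0,
    method: str = "nnls",
    stratified: bool = False,
) -> SuperLearnerFit:
    """Full stacking fit: folds -> Z -> CV AUCs -> weights -> full refits."""
    stage = "fold construction"
    try:
        folds = make_folds(
            train.n, V, seed, stratify=train.outcome if stratified else None
        )
        stage = "cross-validated predictions"
        cvp = cross_validated_predictions(library, train, folds, seed)
        stage = "CV AUC scoring"
        cv_aucs = cv_auc_per_learner(cvp, train.outcome)
        stage = "metalearner"
        weights = fit_metalearner(cvp.Z, train.outcome, method=method)
        stage = "full-data refit"
        full_fits = tuple(fit(spec, train, seed) for spec in library)
    except Exception as exc:
        raise RuntimeError(f"super learner failed at stage: {stage}") from exc
    return SuperLearnerFit(
        library=tuple(library),
        weights=weights,
        full_fits=full_fits,
        cv_aucs=cv_aucs,
        discrete_index=select_discrete_sl(cv_aucs),
        cv_predictions=cvp,
        seed=seed,
    )


def predict_super_learner(slfit: SuperLearnerFit, records) -> np.ndarray:
    """Weighted average of the full-data member predictions."""
    w = slfit.weights.weights
    preds = None
    for weight, model in zip(w, slfit.full_fits):
        p = predict_proba(model, records)
        preds = weight * p if preds is None else preds + weight * p
    return np.clip(preds, 0.0, 1.0) if preds is not None else np.empty(0)
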