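"""Base-learner library: a uniform contract over six model families.

Each learner is declared as a :class:`LearnerSpec` (family, predictor set,
interaction flag, hyperparameters) and fitted on the dummy-coded design of
a training dataset, yielding a :class:`FittedLearner` whose
``predict_proba`` maps records to success probabilities.  The default
comparison grid pairs every family with the full predictor set and with
the RF-screened top-k subset, and additionally gives each regression
family an all-predictors + screened-2-way-interactions configuration —
16 base configurations, with the super learner over them as the 17th
compared model.

Penalized families standardize the dummy columns internally and choose
their penalty strength by internal cross-validation on the deviance unless
a fixed ``C`` is supplied.  Every stochastic family derives its random
state from the pipeline seed plus a stable per-label offset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .schema import Dataset, PredictorSchema, encode_design
from .screening import InteractionList

__all__ = [
    "FAMILIES",
    "REGRESSION_FAMILIES",
    "LearnerSpec",
    "FittedLearner",
    "FitError",
    "build_default_library",
    "fit",
    "predict_proba",
    "coefficients",
]

FAMILIES = ("logistic", "lasso", "ridge", "elastic_net", "random_forest", "neural_net")
REGRESSION_FAMILIES = ("logistic", "lasso", "ridge", "elastic_net")

_FAMILY_DISPLAY = {
    "logistic": "Logistic Regression",
    "lasso": "Lasso",
    "ridge": "Ridge Regression",
    "elastic_net": "Elastic Net",
    "random_forest": "Random Forests",
    "neural_net": "ANN",
}


class FitError(RuntimeError):
    """A learner failed to fit; carries family and spec label."""

    def __init__(self, spec: "LearnerSpec", cause: Exception):
        super().__init__(f"{spec.family} learner {spec.label!r} failed to fit: {cause}")
        self.spec = spec
        self.cause = cause


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative base-learner configuration.

    ``predictors`` is None for the full predictor set, otherwise the
    resolved subset (e.g. the RF top-k).  ``interactions`` holds the
    resolved screened pairs and may be non-empty only for regression
    families.
    """

    family: str
    label: str
    predictors: tuple[str, ...] | None = None
    include_interactions: bool = False
    interactions: tuple[tuple[str, str], ...] = ()
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.include_interactions and self.family not in REGRESSION_FAMILIES:
            raise ValueError("interaction terms are only supported for regression families")

    def seed_for(self, pipeline_seed: int) -> int:
        """Pipeline seed plus a stable per-label offset, kept below 2^31."""
        offset = zlib.adler32(self.label.encode()) % 100_000
        return (pipeline_seed + offset) % (2**31 - 1)


@dataclass(frozen=True)
class FittedLearner:
    spec: LearnerSpec
    model: object
    schema: PredictorSchema
    fingerprint: tuple
    positive_index: int

    def predict_proba(self, records) -> np.ndarray:
        return predict_proba(self, records)


def build_default_library(
    schema: PredictorSchema,
    top_k: tuple[str, ...],
    interactions: InteractionList | tuple[tuple[str, str], ...],
    hyperparameters: dict[str, dict] | None = None,
) -> list[LearnerSpec]:
    """The default 16-configuration comparison grid.

    Six families x {all predictors, top-k predictors} plus the four
    regression families with all predictors and the screened 2-way
    interactions; the super learner over these is the 17th compared
    model.  ``hyperparameters`` optionally overrides settings per family.
    """
    if not top_k:
        raise ValueError("top_k must be non-empty")
    pairs = interactions.pairs if isinstance(interactions, InteractionList) else tuple(interactions)
    hp = hyperparameters or {}
    k = len(top_k)
    specs: list[LearnerSpec] = []
    for family in FAMILIES:
        specs.append(
            LearnerSpec(
                family=family,
                label=f"{_FAMILY_DISPLAY[family]} All Predictors",
                hyperparameters=dict(hp.get(family, {})),
            )
        )
    for family in FAMILIES:
        specs.append(
            LearnerSpec(
                family=family,
                label=f"{_FAMILY_DISPLAY[family]} Top {k} Predictors",
                predictors=tuple(top_k),
                hyperparameters=dict(hp.get(family, {})),
            )
        )
    for family in REGRESSION_FAMILIES:
        specs.append(
            LearnerSpec(
                family=family,
                label=f"{_FAMILY_DISPLAY[family]} All Predictors + 2-Way Interactions",
                include_interactions=True,
                interactions=pairs,
                hyperparameters=dict(hp.get(family, {})),
            )
        )
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate learner labels in library")
    return specs


def _design_for(spec: LearnerSpec, data: Dataset) -> np.ndarray:
    interactions = spec.interactions if spec.include_interactions else ()
    if spec.predictors is not None and len(spec.predictors) == 0:
        # intercept-only learner: constant design handled by DummyClassifier
        return np.zeros((data.n, 1))
    design = encode_design(data, interactions=interactions, predictors=spec.predictors)
    return design.values


def _make_estimator(spec: LearnerSpec, seed: int):
    hp = spec.hyperparameters
    family = spec.family
    if spec.predictors is not None and len(spec.predictors) == 0:
        return DummyClassifier(strategy="prior")
    if family == "logistic":
        return LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=hp.get("max_iter", 2000)
        )
    if family in ("lasso", "ridge", "elastic_net"):
        solver = hp.get(
            "solver", {"lasso": "liblinear", "ridge": "lbfgs", "elastic_net": "saga"}[family]
        )
        l1_ratio = {"lasso": 1.0, "ridge": 0.0, "elastic_net": hp.get("l1_ratio", 0.5)}[family]
        common = dict(solver=solver, max_iter=hp.get("max_iter", 1000), tol=hp.get("tol", 1e-4))
        if "C" in hp:  # fixed penalty, no internal CV
            clf = LogisticRegression(
                l1_ratio=l1_ratio, C=hp["C"], random_state=seed, **common
            )
        else:
            clf = LogisticRegressionCV(
                l1_ratios=[l1_ratio],
                Cs=hp.get("Cs", 7),
                cv=hp.get("cv", 5),
                scoring="neg_log_loss",
                use_legacy_attributes=False,
                random_state=seed,
                **common,
            )
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 50),
            max_depth=hp.get("max_depth"),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            random_state=seed,
            n_jobs=1,
        )
    if family == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (200, 200))),
            max_iter=hp.get("max_iter", 200),
            random_state=seed,
        )
    raise ValueError(f"unknown family {family!r}")  # pragma: no cover


def fit(spec: LearnerSpec, train: Dataset, seed: int) -> FittedLearner:
    """Fit one base learner on the training dataset.

    Raises :class:`FitError` (carrying family and label) if the underlying
    estimator fails; requires both outcome classes present.
    """
    if train.n == 0:
        raise ValueError("training data is empty")
    y = np.asarray(train.outcome)
    if np.unique(y).size < 2:
        raise ValueError("training outcome has a single class; cannot fit")
    X = _design_for(spec, train)
    estimator = _make_estimator(spec, spec.seed_for(seed))
    try:
        estimator.fit(X, y)
    except Exception as exc:
        raise FitError(spec, exc) from exc
    classes = estimator.classes_ if hasattr(estimator, "classes_") else estimator[-1].classes_
    positive_index = int(np.flatnonzero(np.asarray(classes) == 1)[0])
    fingerprint = (train.n, int(y.sum()), tuple(train.schema.names))
    return FittedLearner(
        spec=spec,
        model=estimator,
        schema=train.schema,
        fingerprint=fingerprint,
        positive_index=positive_index,
    )


def _as_dataset(records, schema: PredictorSchema) -> Dataset:
    if isinstance(records, Dataset):
        if records.schema.names != schema.names:
            raise ValueError("records schema does not match the fitted learner's schema")
        return records
    frame = pd.DataFrame(records)
    return Dataset(frame=frame, outcome=np.zeros(len(frame), dtype=np.int8), schema=schema)


def predict_proba(model: FittedLearner, records) -> np.ndarray:
    """Predicted success probability per record, order preserved."""
    data = _as_dataset(records, model.schema)
    if data.n == 0:
        return np.empty(0)
    X = _design_for(model.spec, data)
    probs = model.model.predict_proba(X)[:, model.positive_index]
    return np.clip(probs, 0.0, 1.0)


def coefficients(model: FittedLearner) -> tuple[dict[str, float], float]:
    """Term -> coefficient map on the original dummy scale, plus intercept.

    Undoes the internal standardization of penalized families so
    coefficients are comparable to ground-truth log-odds.  Only defined
    for regression families.
    """
    if model.spec.family not in REGRESSION_FAMILIES:
        raise ValueError("coefficients are only defined for regression families")
    interactions = model.spec.interactions if model.spec.include_interactions else ()
    # column names come from an encoding of an empty frame with the same schema
    names = _design_column_names(model.spec, model.schema)
    est = model.model
    if isinstance(est, Pipeline):
        scaler: StandardScaler = est.named_steps["scale"]
        clf = est.named_steps["clf"]
        beta_std = clf.coef_.ravel()
        beta = beta_std / scaler.scale_
        intercept = float(clf.intercept_[0] - np.sum(beta_std * scaler.mean_ / scaler.scale_))
    else:
        beta = est.coef_.ravel()
        intercept = float(est.intercept_[0])
    if model.positive_index == 0:  # classes_ ordered (1, 0): flip sign
        beta = -beta
        intercept = -intercept
    return dict(zip(names, beta.astype(float))), intercept


def _design_column_names(spec: LearnerSpec, schema: PredictorSchema) -> tuple[str, ...]:
    names: list[str] = []
    main = spec.predictors if spec.predictors is not None else schema.names
    for name in main:
        p = schema[name]
        names.extend(f"{name}={level}" for level in p.dummy_levels)
    if spec.include_interactions:
        for a, b in spec.interactions:
            for la in schema[a].dummy_levels:
                for lb in schema[b].dummy_levels:
                    names.append(f"{a}={la}:{b}={lb}")
    return tuple(names)
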