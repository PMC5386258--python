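"""Shared fixtures: small schemas, toy datasets, fast learner settings."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sudlearn.schema import Dataset, Predictor, PredictorSchema
from sudlearn.simulate import GeneratorConfig


@pytest.fixture(scope="session")
def toy_schema() -> PredictorSchema:
    """Three predictors with 2, 3 and 4 levels (6 dummy terms)."""
    return PredictorSchema(
        (
            Predictor("a", ("a0", "a1")),
            Predictor("b", ("b0", "b1", "b2")),
            Predictor("c", ("c0", "c1", "c2", "c3")),
        )
    )


@pytest.fixture(scope="session")
def toy_dataset(toy_schema) -> Dataset:
    """600 records drawn uniformly over levels, outcome driven by b."""
    rng = np.random.default_rng(12345)
    frame = pd.DataFrame(
        {
            p.name: rng.choice(p.levels, size=600)
            for p in toy_schema.predictors
        }
    )
    logit = -0.3 + 1.2 * (frame["b"] == "b2") - 0.8 * (frame["b"] == "b1")
    outcome = (rng.random(600) < 1 / (1 + np.exp(-logit))).to_numpy().astype(np.int8)
    return Dataset(frame=frame, outcome=outcome, schema=toy_schema)


def make_uniform_config(
    n_predictors: int = 4,
    n_levels: int = 3,
    latent_correlation: float = 0.0,
    main_effects: dict | None = None,
    interaction_effects: tuple = (),
    intercept: float = 0.0,
) -> GeneratorConfig:
    """A small scenario with uniform marginals, for targeted simulations."""
    predictors = tuple(
        Predictor(f"p{i}", tuple(f"l{j}" for j in range(n_levels)))
        for i in range(n_predictors)
    )
    schema = PredictorSchema(predictors)
    marginals = {p.name: tuple([1.0 / n_levels] * n_levels) for p in predictors}
    return GeneratorConfig(
        schema=schema,
        marginals=marginals,
        latent_correlation=latent_correlation,
        main_effects=main_effects or {},
        interaction_effects=interaction_effects,
        intercept=intercept,
    )


@pytest.fixture(scope="session")
def fast_hyperparameters() -> dict:
    """Reduced learner settings that keep multi-learner tests quick."""
    return {
        "lasso": {"C": 0.5},
        "ridge": {"C": 0.5},
        "elastic_net": {"C": 0.5, "max_iter": 300, "tol": 1e-3},
        "neural_net": {"hidden_layer_sizes": [8], "max_iter": 80},
        "random_forest": {"n_estimators": 30},
    }


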