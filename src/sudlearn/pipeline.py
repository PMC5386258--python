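"""End-to-end workflow: split, screen, stack, evaluate, report.

One config drives the whole analysis: load or simulate a dataset, hold
out a test fraction, run the RF-importance and interaction screens on the
training set, build the default 17-model comparison grid, fit the super
learner with V-fold stacking, refit everything on the full training set,
and score every model on the held-out test set with a Mann-Whitney AUC,
DeLong variance, and confidence interval.  The result is the comparison
table (best AUC first) plus summary statistics: the relative AUC
improvement of the best over the worst model and the largest percent
excess of any model's AUC variance over the super learner's.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .auc import auc_confint, relative_improvement, variance_excess
from .learners import build_default_library, predict_proba
from .schema import Dataset, load_schema, read_dataset, split_train_test
from .screening import rank_rf_importance, screen_pairwise_interactions
from .simulate import generate, preset
from .superlearner import SuperLearnerFit, fit_super_learner, predict_super_learner

__all__ = [
    "PipelineConfig",
    "ComparisonTable",
    "PipelineResult",
    "run_pipeline",
    "write_report",
    "read_table",
]

logger = logging.getLogger(__name__)

SL_LABEL = "Super Learning"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; a single master seed governs all stages."""

    preset_name: str | None = "interactions-nonlinear"
    n: int = 20_000
    data_path: str | None = None
    schema_path: str | None = None
    seed: int = 1
    split_fraction: float = 0.8
    V: int = 2
    top_k: int = 10
    alpha: float = 1e-4
    metalearner: str = "nnls"
    stratified: bool = False
    hyperparameters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        data = doc.pop("data", {})
        screening = doc.pop("screening", {})
        kwargs = dict(
            preset_name=data.get("preset"),
            n=data.get("n", 20_000),
            data_path=data.get("path"),
            schema_path=data.get("schema"),
            top_k=screening.get("top_k", 10),
            alpha=float(screening.get("alpha", 1e-4)),
            hyperparameters=doc.pop("learners", {}),
        )
        for key in ("seed", "split_fraction", "V", "metalearner", "stratified"):
            if key in doc:
                kwargs[key] = doc[key]
        if kwargs["preset_name"] is None and kwargs["data_path"] is None:
            kwargs["preset_name"] = "interactions-nonlinear"
        return cls(**kwargs)


@dataclass(frozen=True)
class ComparisonTable:
    """Rows of (label, test AUC, DeLong variance, CI), AUC descending."""

    rows: tuple[tuple[str, float, float, float, float], ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        aucs = [r[1] for r in self.rows]
        if any(a < b for a, b in zip(aucs, aucs[1:])):
            raise ValueError("rows must be sorted by AUC descending")
        if sum(1 for r in self.rows if r[0] == SL_LABEL) != 1:
            raise ValueError("table must contain exactly one super-learner row")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows), columns=["model", "auc", "variance", "ci_lo", "ci_hi"]
        )

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PipelineResult:
    table: ComparisonTable
    slfit: SuperLearnerFit
    importance: object
    interactions: object
    config: PipelineConfig


def _load_data(config: PipelineConfig) -> Dataset:
    if config.data_path is not None:
        if config.schema_path is None:
            raise ValueError("a data path requires a schema path")
        schema = load_schema(config.schema_path)
        data, excluded = read_dataset(config.data_path, schema)
        logger.info("read %d records (%d excluded as incomplete)", data.n, excluded)
        return data
    scenario = preset(config.preset_name)
    logger.info("simulating %d records from preset %r", config.n, scenario.name)
    return generate(scenario.config, config.n, seed=config.seed)


def run_pipeline(config: PipelineConfig, out: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow; optionally write artifacts to ``out``."""
    data = _load_data(config)
    stage = "train/test split"
    try:
        split = split_train_test(data, config.split_fraction, config.seed)
        logger.info("split: %d train / %d test", split.train.n, split.test.n)

        stage = "RF importance screen"
        importance = rank_rf_importance(split.train, config.top_k, config.seed)
        logger.info("top-%d predictors: %s", config.top_k, ", ".join(importance.top))

        stage = "interaction screen"
        interactions = screen_pairwise_interactions(split.train, config.alpha)
        logger.info(
            "interaction screen: %d/%d pairs retained at alpha=%g",
            len(interactions.retained), len(interactions.evaluated), config.alpha,
        )

        stage = "library construction"
        library = build_default_library(
            data.schema, importance.top, interactions, config.hyperparameters
        )

        stage = "super learner fit"
        slfit = fit_super_learner(
            library,
            split.train,
            V=config.V,
            seed=config.seed,
            method=config.metalearner,
            stratified=config.stratified,
        )

        stage = "test-set evaluation"
        y_test = split.test.outcome
        rows = []
        for model in slfit.full_fits:
            est = auc_confint(predict_proba(model, split.test), y_test)
            rows.append((model.spec.label, est.auc, est.variance, est.ci[0], est.ci[1]))
        sl_est = auc_confint(predict_super_learner(slfit, split.test), y_test)
        rows.append((SL_LABEL, sl_est.auc, sl_est.variance, sl_est.ci[0], sl_est.ci[1]))
        rows.sort(key=lambda r: -r[1])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    variances = {label: var for label, _, var, _, _ in rows}
    metadata = {
        "seed": config.seed,
        "split_fraction": config.split_fraction,
        "n_train": split.train.n,
        "n_test": split.test.n,
        "V": config.V,
        "metalearner": config.metalearner,
        "weights": {
            label: float(w)
            for label, w in zip(slfit.cv_predictions.labels, slfit.weights.weights)
        },
        "cv_aucs": {
            label: float(a)
            for label, a in zip(slfit.cv_predictions.labels, slfit.cv_aucs)
        },
        "discrete_super_learner": slfit.discrete_label,
        "top_predictors": list(importance.top),
        "retained_interactions": [list(p) for p in interactions.pairs],
        "relative_improvement_pct": relative_improvement([r[1] for r in rows]),
        "variance_excess_pct": variance_excess(variances, SL_LABEL),
    }
    table = ComparisonTable(rows=tuple(rows), metadata=metadata)
    result = PipelineResult(
        table=table, slfit=slfit, importance=importance,
        interactions=interactions, config=config,
    )
    if out is not None:
        write_report(table, out)
    return result


def write_report(table: ComparisonTable, out: str | Path) -> None:
    """Write the comparison table, CI table, and JSON metadata to a directory."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    frame = table.to_frame()
    frame.to_csv(out / "comparison.csv", index=False)
    frame[["model", "ci_lo", "ci_hi"]].to_csv(out / "confidence_intervals.csv", index=False)
    (out / "metadata.json").write_text(json.dumps(table.metadata, indent=2))
    logger.info("report written to %s", out)


def read_table(path: str | Path) -> ComparisonTable:
    """Re-parse a written comparison.csv (plus metadata.json if present)."""
    path = Path(path)
    csv = path / "comparison.csv" if path.is_dir() else path
    frame = pd.read_csv(csv)
    metadata = {}
    meta_path = csv.parent / "metadata.json"
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
    rows = tuple(
        (str(r.model), float(r.auc), float(r.variance), float(r.ci_lo), float(r.ci_hi))
        for r in frame.itertuples()
    )
    return ComparisonTable(rows=rows, metadata=metadata)
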