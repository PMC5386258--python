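"""Predictor schemas, datasets, dummy-coded design matrices, and splits.

Everything downstream works on purely categorical predictors plus a binary
success outcome, mirroring administrative discharge records: a schema
declares each predictor's legal levels and reference level, a dataset
stores validated records, and the design-matrix encoder produces the
reference-coded 0/1 indicator columns (L-1 per L-level predictor) that the
regression learners consume, optionally with pairwise interaction columns
formed as elementwise products of the constituent main-effect dummies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Predictor",
    "PredictorSchema",
    "Dataset",
    "DesignMatrix",
    "SplitResult",
    "read_dataset",
    "write_dataset",
    "count_dummy_terms",
    "total_model_terms",
    "interaction_dummy_count",
    "encode_design",
    "split_train_test",
    "save_schema",
    "load_schema",
]

OUTCOME_COLUMN = "treatment_success"
SUCCESS_LEVEL = "Yes"


@dataclass(frozen=True)
class Predictor:
    """A categorical predictor: ordered levels and a reference level.

    The reference level is dropped in dummy coding; by convention it is the
    first level unless stated otherwise.
    """

    name: str
    levels: tuple[str, ...]
    reference: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"predictor {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"predictor {self.name!r} has duplicate levels")
        if not self.reference:
            object.__setattr__(self, "reference", self.levels[0])
        if self.reference not in self.levels:
            raise ValueError(f"reference {self.reference!r} not a level of {self.name!r}")

    @property
    def dummy_levels(self) -> tuple[str, ...]:
        """Non-reference levels, in schema order: one dummy column each."""
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class PredictorSchema:
    predictors: tuple[Predictor, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("schema needs at least one predictor")
        names = [p.name for p in self.predictors]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.predictors)

    def __getitem__(self, name: str) -> Predictor:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.predictors)

    def subset(self, names: Sequence[str]) -> "PredictorSchema":
        return PredictorSchema(tuple(self[n] for n in names))


@dataclass(frozen=True)
class Dataset:
    """Validated records of categorical predictor values plus 0/1 outcome."""

    frame: pd.DataFrame
    outcome: np.ndarray
    schema: PredictorSchema

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.outcome):
            raise ValueError("frame and outcome lengths differ")
        y = np.asarray(self.outcome)
        if y.size and not np.isin(y, (0, 1)).all():
            raise ValueError("outcome must be 0/1")
        for p in self.schema.predictors:
            if p.name not in self.frame.columns:
                raise ValueError(f"missing predictor column {p.name!r}")
            bad = ~self.frame[p.name].isin(p.levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"illegal level {self.frame[p.name].iloc[row]!r} for predictor "
                    f"{p.name!r} at row {row}"
                )

    @property
    def n(self) -> int:
        return len(self.frame)

    def subset(self, indices) -> "Dataset":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(np.intp)
        return Dataset(
            frame=self.frame.iloc[idx].reset_index(drop=True),
            outcome=np.asarray(self.outcome)[idx],
            schema=self.schema,
        )


@dataclass(frozen=True)
class DesignMatrix:
    column_names: tuple[str, ...]
    values: np.ndarray
    # column name -> tuple of (predictor, level) pairs (len 1 for main effects,
    # 2 for interactions, 0 for the intercept)
    term_map: dict[str, tuple[tuple[str, str], ...]] = field(repr=False)

    @property
    def n_terms(self) -> int:
        """Number of non-intercept columns."""
        return sum(1 for c in self.column_names if self.term_map[c])


@dataclass(frozen=True)
class SplitResult:
    train: Dataset
    test: Dataset
    seed: int
    fraction: float


def count_dummy_terms(schema: PredictorSchema) -> int:
    """Number of main-effect dummy columns: sum of (levels - 1), no intercept."""
    return sum(len(p.levels) - 1 for p in schema.predictors)


def interaction_dummy_count(schema: PredictorSchema, pair: tuple[str, str]) -> int:
    """Dummy columns contributed by one pairwise interaction: (L_a-1)(L_b-1)."""
    a, b = (schema[name] for name in pair)
    return (len(a.levels) - 1) * (len(b.levels) - 1)


def total_model_terms(n_main: int, n_interactions: int, intercept: bool = True) -> int:
    """Term bookkeeping for a regression model: main + interaction dummies
    (+ intercept)."""
    return n_main + n_interactions + (1 if intercept else 0)


def _dummy_block(frame: pd.DataFrame, predictor: Predictor) -> np.ndarray:
    values = frame[predictor.name].to_numpy()
    block = np.empty((len(frame), len(predictor.dummy_levels)), dtype=np.float64)
    for j, level in enumerate(predictor.dummy_levels):
        block[:, j] = values == level
    return block


def encode_design(
    data: Dataset,
    interactions: Iterable[tuple[str, str]] = (),
    intercept: bool = False,
    predictors: Sequence[str] | None = None,
) -> DesignMatrix:
    """Reference-coded design matrix, optionally with interaction products.

    Parameters
    ----------
    interactions
        Unordered predictor-name pairs; each contributes the elementwise
        products of the two predictors' main-effect dummy columns.
    predictors
        Restrict main effects to this subset (interaction pairs may still
        reference any schema predictor).
    """
    schema = data.schema
    main_names = list(predictors) if predictors is not None else list(schema.names)
    for name in main_names:
        schema[name]  # raises KeyError on unknown predictor

    columns: list[np.ndarray] = []
    names: list[str] = []
    term_map: dict[str, tuple[tuple[str, str], ...]] = {}

    if intercept:
        columns.append(np.ones((data.n, 1)))
        names.append("(Intercept)")
        term_map["(Intercept)"] = ()

    blocks: dict[str, np.ndarray] = {}

    def block_of(name: str) -> np.ndarray:
        if name not in blocks:
            blocks[name] = _dummy_block(data.frame, schema[name])
        return blocks[name]

    for name in main_names:
        p = schema[name]
        blk = block_of(name)
        columns.append(blk)
        for j, level in enumerate(p.dummy_levels):
            col = f"{name}={level}"
            names.append(col)
            term_map[col] = ((name, level),)

    for pair in interactions:
        a, b = pair
        pa, pb = schema[a], schema[b]
        blk_a, blk_b = block_of(a), block_of(b)
        inter = np.einsum("ni,nj->nij", blk_a, blk_b).reshape(data.n, -1)
        columns.append(inter)
        for la in pa.dummy_levels:
            for lb in pb.dummy_levels:
                col = f"{a}={la}:{b}={lb}"
                names.append(col)
                term_map[col] = ((a, la), (b, lb))

    values = np.concatenate(columns, axis=1) if columns else np.empty((data.n, 0))
    return DesignMatrix(column_names=tuple(names), values=values, term_map=term_map)


def read_dataset(
    source: str | Path | io.TextIOBase,
    schema: PredictorSchema,
    outcome_column: str = OUTCOME_COLUMN,
    success_level: str = SUCCESS_LEVEL,
) -> tuple[Dataset, int]:
    """Read a CSV into a complete-case Dataset.

    Rows with any empty predictor or outcome cell are dropped; the second
    return value counts them.  Remaining values are validated against the
    schema (an unknown level raises, naming predictor and row).  The
    outcome is 1 where the cell equals ``success_level`` (e.g. treatment
    completed) and 0 for every other non-missing state.
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    needed = list(schema.names) + [outcome_column]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"missing columns in input: {missing}")
    frame = frame[needed]
    complete = (frame != "").all(axis=1)
    excluded = int((~complete).sum())
    frame = frame[complete].reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("no complete-case rows survive exclusion")
    outcome = (frame[outcome_column] == success_level).to_numpy(dtype=np.int8)
    data = Dataset(frame=frame[list(schema.names)], outcome=outcome, schema=schema)
    return data, excluded


def write_dataset(
    data: Dataset,
    target: str | Path | io.TextIOBase,
    outcome_column: str = OUTCOME_COLUMN,
    success_level: str = SUCCESS_LEVEL,
    failure_level: str = "No",
) -> None:
    out = data.frame.copy()
    out[outcome_column] = np.where(np.asarray(data.outcome) == 1, success_level, failure_level)
    out.to_csv(target, index=False)


def save_schema(schema: PredictorSchema, target: str | Path) -> None:
    """Serialize a schema to YAML (predictor -> levels, reference)."""
    import yaml

    doc = {
        "predictors": [
            {"name": p.name, "levels": list(p.levels), "reference": p.reference}
            for p in schema.predictors
        ]
    }
    Path(target).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_schema(source: str | Path) -> PredictorSchema:
    import yaml

    doc = yaml.safe_load(Path(source).read_text())
    return PredictorSchema(
        tuple(
            Predictor(
                name=p["name"],
                levels=tuple(p["levels"]),
                reference=p.get("reference", ""),
            )
            for p in doc["predictors"]
        )
    )


def split_train_test(data: Dataset, fraction: float, seed: int) -> SplitResult:
    """Simple random train/test split; |train| = floor(fraction * n).

    Deterministic given the seed; train and test partition the records.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_train = int(np.floor(fraction * data.n))
    return SplitResult(
        train=data.subset(perm[:n_train]),
        test=data.subset(perm[n_train:]),
        seed=seed,
        fraction=fraction,
    )
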