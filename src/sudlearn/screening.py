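"""Predictor-reduction procedures: RF importance top-k and interaction screening.

Two screens run once on the full training set before cross-validation:

1. A random forest on the dummy-coded design ranks whole predictors by the
   sum of their columns' impurity-decrease importances; the top k feed the
   reduced-predictor learner configurations.
2. Every unordered predictor pair is tested for a 2-way interaction with a
   block likelihood-ratio test: logistic regression with both main-effect
   dummy blocks, with vs without the interaction block, on
   (L_a-1)(L_b-1) degrees of freedom.  Pairs with p below the screening
   threshold contribute their interaction dummies to the
   "+ 2-way interactions" regression models.  No multiplicity correction
   is applied; the threshold itself is the screen.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2
from sklearn.ensemble import RandomForestClassifier

from .schema import Dataset, PredictorSchema, encode_design

__all__ = [
    "ImportanceRanking",
    "InteractionList",
    "ScreenedPair",
    "candidate_pairs",
    "rank_rf_importance",
    "screen_pairwise_interactions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImportanceRanking:
    """Predictors ordered by non-increasing random-forest importance."""

    ranking: tuple[tuple[str, float], ...]
    k: int

    def __post_init__(self) -> None:
        scores = [s for _, s in self.ranking]
        if any(s < 0 for s in scores):
            raise ValueError("importances must be >= 0")
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("importances must be non-increasing")
        if not 1 <= self.k <= len(self.ranking):
            raise ValueError("k out of range")

    @property
    def top(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.ranking[: self.k])


@dataclass(frozen=True)
class ScreenedPair:
    pair: tuple[str, str]
    df: int
    lr_statistic: float
    p_value: float


@dataclass(frozen=True)
class InteractionList:
    """All evaluated pairs with their block-LRT p-values, plus the threshold."""

    evaluated: tuple[ScreenedPair, ...]
    alpha: float
    skipped: tuple[tuple[str, str], ...] = ()

    @property
    def retained(self) -> tuple[ScreenedPair, ...]:
        return tuple(s for s in self.evaluated if s.p_value < self.alpha)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Retained predictor pairs, for design-matrix construction."""
        return tuple(s.pair for s in self.retained)


def candidate_pairs(schema: PredictorSchema) -> tuple[tuple[str, str], ...]:
    """All C(k, 2) unordered predictor pairs, in schema order."""
    return tuple(itertools.combinations(schema.names, 2))


def rank_rf_importance(
    train: Dataset,
    k: int,
    seed: int,
    n_estimators: int = 50,
) -> ImportanceRanking:
    """Rank predictors by summed impurity-decrease importance in one RF.

    The forest is fitted on the main-effects dummy design of the full
    training set; a predictor's importance is the sum over its dummy
    columns.  Ties at any rank break by schema order (stable sort).
    Deterministic given the seed.
    """
    schema = train.schema
    if not 1 <= k <= len(schema):
        raise ValueError(f"k must be in [1, {len(schema)}]")
    design = encode_design(train)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(design.values, train.outcome)
    per_predictor = {name: 0.0 for name in schema.names}
    for col, importance in zip(design.column_names, forest.feature_importances_):
        predictor = design.term_map[col][0][0]
        per_predictor[predictor] += float(importance)
    order = sorted(
        schema.names, key=lambda name: -per_predictor[name]
    )  # stable: ties keep schema order
    ranking = tuple((name, per_predictor[name]) for name in order)
    return ImportanceRanking(ranking=ranking, k=k)


def _logit_llf(X: np.ndarray, y: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100)
        except Exception:
            res = model.fit(disp=0, method="lbfgs", maxiter=500)
        if not np.isfinite(res.llf):
            raise np.linalg.LinAlgError("non-finite log-likelihood")
        return float(res.llf)


def screen_pairwise_interactions(
    train: Dataset,
    alpha: float,
    pairs: tuple[tuple[str, str], ...] | None = None,
) -> InteractionList:
    """Block likelihood-ratio screen of every 2-way interaction.

    For each unordered pair, fit logistic regression with the two
    main-effect dummy blocks (plus intercept), then add the interaction
    block; the p-value is the chi-square tail of twice the log-likelihood
    gain on df = number of (non-degenerate) interaction columns.
    Interaction columns that are all zero in the data (unobserved level
    combinations) are dropped from the block and from df.  Pairs whose
    fits fail (separation, singularity) are skipped with a warning.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if len(train.schema) < 2:
        raise ValueError("need >= 2 predictors to screen pairs")
    y = np.asarray(train.outcome, dtype=float)
    todo = candidate_pairs(train.schema) if pairs is None else tuple(pairs)
    evaluated: list[ScreenedPair] = []
    skipped: list[tuple[str, str]] = []
    for pair in todo:
        a, b = pair
        main = encode_design(train, intercept=True, predictors=[a, b])
        full = encode_design(train, interactions=[pair], intercept=True, predictors=[a, b])
        n_main = main.values.shape[1]
        inter_block = full.values[:, n_main:]
        keep = inter_block.any(axis=0)
        df = int(keep.sum())
        if df == 0:
            evaluated.append(ScreenedPair(pair=pair, df=0, lr_statistic=0.0, p_value=1.0))
            continue
        X_full = np.concatenate([main.values, inter_block[:, keep]], axis=1)
        try:
            llf0 = _logit_llf(main.values, y)
            llf1 = _logit_llf(X_full, y)
        except Exception as exc:  # separation / singular fits
            logger.warning("interaction screen skipped pair %s: %s", pair, exc)
            skipped.append(pair)
            continue
        stat = max(0.0, 2.0 * (llf1 - llf0))
        p = float(chi2.sf(stat, df))
        evaluated.append(ScreenedPair(pair=pair, df=df, lr_statistic=stat, p_value=p))
    return InteractionList(evaluated=tuple(evaluated), alpha=alpha, skipped=tuple(skipped))
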