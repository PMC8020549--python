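"""Binary probability scorers behind a fixed fit/predict contract.

The modelling pipeline is written against a small contract — ``fit(X, y)``,
``predict_proba(X)`` returning the positive-class probability, tolerance of
NaN feature values at train and predict time (natively or via an imputation
rule owned by the scorer), determinism given its seed — so the learner is an
exchangeable component.  ``GradientBoostedScorer`` (gradient-boosted decision
trees; learned default split directions route missing values) is the primary
learner; ``LogisticScorer`` and ``SingleTreeScorer`` are the comparison
baselines and handle missingness by median/mode imputation fitted on their
training data, since neither underlying model accepts NaN.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import EstimationError

__all__ = [
    "BoosterConfig",
    "BinaryScorer",
    "GradientBoostedScorer",
    "LogisticScorer",
    "SingleTreeScorer",
]


@dataclass(frozen=True)
class BoosterConfig:
    """Gradient-boosting hyperparameters; defaults are the published set."""

    max_depth: int = 5
    min_child_weight: float = 1
    learning_rate: float = 0.1
    n_estimators: int = 100
    gamma: float = 0
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    seed: int = 0

    def xgb_params(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "eta": self.learning_rate,
            "gamma": self.gamma,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "objective": "binary:logistic",
            "seed": self.seed,
            "nthread": 1,
        }


class BinaryScorer(Protocol):
    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "BinaryScorer": ...

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray: ...


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(y) < 2 or set(classes.tolist()) != {0.0, 1.0}:
        raise EstimationError("degenerate training labels: need both classes present")
    return y


class GradientBoostedScorer:
    """Boosted-tree binary classifier (xgboost backend).

    Missing feature values are handled natively: each split learns a default
    direction for NaN, at train and predict time alike.  Deterministic given
    the seed in its :class:`BoosterConfig` (row/column subsampling included).
    """

    def __init__(self, config: BoosterConfig | None = None):
        self.config = config or BoosterConfig()
        self._booster: xgb.Booster | None = None
        self._feature_names: list[str] | None = None

    def with_seed(self, seed: int) -> "GradientBoostedScorer":
        return GradientBoostedScorer(replace(self.config, seed=int(seed)))

    def fit(self, X: pd.DataFrame, y) -> "GradientBoostedScorer":
        y = _check_labels(np.asarray(y))
        self._feature_names = list(X.columns)
        dtrain = xgb.DMatrix(
            X.to_numpy(dtype=float), label=y, missing=np.nan, feature_names=self._feature_names
        )
        self._booster = xgb.train(
            self.config.xgb_params(), dtrain, num_boost_round=self.config.n_estimators
        )
        return self

    def _require_trained(self) -> xgb.Booster:
        if self._booster is None:
            raise EstimationError("scorer is untrained: call fit first")
        return self._booster

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        booster = self._require_trained()
        dm = xgb.DMatrix(
            X[self._feature_names].to_numpy(dtype=float),
            missing=np.nan,
            feature_names=self._feature_names,
        )
        return np.asarray(booster.predict(dm), dtype=float)

    # --- introspection -----------------------------------------------------

    def feature_importance(self) -> dict[str, int]:
        """Split counts per feature across all trees; zero-importance features
        are omitted (a feature never used to split carries no information)."""
        booster = self._require_trained()
        score = booster.get_score(importance_type="weight")
        return {name: int(count) for name, count in score.items()}

    def tree_dump(self) -> list[str]:
        """Text dump of every tree (one string per tree)."""
        return self._require_trained().get_dump(with_stats=False)

    def split_count_from_dump(self) -> dict[str, int]:
        """Recount splits by walking the tree dump — independent of get_score."""
        counts: dict[str, int] = {}
        pattern = re.compile(r"\[([^<>\]]+)<")
        for tree in self.tree_dump():
            for name in pattern.findall(tree):
                counts[name] = counts.get(name, 0) + 1
        return counts

    # --- serialization -----------------------------------------------------

    def to_json(self) -> dict:
        booster = self._require_trained()
        return {
            "kind": "gradient_boosted",
            "config": self.config.__dict__,
            "feature_names": self._feature_names,
            "booster": booster.save_raw(raw_format="json").decode("utf-8"),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "GradientBoostedScorer":
        scorer = cls(BoosterConfig(**doc["config"]))
        booster = xgb.Booster()
        booster.load_model(bytearray(doc["booster"].encode("utf-8")))
        scorer._booster = booster
        scorer._feature_names = list(doc["feature_names"])
        return scorer


class _ImputingScorer:
    """Shared median/mode imputation wrapper for learners that reject NaN."""

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._model = None
        self._fill: pd.Series | None = None
        self._feature_names: list[str] | None = None

    def with_seed(self, seed: int):
        return type(self)(seed=int(seed))

    def _make_model(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _impute(self, X: pd.DataFrame) -> pd.DataFrame:
        filled = X[self._feature_names].fillna(self._fill)
        # a column that was all-NaN in training still has no fill value
        return filled.fillna(0.0)

    def fit(self, X: pd.DataFrame, y):
        y = _check_labels(np.asarray(y))
        self._feature_names = list(X.columns)
        self._fill = X.median(numeric_only=False)
        self._model = self._make_model()
        self._model.fit(self._impute(X).to_numpy(dtype=float), y)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self._model is None:
            raise EstimationError("scorer is untrained: call fit first")
        proba = self._model.predict_proba(self._impute(X).to_numpy(dtype=float))
        return np.asarray(proba[:, 1], dtype=float)


class LogisticScorer(_ImputingScorer):
    """L2-regularized logistic regression baseline (median imputation).

    Features are standardized inside the scorer: the raw cohort mixes scales
    spanning four orders of magnitude (hormone levels vs 0/1 indicators) and
    the solver needs comparable scales to converge.
    """

    def _make_model(self):
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=self.seed)
        )


class SingleTreeScorer(_ImputingScorer):
    """Single classification tree (CART) baseline (median imputation)."""

    def _make_model(self):
        return DecisionTreeClassifier(random_state=self.seed)
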