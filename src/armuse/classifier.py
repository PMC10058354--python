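"""Random-forest block classification and the two train/test protocols.

The classifier is a random forest with 100 trees, unlimited depth, four
features considered at each split, no post-pruning, and a fixed seed (123)
for repeatability.  Two evaluation protocols are provided:

* **intra-subject 10-fold CV** — a subject's blocks are randomly partitioned
  into 10 folds; each fold is predicted by a forest trained on the rest.
* **inter-subject leave-one-out (LOSO)** — each subject is predicted by a
  forest trained on the pooled blocks of every other subject of the same
  group (patients and controls are never mixed).

Accuracy is chunk-size weighted throughout (equal sizes reduce it to plain
accuracy, so the fixed scheme is unaffected).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .evaluation import functional_use_percent, weighted_accuracy
from .features import FEATURE_NAMES


class DegenerateTrainingError(ValueError):
    """Raised when the training set does not contain both classes."""


@dataclasses.dataclass
class ForestConfig:
    n_trees: int = 100
    seed: int = 123
    features_per_split: int = 4
    max_depth: int | None = None


@dataclasses.dataclass
class ProtocolResult:
    """Outcome of one protocol run for one subject."""

    subject_id: str
    protocol: str  # intra_10fold | inter_loso
    method: str    # fixed | variable
    accuracy: float
    predictions: pd.DataFrame  # feature table + 'predicted' column

    @property
    def predicted_fu_percent(self) -> float:
        return functional_use_percent(self.predictions["predicted"],
                                      self.predictions["block_size"])

    @property
    def truth_fu_percent(self) -> float:
        return functional_use_percent(self.predictions["label"],
                                      self.predictions["block_size"])


class FunctionalUseForest(BaseEstimator, ClassifierMixin):
    """Seeded random-forest classifier for block feature vectors.

    Thin sklearn-style estimator around :class:`RandomForestClassifier` with
    the block-classification defaults (100 trees, 4 features per split,
    unlimited depth, seed 123).  Refitting with the same data and seed
    reproduces identical predictions.
    """

    def __init__(self, n_trees: int = 100, seed: int = 123,
                 features_per_split: int = 4, max_depth: int | None = None):
        self.n_trees = n_trees
        self.seed = seed
        self.features_per_split = features_per_split
        self.max_depth = max_depth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateTrainingError(
                "training set contains a single class; both classes are needed"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            max_features=min(self.features_per_split, X.shape[1]),
            random_state=self.seed,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X):
        return self.forest_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.forest_.predict_proba(np.asarray(X, dtype=float))


def train_forest(features, labels, config: ForestConfig | None = None
                 ) -> FunctionalUseForest:
    """Fit a :class:`FunctionalUseForest` from a feature matrix and labels."""
    config = config or ForestConfig()
    return FunctionalUseForest(
        n_trees=config.n_trees, seed=config.seed,
        features_per_split=config.features_per_split,
        max_depth=config.max_depth,
    ).fit(features, labels)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    named = [c for c in table.columns if c in FEATURE_NAMES
             or c.startswith("xcorr_")]
    return named


def run_intra_subject(table: pd.DataFrame, method: str,
                      subject_id: str = "", k: int = 10,
                      forest_config: ForestConfig | None = None,
                      protocol_seed: int = 1, stratified: bool = False
                      ) -> ProtocolResult:
    """Intra-subject k-fold cross-validation on one subject's feature table.

    Folds are an unstratified uniform-random partition (dedicated protocol
    seed); every labelled block is predicted exactly once.
    """
    if len(table) < k:
        raise ValueError(f"subject has {len(table)} blocks; k={k} needed")
    cols = _feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=k, shuffle=True, random_state=protocol_seed)
    predicted = np.empty_like(y)
    for train_idx, test_idx in splitter.split(X, y):
        model = train_forest(X[train_idx], y[train_idx], forest_config)
        predicted[test_idx] = model.predict(X[test_idx])
    out = table.copy()
    out["predicted"] = predicted
    acc = weighted_accuracy(predicted == y, out["block_size"].to_numpy())
    return ProtocolResult(subject_id, "intra_10fold", method, acc, out)


def run_inter_subject(tables: dict[str, pd.DataFrame], method: str,
                      groups: dict[str, str] | None = None,
                      forest_config: ForestConfig | None = None
                      ) -> list[ProtocolResult]:
    """Leave-one-subject-out over a single-group cohort of feature tables."""
    if len(tables) < 2:
        raise ValueError("LOSO requires at least two subjects")
    if groups is not None and len(set(groups.values())) > 1:
        raise ValueError("patient and control groups are evaluated separately")
    results = []
    for held_out, test_table in tables.items():
        train = pd.concat([t for s, t in tables.items() if s != held_out],
                          ignore_index=True)
        cols = _feature_columns(test_table)
        model = train_forest(train[cols].to_numpy(dtype=float),
                             train["label"].to_numpy(), forest_config)
        predicted = model.predict(test_table[cols].to_numpy(dtype=float))
        out = test_table.copy()
        out["predicted"] = predicted
        acc = weighted_accuracy(predicted == out["label"].to_numpy(),
                                out["block_size"].to_numpy())
        results.append(ProtocolResult(held_out, "inter_loso", method, acc, out))
    return results
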