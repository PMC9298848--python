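"""Slide-level benign/malignant classification.

A two-stage random forest: stage 1 is fit on the full feature bank and ranks
features by importance; the top 30 are kept and stage 2 is refit on that
subset to produce the malignancy probability the triage tree consumes.
Feature access is name-keyed throughout, so column order never matters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score

__all__ = ["TwoStageRandomForest", "train_two_stage_rf", "predict_slide", "auc"]


class TwoStageRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest with importance-based feature selection.

    Parameters
    ----------
    n_estimators, max_depth, class_weight : forwarded to both forest stages.
    top_k : number of features kept after the stage-1 importance ranking.
    importance : "impurity" (mean decrease in impurity, default) or
        "permutation".
    random_state : seeds both stages and the permutation importance.

    Fitted attributes: ``selected_features_`` (top-k names, importance order),
    ``importances_`` (stage-1 ranking over all features), ``stage1_``,
    ``stage2_``, ``classes_``.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_depth: int | None = None,
        class_weight: str | dict | None = "balanced",
        top_k: int = 30,
        importance: str = "impurity",
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.top_k = top_k
        self.importance = importance
        self.random_state = random_state

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("feature table must be a pandas DataFrame keyed by feature name")
        return X

    def fit(self, X, y):
        X = self._as_frame(X)
        y = np.asarray(y)
        if X.isna().any().any():
            raise ValueError("feature table contains NaNs")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        if self.top_k > X.shape[1]:
            raise ValueError(
                f"top_k={self.top_k} exceeds the {X.shape[1]} available features"
            )
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")

        rf_kwargs = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.stage1_ = RandomForestClassifier(**rf_kwargs).fit(X.to_numpy(), y)
        if self.importance == "impurity":
            imp = self.stage1_.feature_importances_
        else:
            imp = permutation_importance(
                self.stage1_, X.to_numpy(), y, random_state=self.random_state, n_repeats=5
            ).importances_mean
        order = np.argsort(-imp, kind="stable")  # stable: ties keep table order
        self.importances_ = pd.Series(imp[order], index=X.columns[order])
        self.selected_features_ = list(X.columns[order[: self.top_k]])
        self.stage2_ = RandomForestClassifier(**rf_kwargs).fit(
            X[self.selected_features_].to_numpy(), y
        )
        self.classes_ = self.stage2_.classes_
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def _select(self, X) -> np.ndarray:
        X = self._as_frame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"feature table is missing selected features: {missing}")
        return X[self.selected_features_].to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        return self.stage2_.predict_proba(self._select(X))

    def predict(self, X) -> np.ndarray:
        return self.stage2_.predict(self._select(X))

    def malignancy_probability(self, X) -> np.ndarray:
        """Probability of the positive ("malignant") class per slide."""
        proba = self.predict_proba(X)
        pos = int(np.flatnonzero(self.classes_ == "malignant")[0]) if "malignant" in list(
            self.classes_
        ) else 1
        return proba[:, pos]


def train_two_stage_rf(vectors: pd.DataFrame, labels, config: TwoStageRandomForest | None = None):
    """Fit the two-stage forest; returns (model, selected feature names)."""
    model = config or TwoStageRandomForest()
    model.fit(vectors, labels)
    return model, model.selected_features_


def predict_slide(model: TwoStageRandomForest, vector: pd.Series) -> float:
    """Malignancy probability for one named feature vector."""
    frame = vector.to_frame().T
    return float(model.malignancy_probability(frame)[0])


def auc(scores, labels) -> float:
    """ROC AUC — the Mann–Whitney pairwise statistic with ties counted 1/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
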