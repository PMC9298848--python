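"""Rule-based triple classification and triage metrics.

The final stage routes each slide into one of three categories:
``common_benign`` and ``common_malignant`` (auto-diagnosable) or ``rare``
(recommended for pathologist re-review). The router is an empirical decision
tree over four interpretable quantities — the slide-level malignancy
probability and the maximum lesion area, diameter and perimeter — with
division values 0.5, 300 mm², 7 mm and 35 mm.

Default topology (the probability node first, then geometry, configurable):

* probability < 0.5 (benign branch): ``common_benign`` unless the maximum
  lesion area is implausibly large (≥ 300 mm²), which flags ``rare``;
* probability ≥ 0.5 (malignant branch): ``common_malignant`` only when the
  lesion looks like a typical carcinoma — diameter ≥ 7 mm AND perimeter
  ≥ 35 mm (irregular, invasive edges); otherwise ``rare``.

Ground truth for evaluating the router is *relabeled*: the intermediate
subtypes (TAL, TFCN) are always rare, and any other slide whose binary
prediction disagrees with its benign/malignant label becomes rare too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .synthetic import SUBTYPES

__all__ = [
    "CATEGORIES",
    "TriageThresholds",
    "TriageResult",
    "RelabeledTruth",
    "TriageTree",
    "triple_classify",
    "relabel_ground_truth",
    "triage_metrics",
]

CATEGORIES = ("common_benign", "common_malignant", "rare")
INTERMEDIATE_SUBTYPES = frozenset({"TAL", "TFCN"})


@dataclass(frozen=True)
class TriageThresholds:
    """Division values of the decision tree (probability, mm², mm, mm)."""

    prob_cut: float = 0.5
    area_cut: float = 300.0
    diameter_cut: float = 7.0
    perimeter_cut: float = 35.0

    def __post_init__(self):
        if not 0.0 < self.prob_cut < 1.0:
            raise ValueError("prob_cut must lie in (0, 1)")
        if min(self.area_cut, self.diameter_cut, self.perimeter_cut) <= 0:
            raise ValueError("geometry cuts must be positive")

    def to_dict(self) -> dict:
        return {
            "prob_cut": self.prob_cut,
            "area_cut": self.area_cut,
            "diameter_cut": self.diameter_cut,
            "perimeter_cut": self.perimeter_cut,
        }


@dataclass(frozen=True)
class TriageResult:
    slide_id: str
    rf_prob: float
    max_area_mm2: float
    max_diameter_mm: float
    max_perimeter_mm: float
    decision_path: tuple[tuple[str, str], ...]
    category: str


@dataclass(frozen=True)
class RelabeledTruth:
    slide_id: str
    subtype: str
    binary_pred: str
    category: str


def _default_topology(
    rf_prob: float,
    area: float,
    diameter: float,
    perimeter: float,
    th: TriageThresholds,
) -> tuple[str, tuple[tuple[str, str], ...]]:
    if rf_prob < th.prob_cut:
        if area < th.area_cut:
            return "common_benign", (("probability", "benign"), ("area", "common"))
        return "rare", (("probability", "benign"), ("area", "rare"))
    if diameter >= th.diameter_cut and perimeter >= th.perimeter_cut:
        return "common_malignant", (
            ("probability", "malignant"),
            ("diameter_perimeter", "common"),
        )
    return "rare", (("probability", "malignant"), ("diameter_perimeter", "rare"))


def triple_classify(
    rf_prob: float,
    lesion_maxima: Sequence[float],
    thresholds: TriageThresholds | None = None,
    slide_id: str = "",
    topology: Callable | None = None,
) -> TriageResult:
    """Route one slide through the decision tree.

    ``lesion_maxima`` is (max area mm², max diameter mm, max perimeter mm);
    all three are 0 for a slide with no lesions. The recorded decision path
    starts at the probability node and fully determines the category.
    """
    th = thresholds or TriageThresholds()
    area, diameter, perimeter = (float(v) for v in lesion_maxima)
    if min(area, diameter, perimeter) < 0:
        raise ValueError("lesion maxima must be non-negative")
    if not 0.0 <= rf_prob <= 1.0:
        raise ValueError("rf_prob must lie in [0, 1]")
    topo = topology or _default_topology
    category, path = topo(float(rf_prob), area, diameter, perimeter, th)
    return TriageResult(
        slide_id=slide_id,
        rf_prob=float(rf_prob),
        max_area_mm2=area,
        max_diameter_mm=diameter,
        max_perimeter_mm=perimeter,
        decision_path=path,
        category=category,
    )


class TriageTree(BaseEstimator):
    """Estimator-style wrapper around :func:`triple_classify`.

    ``predict`` consumes a DataFrame with columns ``rf_prob``,
    ``max_area_mm2``, ``max_diameter_mm``, ``max_perimeter_mm`` (indexed by
    slide id) and returns the category per slide; ``classify`` returns full
    :class:`TriageResult` records.
    """

    def __init__(
        self,
        prob_cut: float = 0.5,
        area_cut: float = 300.0,
        diameter_cut: float = 7.0,
        perimeter_cut: float = 35.0,
        topology: Callable | None = None,
    ):
        self.prob_cut = prob_cut
        self.area_cut = area_cut
        self.diameter_cut = diameter_cut
        self.perimeter_cut = perimeter_cut
        self.topology = topology

    @property
    def thresholds(self) -> TriageThresholds:
        return TriageThresholds(
            prob_cut=self.prob_cut,
            area_cut=self.area_cut,
            diameter_cut=self.diameter_cut,
            perimeter_cut=self.perimeter_cut,
        )

    def classify(self, table: pd.DataFrame) -> list[TriageResult]:
        th = self.thresholds
        return [
            triple_classify(
                row["rf_prob"],
                (row["max_area_mm2"], row["max_diameter_mm"], row["max_perimeter_mm"]),
                thresholds=th,
                slide_id=str(idx),
                topology=self.topology,
            )
            for idx, row in table.iterrows()
        ]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray([r.category for r in self.classify(table)], dtype=object)


def relabel_ground_truth(subtype: str, binary_pred: str, binary_label: str) -> str:
    """Relabel one slide for triple-classification evaluation.

    Intermediate subtypes are rare by definition; any other slide is rare
    when the binary prediction disagrees with its label, otherwise it keeps
    its binary side as common benign/malignant.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}")
    for v in (binary_pred, binary_label):
        if v not in ("benign", "malignant"):
            raise ValueError(f"binary value must be 'benign' or 'malignant', got {v!r}")
    if subtype in INTERMEDIATE_SUBTYPES:
        return "rare"
    if binary_pred != binary_label:
        return "rare"
    return "common_malignant" if binary_label == "malignant" else "common_benign"


@dataclass
class TriageMetrics:
    confusion: pd.DataFrame  # rows = truth, cols = predicted
    rare_recall: float
    rare_precision: float
    workload_fraction: float
    direct_accuracy: float
    n_slides: int
    n_flagged: int
    n_rare_truth: int
    thresholds: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {t: self.confusion.loc[t].to_dict() for t in self.confusion.index},
            "rare_recall": self.rare_recall,
            "rare_precision": self.rare_precision,
            "workload_fraction": self.workload_fraction,
            "direct_accuracy": self.direct_accuracy,
            "n_slides": self.n_slides,
            "n_flagged": self.n_flagged,
            "n_rare_truth": self.n_rare_truth,
        }
        if self.thresholds is not None:
            d["thresholds"] = self.thresholds
        return d

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def triage_metrics(
    results: Sequence[TriageResult],
    truth: Sequence[RelabeledTruth],
    thresholds: TriageThresholds | None = None,
) -> TriageMetrics:
    """Score the router against relabeled ground truth.

    Rare recall = flagged true-rare / all rare; rare precision = flagged
    true-rare / all flagged (0 by convention on empty denominators);
    workload = flagged / all; direct accuracy = correct categories among the
    slides *not* flagged for review.
    """
    pred = {r.slide_id: r.category for r in results}
    true = {t.slide_id: t.category for t in truth}
    if set(pred) != set(true):
        only_pred = sorted(set(pred) - set(true))
        only_true = sorted(set(true) - set(pred))
        raise ValueError(
            f"slide id mismatch: only in results {only_pred}, only in truth {only_true}"
        )
    ids = sorted(pred)
    y_true = pd.Categorical([true[i] for i in ids], categories=CATEGORIES)
    y_pred = pd.Categorical([pred[i] for i in ids], categories=CATEGORIES)
    confusion = pd.crosstab(y_true, y_pred, dropna=False)
    confusion.index = pd.Index(CATEGORIES, name="truth")
    confusion.columns = pd.Index(CATEGORIES, name="predicted")

    n = len(ids)
    n_flagged = int(confusion["rare"].sum())
    n_rare = int(confusion.loc["rare"].sum())
    tp = int(confusion.loc["rare", "rare"])
    recall = tp / n_rare if n_rare else 0.0
    precision = tp / n_flagged if n_flagged else 0.0
    workload = n_flagged / n if n else 0.0
    not_flagged = [i for i in ids if pred[i] != "rare"]
    if not_flagged:
        direct_acc = float(np.mean([pred[i] == true[i] for i in not_flagged]))
    else:
        direct_acc = 0.0
    return TriageMetrics(
        confusion=confusion,
        rare_recall=float(recall),
        rare_precision=float(precision),
        workload_fraction=float(workload),
        direct_accuracy=direct_acc,
        n_slides=n,
        n_flagged=n_flagged,
        n_rare_truth=n_rare,
        thresholds=thresholds.to_dict() if thresholds else None,
    )
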