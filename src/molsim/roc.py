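"""ROC evaluation of distance metrics via pairwise same-class discrimination.

The ground truth is built over all unordered molecule pairs: a pair is a
positive when both molecules carry the same class label. Each candidate
metric scores a pair by the *negated* distance between the two descriptor
vectors — smaller distance should mean "same class" — and the resulting
score sweep yields an ROC curve and AUC per metric.

Because ROC analysis depends only on the ranking of scores, any strictly
increasing transform of a distance leaves the curve unchanged. This is the
sense in which ASED (= L2⁴) is evaluated as equivalent to the Euclidean
metric: their ROC curves coincide pointwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .cluster import ClusteringError, METRICS


class ROCError(ValueError):
    """Raised on degenerate pair labelings or invalid metric requests."""


@dataclass
class ROCResult:
    """One metric's ROC curve over labeled molecule pairs."""

    metric: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def pair_labels(class_labels) -> np.ndarray:
    """Binary indicator per unordered molecule pair: 1 when classes match.

    Pairs are enumerated in ``itertools.combinations`` order (the same order
    ``scipy.spatial.distance.pdist`` uses). Degenerate labelings — fewer than
    two molecules, all one class (no negatives), or all classes distinct
    (no positives) — raise, since the ROC is undefined there.
    """
    labels = list(class_labels)
    if len(labels) < 2:
        raise ROCError("need at least 2 molecules to form pairs")
    y = np.array([int(a == b) for a, b in combinations(labels, 2)], dtype=int)
    if y.sum() == 0:
        raise ROCError("no positive pairs: every molecule has a distinct class")
    if y.sum() == len(y):
        raise ROCError("no negative pairs: all molecules share one class")
    return y


def pair_distances(points: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector over all unordered pairs under the metric."""
    if metric not in METRICS:
        raise ClusteringError(f"unknown metric {metric!r}; expected one of {METRICS}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if metric == "ased":
        return pdist(points, metric="sqeuclidean") ** 2
    if metric == "l2":
        return pdist(points, metric="euclidean")
    if metric == "manhattan":
        return pdist(points, metric="cityblock")
    return pdist(points, metric=metric)


def _roc_from_scores(metric: str, y: np.ndarray, scores: np.ndarray) -> ROCResult:
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(
        metric=metric,
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_auc(fpr, tpr)),
        n_positive=int(y.sum()),
        n_negative=int(len(y) - y.sum()),
    )


def roc_for_metric(points: np.ndarray, class_labels, metric: str) -> ROCResult:
    """ROC curve of one distance metric on the pairwise same-class task.

    Scores are negated distances so that small distances rank first; tied
    distances enter the curve simultaneously, matching the trapezoidal AUC.
    """
    y = pair_labels(class_labels)
    d = pair_distances(points, metric)
    if len(d) != len(y):
        raise ROCError(f"{len(d)} pair distances for {len(y)} pair labels")
    return _roc_from_scores(metric, y, -d)


def random_baseline(n_positive: int = 1, n_negative: int = 1) -> ROCResult:
    """The chance-level diagonal, AUC exactly 0.5 by construction."""
    return ROCResult(
        metric="random",
        thresholds=np.array([np.inf, -np.inf]),
        fpr=np.array([0.0, 1.0]),
        tpr=np.array([0.0, 1.0]),
        auc=0.5,
        n_positive=n_positive,
        n_negative=n_negative,
    )


def compare_metrics(
    points: np.ndarray, class_labels, metrics: list[str] | None = None
) -> dict[str, ROCResult]:
    """One ROCResult per metric plus the ``"random"`` diagonal baseline."""
    metrics = list(metrics) if metrics is not None else list(METRICS)
    if not metrics:
        raise ROCError("need at least one metric")
    results = {m: roc_for_metric(points, class_labels, m) for m in metrics}
    y = pair_labels(class_labels)
    results["random"] = random_baseline(int(y.sum()), int(len(y) - y.sum()))
    return results


def cocluster_roc(
    points: np.ndarray, class_labels, k_values: list[int], config
) -> dict[int, ROCResult]:
    """Exploratory variant: score pairs by co-cluster assignment across k.

    For each k, K-means is run on the points and a pair's score is 1 when
    both members land in the same cluster, else 0 — a two-level score whose
    ROC shows how well co-clustering at that k predicts shared class. This
    mode is a coarse diagnostic, not a calibrated comparison of metrics.
    """
    from dataclasses import replace

    from .cluster import kmeans

    y = pair_labels(class_labels)
    out = {}
    for k in k_values:
        res = kmeans(np.asarray(points, dtype=float), replace(config, k=k))
        same = np.array(
            [int(a == b) for a, b in combinations(res.labels.tolist(), 2)], dtype=float
        )
        out[k] = _roc_from_scores(f"cocluster_k{k}", y, same)
    return out


def auc_table_to_json(results: dict[str, ROCResult], path: str | Path) -> None:
    payload = {
        name: {
            "auc": r.auc,
            "n_positive": r.n_positive,
            "n_negative": r.n_negative,
        }
        for name, r in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
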