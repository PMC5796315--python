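"""Segment-image encoding and K-means classification with macro evaluation.

ECG segments of roughly 4-5 beats (~3000 samples at 1000 Hz) are truncated
to the largest leading perfect square (2916 samples -> a 54 x 54 matrix)
and written row-major into a square greyscale image ("z-layout": first
sample top-left, last sample bottom-right), with the segment's amplitude
range mapped affinely onto [0, 255].

Classification is unsupervised K-means (Lloyd's iteration, seeded random
initialization, empty clusters re-seeded from the farthest point) over
min-max-normalized 1-D segments; clusters are mapped to class labels by
majority vote on the training portion, and evaluation uses one-vs-rest
counts per class:

* average accuracy  = (1/N) sum_i (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i)
* macro precision   = (1/N) sum_i TP_i / (TP_i + FP_i)
* macro recall      = (1/N) sum_i TP_i / (TP_i + FN_i)
* F1                = 2 * precision * recall / (precision + recall)

with N the number of classes, reported per class and macro-averaged, under
stratified 10-fold cross-validation. An optional adapter hook exists for a
transfer-learned CNN backbone; in its absence the K-means path is the
complete classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SegmentImage",
    "KMeansModel",
    "EvaluationResult",
    "truncate_square",
    "encode_zlayout",
    "encode_dataset",
    "kmeans_fit",
    "kmeans_predict",
    "map_clusters_to_labels",
    "f1_from_precision_recall",
    "evaluate",
    "crossvalidate",
    "cnn_adapter",
    "register_adapter",
    "CNNBackboneUnavailable",
]


# ---------------------------------------------------------------------------
# z-layout image encoding


@dataclass
class SegmentImage:
    """Square greyscale encoding of one ECG segment.

    ``matrix`` holds float values in [0, 255] (rounded only on PNG export);
    ``amp_min``/``amp_max`` record the affine amplitude mapping bounds in mV.
    """

    matrix: np.ndarray
    side: int
    source_length: int
    amp_min: float
    amp_max: float

    def to_png(self, path: str | Path) -> Path:
        from PIL import Image

        path = Path(path)
        img = np.clip(np.round(self.matrix), 0, 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(path)
        return path


def truncate_square(segment: np.ndarray) -> tuple[np.ndarray, int]:
    """Leading samples up to the largest perfect square length, plus the side.

    A ~3000-sample segment keeps 2916 samples (side 54).
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if n < 4:
        raise ValueError("segment must hold at least 4 samples")
    side = math.isqrt(n)
    return segment[: side * side], side


def encode_zlayout(segment: np.ndarray) -> SegmentImage:
    """Row-major square greyscale image of a perfect-square-length segment.

    Sample ``k`` lands at ``matrix[k // side][k % side]``; amplitudes map
    affinely from [min, max] of the segment to [0, 255], so the encoding is
    invariant under positive affine amplitude transforms. A constant
    segment maps to uniform mid-grey (128).
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    side = math.isqrt(n)
    if side * side != n:
        raise ValueError("segment length must be a perfect square; apply truncate_square")
    amp_min, amp_max = float(np.min(segment)), float(np.max(segment))
    if amp_max > amp_min:
        scaled = (segment - amp_min) / (amp_max - amp_min) * 255.0
    else:
        scaled = np.full(n, 128.0)
    return SegmentImage(
        matrix=scaled.reshape(side, side),
        side=side,
        source_length=n,
        amp_min=amp_min,
        amp_max=amp_max,
    )


def encode_dataset(segments: Sequence[np.ndarray]) -> tuple[np.ndarray, int]:
    """Feature matrix for clustering: truncated, min-max-normalized segments.

    All segments are truncated to the largest perfect square that fits the
    shortest one, then normalized to [0, 1] each. Returns (X, side).
    """
    n_min = min(len(s) for s in segments)
    side = math.isqrt(n_min)
    keep = side * side
    X = np.empty((len(segments), keep))
    for i, seg in enumerate(segments):
        s = np.asarray(seg, dtype=float)[:keep]
        lo, hi = s.min(), s.max()
        X[i] = (s - lo) / (hi - lo) if hi > lo else np.full(keep, 0.5)
    return X, side


# ---------------------------------------------------------------------------
# K-means (Lloyd's iteration)


@dataclass
class KMeansModel:
    centroids: np.ndarray
    assignments: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: list[float] = field(default_factory=list)


def _sq_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # (n, k) squared Euclidean distances.
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
    n_init: int = 10,
) -> KMeansModel:
    """Lloyd's iteration to an assignment fixed point, deterministic per seed.

    Initial centroids are ``k`` distinct points drawn with the seeded
    generator (or the explicit ``init`` array, e.g. to restart from a
    converged state). With ``n_init > 1`` the iteration is restarted from
    that many seeded random initializations and the run with the lowest
    within-cluster sum of squares is kept — the standard guard against a
    poor random initialization. Each pass reassigns every point to its nearest centroid and
    recomputes cluster means; a cluster left empty is re-seeded from the
    point farthest from its assigned centroid. Within-cluster sum of
    squares is non-increasing across iterations.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n points, got k={k}, n={n}")
    if init is None and n_init > 1:
        best: KMeansModel | None = None
        for r in range(n_init):
            model = kmeans_fit(X, k, seed=seed + r, max_iter=max_iter, tol=tol, n_init=1)
            if best is None or model.inertia < best.inertia:
                best = model
        return best
    if init is not None:
        centroids = np.asarray(init, dtype=float).copy()
        if centroids.shape != (k, X.shape[1]):
            raise ValueError("init must have shape (k, n_features)")
    else:
        rng = np.random.default_rng(seed)
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assignments = np.full(n, -1)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = _sq_distances(X, centroids)
        new_assign = np.argmin(d2, axis=1)
        # Re-seed empty clusters from the globally farthest point.
        for j in range(k):
            if not np.any(new_assign == j):
                far = int(np.argmax(d2[np.arange(n), new_assign]))
                centroids[j] = X[far]
                new_assign[far] = j
        new_centroids = np.vstack(
            [X[new_assign == j].mean(axis=0) for j in range(k)]
        )
        inertia = float(
            ((X - new_centroids[new_assign]) ** 2).sum()
        )
        history.append(inertia)
        moved = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        converged = np.array_equal(new_assign, assignments) or moved < tol
        centroids, assignments = new_centroids, new_assign
        if converged:
            break
    return KMeansModel(
        centroids=centroids,
        assignments=assignments,
        inertia=history[-1],
        n_iter=it,
        inertia_history=history,
    )


def kmeans_predict(model: KMeansModel, X: np.ndarray) -> np.ndarray:
    """Nearest-centroid cluster assignment for new points."""
    return np.argmin(_sq_distances(np.asarray(X, dtype=float), model.centroids), axis=1)


def map_clusters_to_labels(
    assignments: np.ndarray,
    labels: Sequence,
    classes: Sequence,
    k: int | None = None,
) -> dict[int, object]:
    """Majority-vote mapping cluster id -> class label on training data.

    Ties break toward the class earliest in ``classes``; a cluster with no
    training members maps to the overall majority class.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    classes = list(classes)
    k = k if k is not None else int(assignments.max()) + 1
    order = {c: i for i, c in enumerate(classes)}
    overall = min(
        classes,
        key=lambda c: (-int(np.sum(labels == c)), order[c]),
    )
    mapping: dict[int, object] = {}
    for j in range(k):
        members = labels[assignments == j]
        if members.size == 0:
            mapping[j] = overall
            continue
        counts = {c: int(np.sum(members == c)) for c in classes}
        mapping[j] = min(classes, key=lambda c: (-counts[c], order[c]))
    return mapping


# ---------------------------------------------------------------------------
# Evaluation (one-vs-rest macro metrics)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvaluationResult:
    """Confusion matrix (rows = actual, columns = predicted) with metrics."""

    classes: list
    confusion: np.ndarray
    per_class: pd.DataFrame
    average_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_samples: int
    folds: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="records"),
            "average_accuracy": self.average_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_samples": self.n_samples,
            "folds": self.folds,
            "notes": self.notes,
        }

    def format_table(self) -> str:
        """Render per-class and macro metrics as a fixed-width report table."""
        lines = [f"{'Abnormality':<14}{'Precision':>10}{'Recall':>10}{'F1':>10}"]
        for _, row in self.per_class.iterrows():
            lines.append(
                f"{row['class']:<14}{row['precision']:>10.2f}"
                f"{row['recall']:>10.2f}{row['f1']:>10.2f}"
            )
        lines.append(
            f"{'Average':<14}{self.macro_precision:>10.2f}"
            f"{self.macro_recall:>10.2f}{self.macro_f1:>10.2f}"
        )
        return "\n".join(lines)


def evaluate(
    predictions: Sequence,
    truths: Sequence,
    classes: Sequence,
) -> EvaluationResult:
    """Confusion matrix and per-class / macro metrics from label sequences.

    Per class i, TP/FP/FN/TN are the one-vs-rest counts, so
    TP_i + FP_i + FN_i + TN_i equals the number of test samples for every
    class. A class absent from the truths has undefined recall and is
    excluded from the macro averages (with a note); a class never predicted
    gets precision 0.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    classes = list(classes)
    n = truths.size
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(truths, predictions):
        cm[index[t], index[p]] += 1

    rows, notes = [], []
    accs, precs, recs = [], [], []
    for i, c in enumerate(classes):
        tp = int(cm[i, i])
        fn = int(cm[i].sum()) - tp
        fp = int(cm[:, i].sum()) - tp
        tn = n - tp - fn - fp
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        if tp + fn == 0:
            recall = float("nan")
            notes.append(f"class {c!r} absent from truths; excluded from macro averages")
        else:
            recall = tp / (tp + fn)
            accs.append((tp + tn) / n)
            precs.append(precision)
            recs.append(recall)
        rows.append(
            {
                "class": c,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "precision": precision,
                "recall": recall,
                "f1": f1_from_precision_recall(precision, recall)
                if not math.isnan(recall)
                else float("nan"),
            }
        )
    macro_p = float(np.mean(precs)) if precs else float("nan")
    macro_r = float(np.mean(recs)) if recs else float("nan")
    return EvaluationResult(
        classes=classes,
        confusion=cm,
        per_class=pd.DataFrame(rows),
        average_accuracy=float(np.mean(accs)) if accs else float("nan"),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=f1_from_precision_recall(macro_p, macro_r),
        n_samples=n,
        notes=notes,
    )


def crossvalidate(
    X: np.ndarray,
    y: Sequence,
    folds: int = 10,
    seed: int = 0,
    k: int | None = None,
) -> EvaluationResult:
    """Stratified k-fold cross-validated K-means classification.

    Folds partition the dataset (each sample tests exactly once). Per fold:
    K-means is fitted on the training subset, clusters are mapped to labels
    by training majority, and the held-out subset is scored. Average
    accuracy, macro precision and macro recall are means over folds; the
    reported F1 is the harmonic mean of the averaged precision and recall
    (the same arithmetic as the per-fold F1). The confusion matrix is the
    sum over test folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    k = k if k is not None else len(classes)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"stratified {folds}-fold CV needs >= {folds} samples per class"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cm_total = np.zeros((len(classes), len(classes)), dtype=int)
    fold_rows = []
    accs, precs, recs = [], [], []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = kmeans_fit(X[tr], k=k, seed=seed + f)
        mapping = map_clusters_to_labels(model.assignments, y[tr], classes, k=k)
        pred = np.asarray([mapping[j] for j in kmeans_predict(model, X[te])])
        res = evaluate(pred, y[te], classes)
        cm_total += res.confusion
        accs.append(res.average_accuracy)
        precs.append(res.macro_precision)
        recs.append(res.macro_recall)
        fold_rows.append(
            {
                "fold": f,
                "test_indices": te.tolist(),
                "average_accuracy": res.average_accuracy,
                "macro_precision": res.macro_precision,
                "macro_recall": res.macro_recall,
                "macro_f1": res.macro_f1,
            }
        )
    macro_p, macro_r = float(np.mean(precs)), float(np.mean(recs))
    pooled = evaluate(
        _pooled_predictions(cm_total, classes), _pooled_truths(cm_total, classes), classes
    )
    return EvaluationResult(
        classes=classes,
        confusion=cm_total,
        per_class=pooled.per_class,
        average_accuracy=float(np.mean(accs)),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=f1_from_precision_recall(macro_p, macro_r),
        n_samples=len(y),
        folds=fold_rows,
    )


def _pooled_truths(cm: np.ndarray, classes: list) -> np.ndarray:
    return np.repeat(classes, cm.sum(axis=1))


def _pooled_predictions(cm: np.ndarray, classes: list) -> np.ndarray:
    out = []
    for i in range(len(classes)):
        out.extend(np.repeat(classes, cm[i]))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Optional CNN adapter


class CNNBackboneUnavailable(RuntimeError):
    """Raised when no pretrained image backbone is installed."""


_ADAPTERS: dict[str, Callable] = {}


def register_adapter(name: str, factory: Callable) -> None:
    """Register a classifier adapter (entry-point-style plugin hook)."""
    _ADAPTERS[name] = factory


def cnn_adapter(
    train_images: Sequence[SegmentImage],
    labels: Sequence,
    backbone: str = "inception_v3",
):
    """Transfer-learning classifier over segment images (optional plugin).

    Requires a registered adapter or an installed deep-learning backbone
    (e.g. a pretrained Inception v3 via keras); when neither is available a
    :class:`CNNBackboneUnavailable` is raised and the K-means path remains
    the supported classifier.
    """
    if backbone in _ADAPTERS:
        return _ADAPTERS[backbone](train_images, labels)
    import importlib.util

    for module in ("tensorflow", "keras", "torch"):
        if importlib.util.find_spec(module) is not None:  # pragma: no cover
            raise CNNBackboneUnavailable(
                f"plugin disabled: backbone {backbone!r} found {module} but no "
                "adapter is registered; use register_adapter()"
            )
    raise CNNBackboneUnavailable(
        f"plugin disabled: no deep-learning backbone available for {backbone!r}; "
        "the K-means classification path remains fully functional"
    )
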