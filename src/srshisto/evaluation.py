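"""Per-class metrics, confusion matrices and report rendering.

For each tissue class: precision = TP / (TP + FP), recall = TP /
(TP + FN), and the F1 score, their harmonic mean 2PR / (P + R).  The
headline figure is the balanced accuracy — the unweighted mean of the
six per-class recalls — which is robust to the strong class imbalance
of annotated tissue datasets.  A zero denominator (a class absent from
truth or predictions) yields a metric of 0 with a logged warning rather
than NaN, so batch reports never crash on degenerate classes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import N_CLASSES, DISPLAY_NAMES, TissueClass

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "precision_recall",
    "f1_score",
    "balanced_accuracy",
    "misclassification_fraction",
    "evaluate",
    "render_report",
]

#: Row order used in rendered tables (the conventional presentation);
#: the internal order everywhere else is the TissueClass enum order.
DISPLAY_ORDER = [
    TissueClass.STROMA,
    TissueClass.ADIPOSE,
    TissueClass.SQUAMOUS_EPITHELIUM,
    TissueClass.MUSCLE,
    TissueClass.GLANDULAR,
    TissueClass.TUMOR,
]


def _to_index(label) -> int:
    if isinstance(label, TissueClass):
        return label.index
    if isinstance(label, str):
        return TissueClass(label).index
    i = int(label)
    if not 0 <= i < N_CLASSES:
        raise ValueError(f"label index {i} outside the {N_CLASSES}-class vocabulary")
    return i


@dataclass
class ConfusionMatrix:
    """6x6 tile counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected a {N_CLASSES}x{N_CLASSES} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def n_tiles(self) -> int:
        return int(self.counts.sum())

    def true_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def predicted_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __getitem__(self, key):
        true_c, pred_c = key
        return int(self.counts[_to_index(true_c), _to_index(pred_c)])


def confusion_matrix(true_labels, pred_labels) -> ConfusionMatrix:
    """Tally (true, predicted) pairs into the fixed-order 6x6 grid."""
    t = [_to_index(x) for x in true_labels]
    p = [_to_index(x) for x in pred_labels]
    if len(t) != len(p):
        raise ValueError(f"label lists differ in length: {len(t)} vs {len(p)}")
    if not t:
        raise ValueError("cannot build a confusion matrix from zero tiles")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def precision_recall(cm: ConfusionMatrix, c: TissueClass) -> tuple[float, float]:
    """(precision, recall) for one class; zero denominators give 0."""
    i = _to_index(c)
    tp = cm.counts[i, i]
    col = cm.counts[:, i].sum()
    row = cm.counts[i, :].sum()
    if col == 0:
        warnings.warn(f"no predictions for class {list(TissueClass)[i].value}; "
                      "precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = float(tp / col)
    if row == 0:
        warnings.warn(f"no true tiles for class {list(TissueClass)[i].value}; "
                      "recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = float(tp / row)
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R); 0 when both inputs are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def balanced_accuracy(recalls) -> float:
    """Unweighted arithmetic mean of the per-class recalls."""
    r = np.asarray(recalls, dtype=np.float64)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("recalls must lie in [0, 1]")
    return float(r.mean())


def misclassification_fraction(cm: ConfusionMatrix, true_c, pred_c) -> float:
    """Fraction of class ``true_c`` tiles predicted as ``pred_c``.

    E.g. 112 of 1393 squamous tiles predicted as tumor -> 0.0804 (8%).
    """
    i, j = _to_index(true_c), _to_index(pred_c)
    row = cm.counts[i, :].sum()
    if row == 0:
        return 0.0
    return float(cm.counts[i, j] / row)


@dataclass
class EvaluationReport:
    """Per-class metrics plus the confusion matrix they derive from."""

    cm: ConfusionMatrix
    precision: dict[TissueClass, float] = field(default_factory=dict)
    recall: dict[TissueClass, float] = field(default_factory=dict)
    f1: dict[TissueClass, float] = field(default_factory=dict)
    balanced_accuracy: float = 0.0
    n_tiles: dict[TissueClass, int] = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "EvaluationReport":
        """Derive every metric from the matrix (single source of truth)."""
        precision, recall, f1 = {}, {}, {}
        for tc in TissueClass:
            p, r = precision_recall(cm, tc)
            precision[tc], recall[tc] = p, r
            f1[tc] = f1_score(p, r)
        return cls(
            cm=cm,
            precision=precision,
            recall=recall,
            f1=f1,
            balanced_accuracy=balanced_accuracy([recall[tc] for tc in TissueClass]),
            n_tiles={tc: int(cm.counts[tc.index, :].sum()) for tc in TissueClass},
        )

    def metrics_frame(self, ndigits: int | None = 2) -> pd.DataFrame:
        rows = []
        for tc in DISPLAY_ORDER:
            p, r, f = self.precision[tc], self.recall[tc], self.f1[tc]
            if ndigits is not None:
                p, r, f = (round(v, ndigits) for v in (p, r, f))
            rows.append(
                {
                    "class": DISPLAY_NAMES[tc],
                    "precision": p,
                    "recall": r,
                    "f1": f,
                    "n_tiles": self.n_tiles[tc],
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        doc = {
            "class_order": [tc.value for tc in TissueClass],
            "confusion_matrix": self.cm.counts.tolist(),
            "precision": {tc.value: self.precision[tc] for tc in TissueClass},
            "recall": {tc.value: self.recall[tc] for tc in TissueClass},
            "f1": {tc.value: self.f1[tc] for tc in TissueClass},
            "balanced_accuracy": self.balanced_accuracy,
            "n_tiles": {tc.value: self.n_tiles[tc] for tc in TissueClass},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text)
        return text


def evaluate(trained, test_x: np.ndarray, test_y) -> EvaluationReport:
    """Predict the test tiles and compile the full report."""
    from .classifier import predict_tiles

    if len(test_x) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    _, pred = predict_tiles(trained, test_x)
    cm = confusion_matrix(list(np.asarray(test_y, dtype=np.int64)), list(pred))
    return EvaluationReport.from_confusion(cm)


def render_report(report: EvaluationReport, outdir, prefix: str = "report") -> dict[str, str]:
    """Write metrics CSV (2 d.p.), confusion CSV, heat-map PNG and full JSON.

    Returns a dict of the written paths.
    """
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(str(outdir), exist_ok=True)
    paths = {}

    metrics_csv = os.path.join(str(outdir), f"{prefix}_metrics.csv")
    report.metrics_frame(ndigits=2).to_csv(metrics_csv, index=False)
    paths["metrics_csv"] = metrics_csv

    cm_csv = os.path.join(str(outdir), f"{prefix}_confusion.csv")
    names = [DISPLAY_NAMES[tc] for tc in TissueClass]
    pd.DataFrame(report.cm.counts, index=names, columns=names).to_csv(cm_csv)
    paths["confusion_csv"] = cm_csv

    json_path = os.path.join(str(outdir), f"{prefix}.json")
    report.to_json(json_path)
    paths["json"] = json_path

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(report.cm.counts, cmap="RdBu_r")
    ax.set_xticks(range(N_CLASSES), names, rotation=45, ha="right")
    ax.set_yticks(range(N_CLASSES), names)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(report.cm.counts[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="tiles")
    fig.tight_layout()
    png_path = os.path.join(str(outdir), f"{prefix}_confusion.png")
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    paths["confusion_png"] = png_path
    return paths
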