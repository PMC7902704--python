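"""Accuracy figures and row-normalized confusion matrices.

The default granularity is per-image (each rendered view is one test item);
per-tree evaluation, which averages the probability vectors of a tree's
views before deciding, is offered as an explicit alternative.  Rows of the
normalized matrix are true classes, so the diagonal holds per-class recall;
matrices are printed as decimals (x100 = percent), read row-wise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = ["ConfusionMatrix", "evaluate", "per_tree_evaluate"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-by-predicted tallies with row normalization and overall accuracy."""

    labels: tuple[str, ...]
    counts: np.ndarray
    row_normalized: np.ndarray
    overall_accuracy: float
    n_items: int
    zero_support_labels: tuple[str, ...] = ()

    def to_dataframe(self, normalized: bool = True) -> pd.DataFrame:
        data = self.row_normalized if normalized else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "row_normalized": self.row_normalized.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "n_items": self.n_items,
            "zero_support_labels": list(self.zero_support_labels),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def __str__(self) -> str:
        """Row-wise decimal rendering mirroring the usual figure layout."""
        width = max(len(lab) for lab in self.labels)
        header = " " * (width + 1) + " ".join(f"{lab[:6]:>6}" for lab in self.labels)
        lines = [header]
        for i, lab in enumerate(self.labels):
            cells = " ".join(f"{v:6.2f}" for v in self.row_normalized[i])
            lines.append(f"{lab:>{width}} {cells}")
        lines.append(f"overall accuracy: {self.overall_accuracy:.4f} (n={self.n_items})")
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[str],
    truths: Sequence[str],
    label_order: Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix over per-item hard labels.

    Rows are normalized by true-class support; classes absent from the test
    set get an all-zero row and are flagged.  Overall accuracy is the
    fraction of items on the diagonal.
    """
    if len(predictions) != len(truths) or len(truths) == 0:
        raise ValueError(
            f"need equal non-zero lengths, got {len(predictions)} vs {len(truths)}"
        )
    labels = tuple(label_order)
    known = set(labels)
    for value in list(predictions) + list(truths):
        if value not in known:
            raise ValueError(f"label {value!r} not in label order {list(labels)}")
    counts = _sk_confusion_matrix(truths, predictions, labels=list(labels))
    support = counts.sum(axis=1)
    norm = np.zeros_like(counts, dtype=float)
    nonzero = support > 0
    norm[nonzero] = counts[nonzero] / support[nonzero, None]
    n = int(counts.sum())
    return ConfusionMatrix(
        labels=labels,
        counts=counts,
        row_normalized=norm,
        overall_accuracy=float(np.trace(counts)) / n,
        n_items=n,
        zero_support_labels=tuple(lab for lab, s in zip(labels, support) if s == 0),
    )


def per_tree_evaluate(
    probs: np.ndarray,
    tree_ids: Sequence[str],
    truths_by_tree: Mapping[str, str],
    label_order: Sequence[str],
) -> ConfusionMatrix:
    """Score at tree level: mean probability over a tree's views, then argmax.

    Ties resolve to the lowest class index (argmax convention).  Each tree
    counts once regardless of its number of views.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != len(tree_ids):
        raise ValueError("probs must be (n_images, n_classes) aligned with tree_ids")
    if probs.shape[0] == 0:
        raise ValueError("no probability vectors given")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for vec, tid in zip(probs, tree_ids):
        if tid in sums:
            sums[tid] += vec
            counts[tid] += 1
        else:
            sums[tid] = vec.copy()
            counts[tid] = 1
    preds, truths = [], []
    for tid in sums:
        mean_vec = sums[tid] / counts[tid]
        preds.append(label_order[int(np.argmax(mean_vec))])
        truths.append(truths_by_tree[tid])
    return evaluate(preds, truths, label_order)
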