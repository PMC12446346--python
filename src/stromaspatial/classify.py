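"""Cell classification and agreement metrics.

Cells become marker-positive or -negative by strict thresholding on an
intensity feature (the feature choice is marker-specific: nuclear maximum
for strictly nuclear markers such as Ki67, whole-cell maximum for markers
with mixed localization such as pNDRG1).  Composite classes restrict a
marker call to cancer cells via the cytokeratin label.  Agreement between
two labelings of the same cells is quantified with a confusion matrix and
its agreement percentage (100 × trace / total).

Learning-based classifiers are pluggable: any callable mapping a list of
cells to a boolean sequence can be applied with :func:`apply_classifier`,
and predictions exported from external tools are merged with
:func:`import_external_labels`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cells import CellRecord, FeatureKey

logger = logging.getLogger(__name__)


@dataclass
class ConfusionResult:
    """Confusion matrix between two labelings of the same cells."""

    classes: list
    matrix: np.ndarray  # rows = labeling A, cols = labeling B
    agreement_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "matrix": self.matrix.tolist(),
            "agreement_pct": self.agreement_pct,
        }


def apply_threshold_classifier(
    cells: list[CellRecord],
    feature_key: FeatureKey,
    threshold: float,
    label_name: str,
) -> list[CellRecord]:
    """Label each cell positive iff ``feature > threshold`` (strict).

    Cells missing the feature are flagged ``unlabeled:<label_name>`` and get
    no entry under ``label_name``.  Cells are modified in place.
    """
    for cell in cells:
        value = cell.features.get(feature_key)
        if value is None or not np.isfinite(value):
            cell.flags.append(f"unlabeled:{label_name}")
            continue
        cell.labels[label_name] = bool(value > threshold)
    return cells


def apply_classifier(
    cells: list[CellRecord],
    classifier: Callable[[list[CellRecord]], Sequence[bool]],
    label_name: str,
) -> list[CellRecord]:
    """Apply any cells → booleans callable as a labeling."""
    preds = classifier(cells)
    if len(preds) != len(cells):
        raise ValueError("classifier returned a prediction count != cell count")
    for cell, pred in zip(cells, preds):
        cell.labels[label_name] = bool(pred)
    return cells


def composite_positive(
    cells: list[CellRecord],
    marker_label: str,
    cytokeratin_label: str,
    composite_name: str | None = None,
) -> list[CellRecord]:
    """Composite call: positive iff marker-positive AND cytokeratin-positive.

    Restricts the marker call to cancer (cytokeratin-positive) cells, the
    convention used when reporting marker-positive cancer cells.
    """
    name = composite_name or f"{marker_label}+{cytokeratin_label}"
    for cell in cells:
        if marker_label not in cell.labels or cytokeratin_label not in cell.labels:
            raise ValueError(
                f"cell {cell.cell_id}: labels {marker_label!r} and "
                f"{cytokeratin_label!r} must both be assigned first"
            )
        cell.labels[name] = cell.labels[marker_label] and cell.labels[cytokeratin_label]
    return cells


def confusion(labels_a: Sequence, labels_b: Sequence) -> ConfusionResult:
    """Confusion matrix and agreement percentage between two labelings.

    ``labels_a`` and ``labels_b`` are parallel sequences over the same cells
    (any hashable class values).  Agreement is the percentage of cells on
    the diagonal, and is symmetric under swapping the two labelings.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"labelings differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("cannot compare empty labelings")
    classes = sorted(set(labels_a) | set(labels_b), key=str)
    index = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        matrix[index[a], index[b]] += 1
    agreement = 100.0 * np.trace(matrix) / matrix.sum()
    return ConfusionResult(classes=classes, matrix=matrix,
                           agreement_pct=float(agreement))


def confusion_from_cells(cells: list[CellRecord], label_a: str,
                         label_b: str) -> ConfusionResult:
    """Confusion between two label names carried on the same cells."""
    pairs = [(c.labels[label_a], c.labels[label_b]) for c in cells
             if label_a in c.labels and label_b in c.labels]
    if not pairs:
        raise ValueError(f"no cells carry both {label_a!r} and {label_b!r}")
    a, b = zip(*pairs)
    return confusion(a, b)


def import_external_labels(
    cells: list[CellRecord], path, label_name: str,
    id_column: str = "cell_id", class_column: str = "class",
    positive_value: str = "positive",
) -> list[str]:
    """Merge labels exported by an external classifier into the cells.

    The file is a CSV keyed by ``id_column`` with the class in
    ``class_column``.  Returns the ids present in the file but not in the
    cell list (and logs them); duplicate ids in the file are an error.
    """
    df = pd.read_csv(path)
    for col in (id_column, class_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df[id_column].duplicated().any():
        dupes = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate cell id(s) {dupes}")
    mapping = dict(zip(df[id_column], df[class_column]))
    matched = set()
    for cell in cells:
        if cell.cell_id in mapping:
            cell.labels[label_name] = mapping[cell.cell_id] == positive_value
            matched.add(cell.cell_id)
    unmatched = [str(k) for k in mapping if k not in matched]
    if unmatched:
        logger.warning("%d external label(s) had no matching cell: %s",
                       len(unmatched), unmatched[:10])
    return unmatched
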