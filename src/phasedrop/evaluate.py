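"""Ground-truth scoring utilities for simulated fields.

Matches segmented objects against the phantom's truth footprints to score
segmentation recall (IoU-based) and to transfer truth phenotype labels onto
extracted cell records for classifier training and held-out evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CellRecord
from .phase import LabeledMask
from .synth import PhantomField

__all__ = [
    "match_truth_objects",
    "segmentation_recall",
    "truth_phenotypes_for_records",
    "macro_accuracy",
]


def _intersection_matrix(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Pixel-count matrix of shape (n_truth+1, n_pred+1) including background."""
    nt, np_ = int(truth.max()), int(pred.max())
    idx = truth.astype(np.int64) * (np_ + 1) + pred.astype(np.int64)
    counts = np.bincount(idx.ravel(), minlength=(nt + 1) * (np_ + 1))
    return counts.reshape(nt + 1, np_ + 1)


def match_truth_objects(mask: LabeledMask, phantom: PhantomField) -> pd.DataFrame:
    """Best-overlap match of every truth cell to a segmented object.

    Returns one row per truth cell with the matched predicted label (0 when
    the cell fell entirely in background) and the IoU between the truth
    footprint and that object.
    """
    inter = _intersection_matrix(phantom.truth_label_map, mask.label_map)
    truth_areas = inter.sum(axis=1)
    pred_areas = inter.sum(axis=0)
    rows = []
    for cell in phantom.truth_cells:
        t = cell.cell_id
        if t >= inter.shape[0] or truth_areas[t] == 0:
            rows.append(
                {"truth_id": t, "phenotype": cell.phenotype, "pred_label": 0, "iou": 0.0}
            )
            continue
        overlaps = inter[t].copy()
        overlaps[0] = 0  # background cannot be a match
        p = int(overlaps.argmax())
        if p == 0:
            iou = 0.0
        else:
            i = inter[t, p]
            iou = i / (truth_areas[t] + pred_areas[p] - i)
        rows.append(
            {
                "truth_id": t,
                "phenotype": cell.phenotype,
                "pred_label": p,
                "iou": float(iou),
            }
        )
    return pd.DataFrame(rows)


def segmentation_recall(
    mask: LabeledMask,
    phantom: PhantomField,
    iou_threshold: float = 0.5,
    min_area_um2: float = 20.0,
) -> tuple[int, int]:
    """(recovered, eligible) truth cells at the given IoU threshold.

    Truth cells smaller than the segmentation's minimum-area filter are not
    eligible — the filter removes them by design.
    """
    matches = match_truth_objects(mask, phantom)
    eligible = [c for c in phantom.truth_cells if c.area_um2 >= min_area_um2]
    ids = {c.cell_id for c in eligible}
    hit = matches[matches.truth_id.isin(ids) & (matches.iou > iou_threshold)]
    return len(hit), len(ids)


def truth_phenotypes_for_records(
    records: list[CellRecord], mask: LabeledMask, phantom: PhantomField
) -> list[str | None]:
    """Truth phenotype per record by majority pixel overlap (None = unmatched)."""
    inter = _intersection_matrix(phantom.truth_label_map, mask.label_map)
    pheno_by_id = {c.cell_id: c.phenotype for c in phantom.truth_cells}
    labels: list[str | None] = []
    for rec in records:
        p = rec.cell_id
        if p <= 0 or p >= inter.shape[1]:
            labels.append(None)
            continue
        col = inter[:, p].copy()
        col[0] = 0
        t = int(col.argmax())
        labels.append(pheno_by_id.get(t) if col[t] > 0 else None)
    return labels


def macro_accuracy(truth: list[str], predicted: list[str]) -> float:
    """Mean per-class recall (balanced accuracy) over the truth classes."""
    truth_arr = np.asarray(truth)
    pred_arr = np.asarray(predicted)
    recalls = []
    for cls in np.unique(truth_arr):
        sel = truth_arr == cls
        recalls.append(float((pred_arr[sel] == cls).mean()))
    return float(np.mean(recalls))
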