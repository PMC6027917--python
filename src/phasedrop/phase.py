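"""Segmentation and OPD quantification of quantitative phase images.

The measurement chain mirrors label-free adipogenesis quantification:
cells are segmented with a fixed threshold set slightly above the image
background, the average optical path difference (OPD, nm) is measured
within the segmented cells, and the fields imaged per well (four by
convention) are averaged into one well-level value.  For cell counting and
classification an iterative-intermeans (Ridler–Calvard) threshold is used
and objects touching the image border are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import PhaseImage

__all__ = [
    "DegenerateHistogramError",
    "LabeledMask",
    "WellMeasurement",
    "ridler_calvard_threshold",
    "fixed_threshold_segment",
    "intermeans_segment",
    "mean_opd",
    "count_cells",
    "aggregate_well",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested on a constant image."""


@dataclass
class LabeledMask:
    """Connected-component labelling of segmented cells.

    ``label_map`` uses 0 for background and contiguous positive integers for
    objects; ``border_excluded_ids`` lists labels touching the image edge
    (kept in the mask — they contribute to pooled OPD — but excluded from
    counting and classification).
    """

    label_map: np.ndarray
    n_objects: int
    border_excluded_ids: tuple[int, ...]
    threshold: float = float("nan")


def _as_array(image: PhaseImage | np.ndarray) -> np.ndarray:
    return image.opd_map if isinstance(image, PhaseImage) else np.asarray(image)


def ridler_calvard_threshold(
    image: PhaseImage | np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> float:
    """Iterative-intermeans (Ridler–Calvard / isodata) threshold.

    Starting from the midrange, iterates ``t <- (mean below t + mean above
    t) / 2`` to a fixed point: the converged threshold lies midway between
    the means of the two classes it induces.
    """
    values = _as_array(image).ravel().astype(np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("image contains non-finite values")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise DegenerateHistogramError("constant image has no threshold")
    t = 0.5 * (vmin + vmax)
    for _ in range(max_iter):
        lo = values[values <= t]
        hi = values[values > t]
        if hi.size == 0:  # threshold drifted past the top value
            t = vmax
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


def _label_and_filter(
    foreground: np.ndarray, min_area_px: int
) -> tuple[np.ndarray, int, tuple[int, ...]]:
    labels, _ = ndimage.label(foreground, structure=_STRUCT8)
    if min_area_px > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        kill = np.flatnonzero(areas < min_area_px)
        kill = kill[kill > 0]
        if kill.size:
            labels[np.isin(labels, kill)] = 0
    # relabel to contiguous 1..n
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    labels = lut[labels]
    n = int(ids.size)
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = tuple(int(b) for b in border if b > 0)
    return labels, n, border


def fixed_threshold_segment(
    image: PhaseImage | np.ndarray,
    offset_sd: float = 3.0,
    min_area_um2: float = 20.0,
    pixel_size_um: float | None = None,
) -> LabeledMask:
    """Segment cells with a fixed threshold slightly above the background.

    The background level and spread are estimated robustly from the whole
    image (median and MAD-derived sigma, valid because cells cover a
    minority of pixels); the threshold is ``median + offset_sd * 1.4826 *
    MAD``.  Components smaller than ``min_area_um2`` are removed and objects
    touching the edge are flagged for border exclusion.
    """
    opd = _as_array(image).astype(np.float64)
    if not np.all(np.isfinite(opd)):
        raise ValueError("image contains non-finite values")
    if pixel_size_um is None:
        pixel_size_um = (
            image.optics.pixel_size_um if isinstance(image, PhaseImage) else 1.0
        )
    med = float(np.median(opd))
    sd = 1.4826 * float(np.median(np.abs(opd - med)))
    threshold = med + offset_sd * sd
    min_area_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    labels, n, border = _label_and_filter(opd > threshold, min_area_px)
    return LabeledMask(labels, n, border, threshold=threshold)


def intermeans_segment(
    image: PhaseImage | np.ndarray,
    min_area_um2: float = 20.0,
    pixel_size_um: float | None = None,
) -> LabeledMask:
    """Segment with the Ridler–Calvard threshold (counting/classification path)."""
    opd = _as_array(image).astype(np.float64)
    if pixel_size_um is None:
        pixel_size_um = (
            image.optics.pixel_size_um if isinstance(image, PhaseImage) else 1.0
        )
    threshold = ridler_calvard_threshold(opd)
    min_area_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    labels, n, border = _label_and_filter(opd > threshold, min_area_px)
    return LabeledMask(labels, n, border, threshold=threshold)


def mean_opd(image: PhaseImage | np.ndarray, mask: LabeledMask) -> float:
    """Pooled mean OPD (nm) over all segmented-cell pixels.

    Border-excluded objects still contribute (exclusion applies to counting
    and classification only).  An empty mask yields NaN, never a silent 0.
    """
    opd = _as_array(image)
    if opd.shape != mask.label_map.shape:
        raise ValueError("image and mask shapes differ")
    pixels = opd[mask.label_map > 0]
    if pixels.size == 0:
        return float("nan")
    return float(pixels.mean())


def count_cells(mask: LabeledMask) -> int:
    """Number of segmented objects after border exclusion."""
    return mask.n_objects - len(mask.border_excluded_ids)


@dataclass
class WellMeasurement:
    """Per-well aggregate of the imaging fields.

    ``mean_opd`` averages the per-field mean OPDs over fields that contained
    cells; fields with empty masks are dropped (``n_fields_used`` records
    how many contributed).  ``no_cells`` flags a well where every field was
    empty.
    """

    well_id: str
    field_opds: tuple[float, ...]
    mean_opd: float
    cell_count: int
    n_fields_used: int
    no_cells: bool
    counts_per_phenotype: dict[str, int] = field(default_factory=dict)
    dead_fraction: float = float("nan")


def aggregate_well(
    field_opds: list[float],
    field_counts: list[int] | None = None,
    well_id: str = "",
) -> WellMeasurement:
    """Average field OPDs into one well value, dropping cell-free fields."""
    if len(field_opds) < 1:
        raise ValueError("need at least one field")
    counts = field_counts if field_counts is not None else [0] * len(field_opds)
    if len(counts) != len(field_opds):
        raise ValueError("field_counts length must match field_opds")
    valid = [v for v in field_opds if math.isfinite(v)]
    no_cells = len(valid) == 0
    return WellMeasurement(
        well_id=well_id,
        field_opds=tuple(field_opds),
        mean_opd=float(np.mean(valid)) if valid else float("nan"),
        cell_count=int(sum(counts)),
        n_fields_used=len(valid),
        no_cells=no_cells,
    )
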