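"""Fluorescence comparison branch: stain-based lipid and death readouts.

Implements the conventional high-content measurements that the label-free
phase readout is benchmarked against: illumination correction by division
with a heavily blurred copy of the field, nucleus detection on the Hoechst
channel, neutral-lipid intensity in a 20 µm disk around each nucleus
(LipidTox-style), lipid-droplet intensity within a cytoplasm mask built
from faint membrane staining (Nile-Red-style) and the ethidium-homodimer
positive-cell fraction for death scoring.  Per-cell medians are summarised
to field medians; fields are averaged per well by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .phase import DegenerateHistogramError, ridler_calvard_threshold

__all__ = [
    "NucleusSet",
    "FieldReadout",
    "correct_illumination",
    "detect_nuclei",
    "lipid_intensity_per_nucleus",
    "nile_red_quant",
    "ethd_positive_fraction",
    "blank_field_cutoff",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class NucleusSet:
    centroids: list[tuple[float, float]]  # (row, col) pixels

    @property
    def count(self) -> int:
        return len(self.centroids)


@dataclass
class FieldReadout:
    """One field-level fluorescence value with per-cell detail and QC flag."""

    value: float
    per_cell: list[float]
    flagged: bool = False
    reason: str = ""


def correct_illumination(
    channel: np.ndarray, smoothing_scale_um: float = 100.0, pixel_size_um: float = 0.65
) -> np.ndarray:
    """Divide out smooth illumination gradients, preserving the global median.

    The illumination estimate is a Gaussian blur whose kernel FWHM is
    ``smoothing_scale_um`` (much larger than a cell, so cellular structure
    is untouched); the image is divided by it and rescaled so the output
    median equals the input median.  Within ~2 kernel widths of the field
    edge the estimate is boundary-padded and residual gradients survive
    there.
    """
    channel = np.asarray(channel, dtype=np.float64)
    sigma_px = smoothing_scale_um / 2.355 / pixel_size_um  # FWHM -> sigma
    smooth = ndimage.gaussian_filter(channel, sigma=sigma_px, mode="nearest")
    if np.any(smooth <= 0):
        raise ValueError("illumination estimate contains non-positive values")
    corrected = channel / smooth
    med_in = np.median(channel)
    med_out = np.median(corrected)
    if med_out > 0:
        corrected *= med_in / med_out
    return corrected


def detect_nuclei(
    nuclear_channel: np.ndarray,
    min_area_um2: float = 10.0,
    pixel_size_um: float = 0.65,
) -> NucleusSet:
    """Centroids of nuclear blobs above an automatic intermeans threshold."""
    img = np.asarray(nuclear_channel, dtype=np.float64)
    try:
        thr = ridler_calvard_threshold(img)
    except DegenerateHistogramError:
        return NucleusSet(centroids=[])
    labels, _ = ndimage.label(img > thr, structure=_STRUCT8)
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    centroids = [
        tuple(float(c) for c in p.centroid)
        for p in regionprops(labels)
        if p.area >= min_px
    ]
    return NucleusSet(centroids=centroids)


def _disk_median(
    img: np.ndarray, center: tuple[float, float], radius_px: float
) -> tuple[float, bool]:
    """Median over a disk; second value flags clipping at the image edge."""
    ny, nx = img.shape
    cr, cc = center
    r0 = int(math.floor(cr - radius_px))
    r1 = int(math.ceil(cr + radius_px)) + 1
    c0 = int(math.floor(cc - radius_px))
    c1 = int(math.ceil(cc + radius_px)) + 1
    clipped = r0 < 0 or c0 < 0 or r1 > ny or c1 > nx
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(ny, r1), min(nx, c1)
    rr = np.arange(r0, r1, dtype=np.float64)[:, None]
    cc_ = np.arange(c0, c1, dtype=np.float64)[None, :]
    inside = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius_px**2
    values = img[r0:r1, c0:c1][inside]
    if values.size == 0:
        return float("nan"), True
    return float(np.median(values)), clipped


def lipid_intensity_per_nucleus(
    lipid_channel: np.ndarray,
    nuclei: NucleusSet,
    radius_um: float = 20.0,
    pixel_size_um: float = 0.65,
) -> FieldReadout:
    """Median lipid intensity in a disk of ``radius_um`` around each nucleus.

    The field summary is the median over cells; wells average their fields.
    Nuclei whose disk is clipped by the field edge are measured on the
    clipped disk and the field is flagged.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    img = np.asarray(lipid_channel, dtype=np.float64)
    radius_px = radius_um / pixel_size_um
    per_cell, any_clipped = [], False
    for center in nuclei.centroids:
        value, clipped = _disk_median(img, center, radius_px)
        any_clipped |= clipped
        if math.isfinite(value):
            per_cell.append(value)
    if not per_cell:
        return FieldReadout(float("nan"), [], flagged=True, reason="no nuclei")
    return FieldReadout(
        value=float(np.median(per_cell)),
        per_cell=per_cell,
        flagged=any_clipped,
        reason="edge-clipped disk" if any_clipped else "",
    )


def nile_red_quant(
    nile_channel: np.ndarray,
    min_area_um2: float = 100.0,
    pixel_size_um: float = 0.65,
) -> FieldReadout:
    """Droplet intensity within a cytoplasm mask from faint membrane staining.

    The cytoplasm mask is thresholded on the log-intensity histogram
    (intermeans), separating faintly stained cell bodies from background;
    droplet intensities are the per-cell medians within the mask and the
    field value is their median.  An empty mask — the signature of a failed
    staining round — yields a flagged NaN readout.
    """
    img = np.asarray(nile_channel, dtype=np.float64)
    if img.max() <= img.min():
        return FieldReadout(float("nan"), [], flagged=True, reason="empty cytoplasm mask")
    log_img = np.log1p(np.clip(img, 0.0, None))
    thr = ridler_calvard_threshold(log_img)
    mask = log_img > thr
    labels, _ = ndimage.label(mask, structure=_STRUCT8)
    min_px = max(1, int(round(min_area_um2 / pixel_size_um**2)))
    per_cell = [
        float(np.median(p.image_intensity[p.image]))
        for p in regionprops(labels, intensity_image=img)
        if p.area >= min_px
    ]
    if not per_cell:
        return FieldReadout(float("nan"), [], flagged=True, reason="empty cytoplasm mask")
    return FieldReadout(value=float(np.median(per_cell)), per_cell=per_cell)


def ethd_positive_fraction(
    death_channel: np.ndarray,
    nuclei: NucleusSet,
    fixed_cutoff: float,
    measure_radius_um: float = 5.0,
    pixel_size_um: float = 0.65,
) -> FieldReadout:
    """Fraction of cells whose median death-stain intensity exceeds a cutoff.

    Cells are anchored at detected nuclei; each is scored on the median
    intensity in a small perinuclear disk against the fixed positive/negative
    cutoff.  Zero nuclei yield a flagged NaN.
    """
    if fixed_cutoff <= 0:
        raise ValueError("fixed_cutoff must be positive")
    img = np.asarray(death_channel, dtype=np.float64)
    if nuclei.count == 0:
        return FieldReadout(float("nan"), [], flagged=True, reason="no nuclei")
    radius_px = measure_radius_um / pixel_size_um
    per_cell = [
        _disk_median(img, center, radius_px)[0] for center in nuclei.centroids
    ]
    positives = sum(v > fixed_cutoff for v in per_cell)
    return FieldReadout(value=positives / len(per_cell), per_cell=per_cell)


def blank_field_cutoff(
    negative_channels: list[np.ndarray], quantile: float = 0.999
) -> float:
    """Fixed positivity cutoff from negative-control fields.

    Returns the requested upper quantile (default 99.9%) of the pooled
    negative-control intensities, the conventional way to set a fixed
    positive/negative separation when none is given.
    """
    pooled = np.concatenate([np.asarray(c).ravel() for c in negative_channels])
    return float(np.quantile(pooled, quantile))
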