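"""Per-cell feature extraction and phenotype classification.

Each segmented object is summarised by size, shape and OPD features and
assigned one of four phenotypes: ``undifferentiated`` (large, low OPD),
``adipocytic`` (large, high OPD from lipid droplets), ``dead`` (small,
round, high OPD) or ``error`` (anything matching none of the rules, e.g.
small low-OPD debris).  Classification is available both as transparent
thresholds on area / roundness / mean OPD and as a trained Random Forest or
k-nearest-neighbours model, the two algorithms conventionally offered by
high-content classification plugins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from skimage.measure import regionprops

from .phase import LabeledMask
from .synth import PhaseImage

__all__ = [
    "CellRecord",
    "RuleThresholds",
    "ClassifierModel",
    "FEATURE_NAMES",
    "extract_cell_features",
    "classify_cells_rules",
    "feature_matrix",
    "train_cell_classifier",
    "apply_cell_classifier",
    "save_classifier",
    "load_classifier",
    "dead_fraction",
]

_MODEL_FORMAT_VERSION = 1

#: Features used by trained classifiers.  Beyond the three rule axes (area,
#: form factor, mean OPD) the OPD spread and upper decile are included:
#: droplet inclusions create bright puncta that mark adipocytic cells even
#: when their mean OPD is ambiguous.
FEATURE_NAMES = (
    "area_um2",
    "perimeter_um",
    "form_factor",
    "eccentricity",
    "mean_opd_nm",
    "integrated_opd",
    "opd_sd_nm",
    "opd_p90_nm",
)


@dataclass
class CellRecord:
    """Morphological and OPD features of one segmented cell."""

    cell_id: int
    centroid: tuple[float, float]
    area_um2: float
    perimeter_um: float
    form_factor: float  # 4*pi*area / perimeter^2, 1 for a perfect circle
    eccentricity: float
    mean_opd_nm: float
    integrated_opd: float  # nm * um^2
    opd_sd_nm: float
    opd_p90_nm: float
    phenotype: str = "error"


@dataclass(frozen=True)
class RuleThresholds:
    """Cut-offs for the transparent rule-based phenotype calls.

    ``opd_high_cutoff_nm`` separates low-OPD (plain cytoplasm) from high-OPD
    (droplet-bearing or pyknotic) cells; the default sits midway between the
    simulated cytoplasm-only and droplet-bearing per-cell means.
    """

    area_small_cutoff_um2: float = 200.0
    opd_high_cutoff_nm: float = 120.0
    roundness_cutoff: float = 0.85

    def __post_init__(self) -> None:
        if min(
            self.area_small_cutoff_um2, self.opd_high_cutoff_nm, self.roundness_cutoff
        ) <= 0:
            raise ValueError("all rule thresholds must be positive")


def extract_cell_features(
    image: PhaseImage | np.ndarray,
    mask: LabeledMask,
    pixel_size_um: float | None = None,
) -> list[CellRecord]:
    """One feature record per non-border segmented object.

    Areas and perimeters are converted to physical units via the pixel
    size; OPD features are taken over the object's own pixels.  Phenotypes
    are initialised to ``error`` until classified.
    """
    opd = image.opd_map if isinstance(image, PhaseImage) else np.asarray(image)
    if pixel_size_um is None:
        pixel_size_um = (
            image.optics.pixel_size_um if isinstance(image, PhaseImage) else 1.0
        )
    ps2 = pixel_size_um**2
    excluded = set(mask.border_excluded_ids)
    records: list[CellRecord] = []
    for prop in regionprops(mask.label_map, intensity_image=opd):
        if prop.label in excluded:
            continue
        # Crofton estimator: unbiased for digitised smooth shapes
        perimeter_um = prop.perimeter_crofton * pixel_size_um
        area_um2 = prop.area * ps2
        if perimeter_um > 0:
            form_factor = 4.0 * np.pi * area_um2 / perimeter_um**2
        else:  # single-pixel object
            form_factor = 1.0
        values = prop.image_intensity[prop.image]
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                centroid=tuple(float(c) for c in prop.centroid),
                area_um2=float(area_um2),
                perimeter_um=float(perimeter_um),
                form_factor=float(min(form_factor, 1.2)),
                eccentricity=float(prop.eccentricity),
                mean_opd_nm=float(values.mean()),
                integrated_opd=float(values.mean() * area_um2),
                opd_sd_nm=float(values.std()),
                opd_p90_nm=float(np.percentile(values, 90)),
            )
        )
    return records


def classify_cells_rules(
    records: list[CellRecord], thresholds: RuleThresholds | None = None
) -> list[CellRecord]:
    """Assign phenotypes by thresholds on area, roundness and mean OPD.

    dead: small AND round AND high OPD; adipocytic: large AND high OPD;
    undifferentiated: large AND low OPD; everything else: error.
    """
    thr = thresholds or RuleThresholds()
    out = []
    for rec in records:
        small = rec.area_um2 < thr.area_small_cutoff_um2
        high = rec.mean_opd_nm > thr.opd_high_cutoff_nm
        round_ = rec.form_factor > thr.roundness_cutoff
        if small and round_ and high:
            phenotype = "dead"
        elif not small and high:
            phenotype = "adipocytic"
        elif not small and not high:
            phenotype = "undifferentiated"
        else:
            phenotype = "error"
        out.append(dataclasses.replace(rec, phenotype=phenotype))
    return out


def feature_matrix(records: list[CellRecord]) -> np.ndarray:
    """Stack the classifier features of ``records`` into an (n, d) array."""
    return np.array(
        [[getattr(r, name) for name in FEATURE_NAMES] for r in records],
        dtype=np.float64,
    )


@dataclass
class ClassifierModel:
    algorithm: str  # "random_forest" | "k_neighbors"
    estimator: object
    feature_names: tuple[str, ...]
    hyperparameters: dict
    training_seed: int
    holdout_accuracy: float = float("nan")
    format_version: int = _MODEL_FORMAT_VERSION


def train_cell_classifier(
    records: list[CellRecord],
    truth_labels: list[str],
    algorithm: str = "random_forest",
    seed: int = 0,
    holdout_fraction: float = 0.25,
    **hyperparameters,
) -> ClassifierModel:
    """Fit a phenotype classifier on labelled cell records.

    Labels come from simulator ground truth.  A stratified hold-out split
    (``holdout_fraction``) provides an honest accuracy estimate, after which
    the model is refitted on all records.  Deterministic under ``seed``.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import accuracy_score
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import KNeighborsClassifier

    if len(records) != len(truth_labels):
        raise ValueError("records and truth_labels length mismatch")
    classes = set(truth_labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")

    if algorithm == "random_forest":
        params = {"n_estimators": 100, **hyperparameters}
        est = RandomForestClassifier(random_state=seed, **params)
    elif algorithm == "k_neighbors":
        params = {"n_neighbors": 5, **hyperparameters}
        est = KNeighborsClassifier(**params)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    X = feature_matrix(records)
    y = np.asarray(truth_labels)
    holdout = float("nan")
    if 0.0 < holdout_fraction < 1.0:
        counts = min(np.unique(y, return_counts=True)[1])
        stratify = y if counts >= 2 else None
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=holdout_fraction, random_state=seed, stratify=stratify
        )
        est.fit(X_tr, y_tr)
        holdout = float(accuracy_score(y_te, est.predict(X_te)))
    est.fit(X, y)
    return ClassifierModel(
        algorithm=algorithm,
        estimator=est,
        feature_names=FEATURE_NAMES,
        hyperparameters=params,
        training_seed=seed,
        holdout_accuracy=holdout,
    )


def apply_cell_classifier(
    model: ClassifierModel, records: list[CellRecord]
) -> tuple[list[CellRecord], dict[str, int]]:
    """Predict a phenotype for every record; returns records and counts."""
    if tuple(model.feature_names) != FEATURE_NAMES:
        raise ValueError("model was trained with a different feature list")
    if not records:
        return [], {}
    predictions = model.estimator.predict(feature_matrix(records))
    out = [
        dataclasses.replace(rec, phenotype=str(p))
        for rec, p in zip(records, predictions)
    ]
    counts: dict[str, int] = {}
    for rec in out:
        counts[rec.phenotype] = counts.get(rec.phenotype, 0) + 1
    return out, counts


def save_classifier(model: ClassifierModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": model.format_version,
            "algorithm": model.algorithm,
            "estimator": model.estimator,
            "feature_names": model.feature_names,
            "hyperparameters": model.hyperparameters,
            "training_seed": model.training_seed,
            "holdout_accuracy": model.holdout_accuracy,
        },
        path,
    )


def load_classifier(path: str | Path) -> ClassifierModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported classifier file version")
    return ClassifierModel(
        algorithm=payload["algorithm"],
        estimator=payload["estimator"],
        feature_names=tuple(payload["feature_names"]),
        hyperparameters=payload["hyperparameters"],
        training_seed=payload["training_seed"],
        holdout_accuracy=payload["holdout_accuracy"],
    )


def dead_fraction(records: list[CellRecord]) -> float:
    """Dead cells over all non-error cells; NaN when undefined."""
    classified = [r for r in records if r.phenotype != "error"]
    if not classified:
        return float("nan")
    return sum(r.phenotype == "dead" for r in classified) / len(classified)
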