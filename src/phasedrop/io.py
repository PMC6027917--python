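"""File I/O: float32 TIFF fields, CSV tables and YAML configs.

Fields are written one single-plane 32-bit float TIFF per channel with the
suffix convention ``_opd`` (phase, nm), ``_nuc`` / ``_lip`` / ``_dead``
(fluorescence).  Pixel size and wavelength ride along as a JSON image
description so phase images round-trip with their optics metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .synth import FieldSet, FluorescenceField, OpticsConfig, PhaseImage

CHANNEL_SUFFIXES = ("_opd", "_nuc", "_lip", "_dead")


def write_phase_tiff(path: str | Path, image: PhaseImage) -> None:
    meta = {
        "units": "nm",
        "wavelength_nm": image.optics.wavelength_nm,
        "pixel_size_um": image.optics.pixel_size_um,
        "opd_noise_sd_nm": image.optics.opd_noise_sd_nm,
        "background_drift_amplitude_nm": image.optics.background_drift_amplitude_nm,
        "provenance": image.provenance,
    }
    tifffile.imwrite(
        str(path), image.opd_map.astype(np.float32), description=json.dumps(meta)
    )


def read_phase_tiff(path: str | Path) -> PhaseImage:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.pages[0].asarray().astype(np.float64)
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    optics = OpticsConfig(
        wavelength_nm=float(meta.get("wavelength_nm", 684.0)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.65)),
        field_shape=tuple(data.shape),
        opd_noise_sd_nm=float(meta.get("opd_noise_sd_nm", 0.0)),
        background_drift_amplitude_nm=float(
            meta.get("background_drift_amplitude_nm", 0.0)
        ),
    )
    return PhaseImage(
        opd_map=data, optics=optics, provenance=str(meta.get("provenance", ""))
    )


def write_channel_tiff(path: str | Path, channel: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(channel, dtype=np.float32))


def read_channel_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_field_set(stem: str | Path, fs: FieldSet) -> list[Path]:
    """Write one field's channels next to each other: ``<stem>_opd.tif`` etc."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []
    opd_path = stem.parent / f"{stem.name}_opd.tif"
    write_phase_tiff(opd_path, fs.phase)
    written.append(opd_path)
    if fs.fluor is not None:
        for suffix, channel in zip(
            CHANNEL_SUFFIXES[1:],
            (
                fs.fluor.nuclear_channel,
                fs.fluor.lipid_channel,
                fs.fluor.death_channel,
            ),
        ):
            p = stem.parent / f"{stem.name}{suffix}.tif"
            write_channel_tiff(p, channel)
            written.append(p)
    return written


def read_fluor_field(stem: str | Path) -> FluorescenceField:
    stem = Path(stem)
    channels = {}
    for suffix in CHANNEL_SUFFIXES[1:]:
        p = stem.parent / f"{stem.name}{suffix}.tif"
        channels[suffix] = read_channel_tiff(p)
    return FluorescenceField(
        nuclear_channel=channels["_nuc"],
        lipid_channel=channels["_lip"],
        death_channel=channels["_dead"],
        illumination_gradient=np.ones_like(channels["_nuc"]),
        stain_failure=False,
    )


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return payload


def dump_yaml_config(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
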