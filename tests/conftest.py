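"""Shared fixtures: small, fast synthetic configurations.

Simulation studies in the tests run on half-scale cell geometry and small
fields; this preserves coverage (fraction of the field occupied by cells),
phenotype contrast and noise levels while keeping pixel counts low.
"""

import dataclasses

import numpy as np
import pytest

from phasedrop import synth


@pytest.fixture(scope="session")
def small_geometry() -> synth.PhantomGeometry:
    """Half-scale cells on a 256 px field at realistic ~35% coverage."""
    return synth.PhantomGeometry(field_shape=(256, 256)).scaled(0.5)


@pytest.fixture(scope="session")
def sparse_geometry() -> synth.PhantomGeometry:
    """Non-overlapping, interior-only cells for per-cell ground-truth tests."""
    geom = synth.PhantomGeometry(field_shape=(256, 256)).scaled(0.5)
    return dataclasses.replace(
        geom, min_separation_frac=1.15, placement_margin_frac=0.15
    )


@pytest.fixture(scope="session")
def small_optics() -> synth.OpticsConfig:
    return synth.OpticsConfig(field_shape=(256, 256))


@pytest.fixture(scope="session")
def quiet_optics() -> synth.OpticsConfig:
    """Noise- and drift-free optics for oracle checks."""
    return synth.OpticsConfig(
        field_shape=(256, 256), opd_noise_sd_nm=0.0, background_drift_amplitude_nm=0.0
    )


@pytest.fixture(scope="session")
def mixed_phantom(small_geometry):
    return synth.make_phantom_field(
        20,
        {"undifferentiated": 0.5, "adipocytic": 0.35, "dead": 0.15},
        small_geometry,
        seed=42,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
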