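"""Ground-truthed synthetic phase and fluorescence fields.

This module builds optical phantoms of differentiating adipocyte cultures:
per-pixel thickness maps ``d(x, y)`` and z-integrated refractive-index maps
``n_c(x, y)`` over a medium of index ``n_m``, from which a quantitative phase
image follows as the optical path difference

    OPD(x, y) = d(x, y) * (n_c(x, y) - n_m)      [nm]

Three cell phenotypes are modelled, matching the morphological definitions
used for label-free classification of stromal-cell adipogenesis:

* ``undifferentiated`` — large, spread cells of moderate thickness and plain
  cytoplasmic refractive index, hence a low OPD signal;
* ``adipocytic`` — equally large cells that additionally carry circular lipid
  droplet inclusions; the droplets' elevated refractive index produces bright
  high-OPD puncta and raises the per-cell mean OPD;
* ``dead`` — small, nearly round, thick caps with a high integrated OPD.

On top of the phantoms the module renders matched fluorescence channels
(nuclear stain, neutral-lipid stain with a faint cytoplasmic component,
dead-cell stain), multi-day differentiation time courses and full
dose-response plates driven by Hill curves in log-concentration, all
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

PHENOTYPES = ("undifferentiated", "adipocytic", "dead")

__all__ = [
    "PHENOTYPES",
    "OpticsConfig",
    "PhantomGeometry",
    "StainConfig",
    "CellTruth",
    "PhantomField",
    "PhaseImage",
    "FluorescenceField",
    "WellSpec",
    "PlateLayout",
    "CompoundResponse",
    "ResponseModel",
    "FieldSet",
    "TimecourseConfig",
    "SimulationConfig",
    "make_phantom_field",
    "render_phase_image",
    "render_fluor_channels",
    "simulate_well_fields",
    "simulate_timecourse",
    "dose_series",
    "expected_adipocytic_fraction",
    "expected_dead_fraction",
    "simulate_dose_response_plate",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging geometry and noise of the phase microscope.

    ``wavelength_nm`` is the laser source wavelength (684 nm red diode, the
    standard source for transmission holographic microscopes); it is recorded
    as metadata and does not enter the OPD forward model.  ``pixel_size_um``
    defaults to a 10x objective scale; use 0.325 for 20x.  ``opd_noise_sd_nm``
    is the additive temporal/shot phase noise per pixel and
    ``background_drift_amplitude_nm`` bounds a smooth low-order polynomial
    background (residual tilt/defocus of the reference arm).
    """

    wavelength_nm: float = 684.0
    pixel_size_um: float = 0.65
    field_shape: tuple[int, int] = (512, 512)
    opd_noise_sd_nm: float = 4.0
    background_drift_amplitude_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.opd_noise_sd_nm < 0:
            raise ValueError("opd_noise_sd_nm must be non-negative")


@dataclass(frozen=True)
class PhantomGeometry:
    """Cell geometry, refractive indices and placement rules for phantoms.

    Thickness profiles are spherical caps ``d(r) = d_max * sqrt(1-(r/R)^2)``.
    Index defaults (medium 1.337, cytoplasm 1.365, lipid droplet 1.470) are
    literature-typical for culture medium, cytoplasm and neutral lipid and
    preserve the ordering that makes droplets the brightest OPD structures.
    Cells may touch; ``min_separation_frac`` caps overlap by requiring the
    centroid distance of any pair to exceed that fraction of the sum of
    their radii.  ``placement_margin_frac`` > 0 keeps centroids away from the
    field edge (useful when border-touching objects would be excluded).
    """

    field_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    medium_index: float = 1.337
    cytoplasm_index: float = 1.365
    droplet_index: float = 1.470
    # (min, max) uniform sampling ranges
    spread_radius_um: tuple[float, float] = (15.0, 30.0)
    spread_thickness_nm: tuple[float, float] = (3000.0, 6000.0)
    dead_radius_um: tuple[float, float] = (4.0, 8.0)
    dead_thickness_nm: tuple[float, float] = (6000.0, 10000.0)
    droplet_radius_um: tuple[float, float] = (1.0, 5.0)
    droplet_area_fraction: tuple[float, float] = (0.15, 0.45)
    min_separation_frac: float = 0.5
    placement_margin_frac: float = 0.0
    max_placement_tries: int = 200

    def scaled(self, factor: float) -> "PhantomGeometry":
        """Return a copy with the cell footprints multiplied by ``factor``.

        Used to pack more cells into small fields for fast simulation
        studies without changing the phenotype contrast structure.  Droplet
        inclusions keep their physical size: organelle scale is independent
        of how spread the cell is (droplets larger than half the cell radius
        are clipped at render time anyway).
        """
        sc = lambda t: (t[0] * factor, t[1] * factor)
        return replace(
            self,
            spread_radius_um=sc(self.spread_radius_um),
            dead_radius_um=sc(self.dead_radius_um),
        )


@dataclass(frozen=True)
class StainConfig:
    """Rendering parameters for the matched fluorescence channels.

    ``lipid_per_nm`` converts droplet optical-path excess (nm) into lipid
    stain counts, so per-cell integrated lipid intensity grows monotonically
    with droplet content.  ``stain_failure`` emulates a failed neutral-lipid
    staining round: the lipid channel (and only it) is scaled by
    ``stain_failure_scale`` globally.
    """

    nucleus_sigma_um: float = 4.0
    nuclear_amplitude: float = 120.0
    cytoplasm_amplitude: float = 6.0
    lipid_per_nm: float = 0.25
    death_amplitude: float = 150.0
    background_level: float = 2.0
    noise_sd: float = 1.0
    psf_sigma_um: float = 1.5
    illumination_amplitude: float = 0.15
    stain_failure: bool = False
    stain_failure_scale: float = 0.08


# ---------------------------------------------------------------------------
# phantom containers


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    phenotype: str
    centroid: tuple[float, float]  # (row, col) pixels
    area_um2: float
    droplet_volume_fraction: float


@dataclass
class PhantomField:
    """Ground-truth optical phantom: thickness + refractive-index maps.

    ``truth_label_map`` assigns each pixel to the cell whose thickness
    dominates there (0 = background), giving truth footprints for
    segmentation-recall scoring.
    """

    thickness_map: np.ndarray  # nm
    refindex_map: np.ndarray  # dimensionless
    medium_index: float
    truth_cells: list[CellTruth]
    truth_label_map: np.ndarray
    pixel_size_um: float

    @property
    def noiseless_opd(self) -> np.ndarray:
        """OPD (nm) implied by the phantom: d * (n_c - n_m)."""
        return self.thickness_map * (self.refindex_map - self.medium_index)


@dataclass
class PhaseImage:
    """A quantitative phase image: per-pixel optical path difference in nm."""

    opd_map: np.ndarray
    optics: OpticsConfig
    provenance: str = ""


@dataclass
class FluorescenceField:
    nuclear_channel: np.ndarray
    lipid_channel: np.ndarray
    death_channel: np.ndarray
    illumination_gradient: np.ndarray
    stain_failure: bool


# ---------------------------------------------------------------------------
# phantom construction


def _split_counts(n_cells: int, phenotype_mix: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n_cells to phenotypes."""
    total = sum(phenotype_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"phenotype fractions must sum to 1, got {total}")
    unknown = set(phenotype_mix) - set(PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotypes: {sorted(unknown)}")
    quotas = {p: n_cells * phenotype_mix.get(p, 0.0) for p in PHENOTYPES}
    counts = {p: int(math.floor(q)) for p, q in quotas.items()}
    short = n_cells - sum(counts.values())
    for p in sorted(PHENOTYPES, key=lambda p: quotas[p] - counts[p], reverse=True):
        if short <= 0:
            break
        counts[p] += 1
        short -= 1
    return counts


def make_phantom_field(
    n_cells: int,
    phenotype_mix: dict[str, float],
    geometry: PhantomGeometry | None = None,
    seed: int | np.random.Generator = 0,
) -> PhantomField:
    """Place ``n_cells`` cells of the given phenotype mix into a phantom.

    Cells are placed by rejection sampling under the pairwise-overlap cap;
    thickness maps compose by per-pixel maximum (a later cell occludes an
    earlier one only where it is thicker).  Droplet inclusions contribute
    excess optical path at the elevated droplet index; the refractive-index
    map absorbs that excess so that ``d * (n_c - n_m)`` reproduces the full
    OPD exactly.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    geom = geometry or PhantomGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = tuple(geom.field_shape)
    ps = geom.pixel_size_um

    thickness = np.zeros(shape, dtype=np.float64)
    droplet_opd = np.zeros(shape, dtype=np.float64)  # nm of droplet OPD excess
    labels = np.zeros(shape, dtype=np.int32)

    counts = _split_counts(n_cells, phenotype_mix)
    # interleave phenotypes so truncation of placement failures stays unbiased
    order: list[str] = []
    for p in PHENOTYPES:
        order.extend([p] * counts[p])
    rng.shuffle(order)

    placed_rc = np.empty((0, 2))
    placed_rad = np.empty(0)
    truth: list[CellTruth] = []
    n_rows, n_cols = shape
    dn_cyto = geom.cytoplasm_index - geom.medium_index
    dn_drop = geom.droplet_index - geom.cytoplasm_index

    for phenotype in order:
        if phenotype == "dead":
            radius_um = rng.uniform(*geom.dead_radius_um)
            d_max = rng.uniform(*geom.dead_thickness_nm)
        else:
            radius_um = rng.uniform(*geom.spread_radius_um)
            d_max = rng.uniform(*geom.spread_thickness_nm)
        r_px = radius_um / ps

        margin = geom.placement_margin_frac
        lo_r, hi_r = margin * n_rows, (1 - margin) * n_rows
        lo_c, hi_c = margin * n_cols, (1 - margin) * n_cols
        pos = None
        for _ in range(geom.max_placement_tries):
            cr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            if placed_rad.size == 0 or np.all(
                np.hypot(cr - placed_rc[:, 0], cc - placed_rc[:, 1])
                >= geom.min_separation_frac * (r_px + placed_rad)
            ):
                pos = (cr, cc)
                break
        if pos is None:
            # field saturated under the overlap cap: keep last candidate
            pos = (cr, cc)
        cr, cc = pos
        placed_rc = np.vstack([placed_rc, [cr, cc]])
        placed_rad = np.append(placed_rad, r_px)
        cell_id = len(truth) + 1

        # local bounding box
        r0 = max(0, int(math.floor(cr - r_px)) - 1)
        r1 = min(n_rows, int(math.ceil(cr + r_px)) + 2)
        c0 = max(0, int(math.floor(cc - r_px)) - 1)
        c1 = min(n_cols, int(math.ceil(cc + r_px)) + 2)
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        ccs = np.arange(c0, c1, dtype=np.float64)[None, :]
        rho2 = (rr - cr) ** 2 + (ccs - cc) ** 2
        inside = rho2 < r_px**2
        cap = np.zeros_like(rho2)
        cap[inside] = d_max * np.sqrt(1.0 - rho2[inside] / r_px**2)

        sub_t = thickness[r0:r1, c0:c1]
        sub_l = labels[r0:r1, c0:c1]
        takeover = cap > sub_t
        sub_t[takeover] = cap[takeover]
        sub_l[takeover] = cell_id

        dvf = 0.0
        if phenotype == "adipocytic":
            target_frac = rng.uniform(*geom.droplet_area_fraction)
            cell_area_px = math.pi * r_px**2
            covered = 0.0
            sub_drop = droplet_opd[r0:r1, c0:c1]
            for _ in range(120):
                if covered >= target_frac * cell_area_px:
                    break
                dr_um = rng.uniform(*geom.droplet_radius_um)
                dr = min(dr_um / ps, 0.5 * r_px)
                # droplets sit in the thicker inner region of the cell
                ang = rng.uniform(0.0, 2 * math.pi)
                rad = 0.7 * r_px * math.sqrt(rng.uniform())
                dcr = cr + rad * math.sin(ang)
                dcc = cc + rad * math.cos(ang)
                # work on the droplet's own sub-box within the cell box
                dr0 = max(r0, int(dcr - dr) - 1) - r0
                dr1 = min(r1, int(dcr + dr) + 2) - r0
                dc0 = max(c0, int(dcc - dr) - 1) - c0
                dc1 = min(c1, int(dcc + dr) + 2) - c0
                if dr0 >= dr1 or dc0 >= dc1:
                    continue
                drho2 = (rr[dr0:dr1] - dcr) ** 2 + (ccs[:, dc0:dc1] - dcc) ** 2
                din = drho2 < dr**2
                path = np.zeros_like(drho2)
                # chord of the droplet sphere, bounded by the cell thickness
                path[din] = 2.0 * dr * ps * 1e3 * np.sqrt(1.0 - drho2[din] / dr**2)
                path = np.minimum(path, cap[dr0:dr1, dc0:dc1])
                sub_drop[dr0:dr1, dc0:dc1] += (
                    np.where(inside[dr0:dr1, dc0:dc1], path, 0.0) * dn_drop
                )
                covered += math.pi * dr**2
            dvf = min(1.0, covered / cell_area_px)

        truth.append(
            CellTruth(
                cell_id=cell_id,
                phenotype=phenotype,
                centroid=(cr, cc),
                area_um2=math.pi * radius_um**2,
                droplet_volume_fraction=dvf,
            )
        )

    refindex = np.full(shape, geom.medium_index, dtype=np.float64)
    body = thickness > 0
    # fold cytoplasm contrast and droplet OPD excess into the z-integrated index
    refindex[body] = (
        geom.medium_index + dn_cyto + droplet_opd[body] / thickness[body]
    )
    labels[~body] = 0
    return PhantomField(
        thickness_map=thickness,
        refindex_map=refindex,
        medium_index=geom.medium_index,
        truth_cells=truth,
        truth_label_map=labels,
        pixel_size_um=ps,
    )


# ---------------------------------------------------------------------------
# rendering


from functools import lru_cache


@lru_cache(maxsize=8)
def _poly_basis(shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)[:, None]
    x = np.linspace(-1.0, 1.0, nx)[None, :]
    one = np.ones(shape)
    return np.stack([x * one, y * one, x * y, x**2 * one, y**2 * one, one])


def _smooth_polynomial_field(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean low-order 2D polynomial surface with max |value| = amplitude."""
    c = rng.uniform(-1.0, 1.0, size=6)
    surf = np.tensordot(c, _poly_basis(tuple(shape)), axes=1)
    surf -= surf.mean()
    peak = np.abs(surf).max()
    if peak > 0:
        surf *= amplitude / peak
    return surf


def render_phase_image(
    phantom: PhantomField,
    optics: OpticsConfig | None = None,
    seed: int | np.random.Generator = 0,
    provenance: str = "synthetic",
) -> PhaseImage:
    """Render the phantom's OPD map with phase noise and background drift.

    The noiseless component is exactly ``d(x,y) * (n_c(x,y) - n_m)``;
    additive Gaussian noise (``opd_noise_sd_nm``) and a smooth polynomial
    drift (``background_drift_amplitude_nm``) are superposed.
    """
    optics = optics or OpticsConfig(
        pixel_size_um=phantom.pixel_size_um, field_shape=phantom.thickness_map.shape
    )
    if tuple(phantom.thickness_map.shape) != tuple(optics.field_shape):
        raise ValueError(
            f"phantom shape {phantom.thickness_map.shape} != optics field_shape "
            f"{optics.field_shape}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    opd = phantom.noiseless_opd.copy()
    if optics.background_drift_amplitude_nm > 0:
        opd += _smooth_polynomial_field(
            opd.shape, optics.background_drift_amplitude_nm, rng
        )
    if optics.opd_noise_sd_nm > 0:
        opd += rng.normal(0.0, optics.opd_noise_sd_nm, size=opd.shape)
    return PhaseImage(opd_map=opd, optics=optics, provenance=provenance)


def render_fluor_channels(
    phantom: PhantomField,
    stain_config: StainConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> FluorescenceField:
    """Render nuclear / neutral-lipid / dead-cell stain channels.

    Nuclei are Gaussian blobs at every cell centroid (live and dead).  The
    lipid channel combines a faint whole-cytoplasm component (the membrane
    staining used to build cytoplasm masks) with a droplet term proportional
    to the phantom's droplet optical-path excess, making integrated per-cell
    lipid intensity strictly monotone in droplet content.  The dead-cell
    channel is bright only over dead cells.  One smooth multiplicative
    illumination gradient is shared by all channels.
    """
    cfg = stain_config or StainConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = phantom.thickness_map.shape
    ny, nx = shape
    ps = phantom.pixel_size_um

    nuclear = np.zeros(shape)
    death = np.zeros(shape)
    sigma_px = cfg.nucleus_sigma_um / ps
    yy = np.arange(ny, dtype=np.float64)
    xx = np.arange(nx, dtype=np.float64)
    for cell in phantom.truth_cells:
        cr, cc = cell.centroid
        amp = cfg.nuclear_amplitude * rng.uniform(0.8, 1.2)
        sig = sigma_px * (0.6 if cell.phenotype == "dead" else 1.0)
        r0 = max(0, int(cr - 4 * sig))
        r1 = min(ny, int(cr + 4 * sig) + 1)
        c0 = max(0, int(cc - 4 * sig))
        c1 = min(nx, int(cc + 4 * sig) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        gy = np.exp(-0.5 * ((yy[r0:r1, None] - cr) / sig) ** 2)
        gx = np.exp(-0.5 * ((xx[None, c0:c1] - cc) / sig) ** 2)
        blob = amp * gy * gx
        nuclear[r0:r1, c0:c1] += blob
        if cell.phenotype == "dead":
            death[r0:r1, c0:c1] += (cfg.death_amplitude / cfg.nuclear_amplitude) * blob

    body = phantom.thickness_map > 0
    droplet_opd = phantom.thickness_map * (
        phantom.refindex_map - phantom.medium_index
    ) - phantom.thickness_map * _cytoplasm_contrast(phantom)
    droplet_opd = np.clip(droplet_opd, 0.0, None)
    lipid = cfg.cytoplasm_amplitude * body + cfg.lipid_per_nm * droplet_opd
    if cfg.psf_sigma_um > 0:
        # wide-field optical blur spreads droplet signal over the cell body
        from scipy import ndimage

        lipid = ndimage.gaussian_filter(lipid, sigma=cfg.psf_sigma_um / ps)
    if cfg.stain_failure:
        lipid = lipid * cfg.stain_failure_scale

    gradient = 1.0 + _smooth_polynomial_field(shape, cfg.illumination_amplitude, rng)
    channels = []
    for ch in (nuclear, lipid, death):
        img = (ch + cfg.background_level) * gradient
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=shape)
        channels.append(np.clip(img, 0.0, None))
    return FluorescenceField(
        nuclear_channel=channels[0],
        lipid_channel=channels[1],
        death_channel=channels[2],
        illumination_gradient=gradient,
        stain_failure=cfg.stain_failure,
    )


def _cytoplasm_contrast(phantom: PhantomField) -> float:
    """Cytoplasm-over-medium index contrast implied by droplet-free pixels."""
    body = phantom.thickness_map > 0
    if not body.any():
        return 0.0
    # droplet-free body pixels carry exactly the cytoplasm contrast
    contrasts = phantom.refindex_map[body] - phantom.medium_index
    return float(np.min(contrasts))


# ---------------------------------------------------------------------------
# wells, time courses and plates


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    compound: str | None = None
    concentration: float | None = None  # molar
    induced: bool = False
    n_fields: int = 4

    def __post_init__(self) -> None:
        if self.compound is not None and (
            self.concentration is None or self.concentration <= 0
        ):
            raise ValueError(f"well {self.well_id}: compound requires concentration > 0")


@dataclass(frozen=True)
class PlateLayout:
    wells: tuple[WellSpec, ...]

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well_ids must be unique")


@dataclass(frozen=True)
class CompoundResponse:
    """Hill-curve response of adipocytic differentiation to one compound.

    Agonists raise the adipocytic fraction from ``baseline_fraction`` toward
    ``max_fraction`` on non-induced wells; antagonists suppress it from the
    induced plateau back toward baseline.  Concentrations above
    ``toxicity_threshold`` (molar; None = non-toxic) recruit extra dead
    cells, the behaviour reported for PPARγ inhibitors above ~10 µM.
    """

    direction: str  # "agonist" | "antagonist"
    true_ec50: float  # molar
    hill_slope: float = 1.0
    baseline_fraction: float = 0.05
    max_fraction: float = 0.70
    toxicity_threshold: float | None = None
    toxicity_max_dead: float = 0.25

    def __post_init__(self) -> None:
        if self.direction not in ("agonist", "antagonist"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.true_ec50 <= 0:
            raise ValueError("true_ec50 must be positive")
        if not (0.0 <= self.baseline_fraction <= self.max_fraction <= 1.0):
            raise ValueError("need 0 <= baseline <= max <= 1")


ResponseModel = dict[str, CompoundResponse]


@dataclass
class FieldSet:
    """One imaging field: phantom truth plus rendered phase (and stains)."""

    phantom: PhantomField
    phase: PhaseImage
    fluor: FluorescenceField | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs for well/time-course/plate simulation."""

    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    stain: StainConfig = field(default_factory=StainConfig)
    cells_per_field: int = 25
    fields_per_well: int = 4
    baseline_dead_fraction: float = 0.02
    well_noise_sd: float = 0.02  # SD of per-well adipocytic-fraction jitter
    render_fluor: bool = True


@dataclass(frozen=True)
class TimecourseConfig(SimulationConfig):
    """Six-day differentiation time-course conditions.

    Induced wells follow a saturating adipocytic-fraction curve
    ``b + (m - b) * (1 - exp(-(day-1)/tau))`` — no differentiation yet on
    day 1, plateau ``plateau_fraction`` by ~day 5.  Non-induced wells stay at
    the spontaneous-differentiation baseline (~5% of confluent
    preadipocytes).
    """

    baseline_fraction: float = 0.05
    plateau_fraction: float = 0.70
    rise_tau_days: float = 1.5
    n_wells_per_arm: int = 8
    nile_red_failure_day: int | None = None


def _well_mix(
    adipo: float, dead: float, rng: np.random.Generator, well_noise_sd: float
) -> dict[str, float]:
    """Perturb expected fractions into a realizable phenotype mix."""
    a = adipo + rng.normal(0.0, well_noise_sd) if well_noise_sd > 0 else adipo
    a = float(np.clip(a, 0.0, 1.0))
    d = float(np.clip(dead, 0.0, 1.0 - a))
    return {"adipocytic": a, "dead": d, "undifferentiated": 1.0 - a - d}


def simulate_well_fields(
    mix: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    stain_override: StainConfig | None = None,
) -> list[FieldSet]:
    """Render the imaging fields of one well with multinomial cell counts."""
    fields = []
    probs = [mix.get(p, 0.0) for p in PHENOTYPES]
    for _ in range(config.fields_per_well):
        counts = rng.multinomial(config.cells_per_field, probs)
        field_mix = (
            {p: c / config.cells_per_field for p, c in zip(PHENOTYPES, counts)}
            if config.cells_per_field > 0
            else {"undifferentiated": 1.0}
        )
        phantom = make_phantom_field(
            config.cells_per_field, field_mix, config.geometry, rng
        )
        phase = render_phase_image(phantom, config.optics, rng)
        fluor = None
        if config.render_fluor:
            fluor = render_fluor_channels(
                phantom, stain_override or config.stain, rng
            )
        fields.append(FieldSet(phantom=phantom, phase=phase, fluor=fluor))
    return fields


def induced_fraction_curve(day: float, config: TimecourseConfig) -> float:
    """Expected adipocytic fraction of an induced well on a given day."""
    b, m = config.baseline_fraction, config.plateau_fraction
    return b + (m - b) * (1.0 - math.exp(-(day - 1.0) / config.rise_tau_days))


def iter_timecourse_wells(
    days: int,
    induced: bool,
    config: TimecourseConfig,
    rng: np.random.Generator,
):
    """Yield ``(fields, truth_row)`` per well of one time-course arm.

    Streaming counterpart of :func:`simulate_timecourse`: callers quantify
    each well as it is produced, so rendered fields never accumulate.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    arm = "induced" if induced else "control"
    for day in range(1, days + 1):
        expected = (
            induced_fraction_curve(day, config) if induced else config.baseline_fraction
        )
        stain = config.stain
        if config.nile_red_failure_day == day:
            stain = replace(stain, stain_failure=True)
        for w in range(config.n_wells_per_arm):
            well_id = f"{arm}_d{day}_w{w:02d}"
            mix = _well_mix(
                expected, config.baseline_dead_fraction, rng, config.well_noise_sd
            )
            fields = simulate_well_fields(mix, config, rng, stain_override=stain)
            yield fields, {
                "day": day,
                "arm": arm,
                "well_id": well_id,
                "expected_adipocytic": expected,
                "realized_adipocytic": _realized_fraction(fields, "adipocytic"),
                "realized_dead": _realized_fraction(fields, "dead"),
                "stain_failure": stain.stain_failure,
            }


def simulate_timecourse(
    days: int,
    induced: bool,
    config: TimecourseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, dict[str, list[FieldSet]]], pd.DataFrame]:
    """Simulate one arm of the differentiation time course.

    Returns ``(fields, truth)`` where ``fields[day][well_id]`` holds the
    rendered fields of one well and ``truth`` records per-well expected and
    realized phenotype fractions per day.  All fields stay in memory; large
    studies should consume :func:`iter_timecourse_wells` instead.
    """
    cfg = config or TimecourseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[int, dict[str, list[FieldSet]]] = {}
    rows = []
    for fields, row in iter_timecourse_wells(days, induced, cfg, rng):
        out.setdefault(row["day"], {})[row["well_id"]] = fields
        rows.append(row)
    return out, pd.DataFrame(rows)


def _realized_fraction(fields: Sequence[FieldSet], phenotype: str) -> float:
    cells = [c for f in fields for c in f.phantom.truth_cells]
    if not cells:
        return float("nan")
    return sum(c.phenotype == phenotype for c in cells) / len(cells)


# -- dose response ----------------------------------------------------------


def dose_series(
    top: float = 100e-6, bottom: float = 4.6e-9, n: int = 14
) -> np.ndarray:
    """Geometrically spaced concentration series, highest first (molar).

    Defaults reproduce a 14-point series from 100 µM down to 4.6 nM; the
    dilution ratio (~2.16x) is fixed by the endpoints.
    """
    return np.geomspace(top, bottom, n)


def expected_adipocytic_fraction(model: CompoundResponse, concentration: float) -> float:
    """Hill-curve expected adipocytic fraction at one concentration."""
    c, k, h = concentration, model.true_ec50, model.hill_slope
    occ = c**h / (c**h + k**h)
    b, m = model.baseline_fraction, model.max_fraction
    if model.direction == "agonist":
        return b + (m - b) * occ
    return m - (m - b) * occ


def expected_dead_fraction(
    model: CompoundResponse, concentration: float, baseline_dead: float
) -> float:
    """Dead fraction: baseline plus a toxicity term above the threshold."""
    extra = 0.0
    thr = model.toxicity_threshold
    if thr is not None and concentration > thr:
        extra = model.toxicity_max_dead * (1.0 - (thr / concentration) ** 1.5)
    return min(1.0, baseline_dead + extra)


def simulate_dose_well(
    well: WellSpec,
    model: ResponseModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[FieldSet], dict]:
    """Simulate one dose-plate well: rendered fields plus its truth row.

    The expected adipocytic fraction follows the compound's Hill curve; a
    per-well Gaussian response jitter of ``well_noise_sd`` (in units of the
    compound's dynamic range) is added before cells are drawn multinomially.
    """
    if well.compound is None:
        expected = 0.70 if well.induced else 0.05
        dead = config.baseline_dead_fraction
        dyn = 0.65
    else:
        cmp_model = model[well.compound]
        expected = expected_adipocytic_fraction(cmp_model, well.concentration)
        dead = expected_dead_fraction(
            cmp_model, well.concentration, config.baseline_dead_fraction
        )
        dyn = cmp_model.max_fraction - cmp_model.baseline_fraction
    noisy = expected + (
        rng.normal(0.0, config.well_noise_sd * dyn) if config.well_noise_sd > 0 else 0.0
    )
    mix = _well_mix(noisy, dead, rng, well_noise_sd=0.0)
    well_cfg = replace(config, fields_per_well=well.n_fields)
    fields = simulate_well_fields(mix, well_cfg, rng)
    row = {
        "well_id": well.well_id,
        "compound": well.compound,
        "concentration_molar": well.concentration,
        "induced": well.induced,
        "expected_adipocytic": expected,
        "realized_adipocytic": _realized_fraction(fields, "adipocytic"),
        "expected_dead": dead,
        "realized_dead": _realized_fraction(fields, "dead"),
    }
    return fields, row


def check_layout_compounds(layout: PlateLayout, model: ResponseModel) -> None:
    unknown = {
        w.compound for w in layout.wells if w.compound is not None
    } - set(model)
    if unknown:
        raise KeyError(f"compounds missing from response model: {sorted(unknown)}")


def simulate_dose_response_plate(
    layout: PlateLayout,
    model: ResponseModel,
    config: SimulationConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, list[FieldSet]], pd.DataFrame]:
    """Simulate every well of a dose-response plate, keeping all fields.

    Returns ``(fields_by_well, truth_table)``.  All rendered fields are held
    in memory, so this suits small plates and tests; large studies should
    iterate ``simulate_dose_well`` and quantify each well before moving on.
    """
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    check_layout_compounds(layout, model)
    fields_by_well: dict[str, list[FieldSet]] = {}
    rows = []
    for well in layout.wells:
        fields, row = simulate_dose_well(well, model, cfg, rng)
        fields_by_well[well.well_id] = fields
        rows.append(row)
    return fields_by_well, pd.DataFrame(rows)
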