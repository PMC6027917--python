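"""Screening statistics: Z', linear correlation and 4PL dose-response fits.

The Z' factor is the standard screening-window coefficient

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|,

bounded above by 1, negative when the control distributions overlap.
Dose-response curves are fitted with the four-parameter logistic (4PL)
model in log10 concentration,

    r(x) = bottom + (top - bottom) / (1 + 10^(h * (log10 x - log10 m))),

whose inflection ``m`` is reported as the relative IC50/EC50.  Fits whose
midpoint falls beyond the highest tested concentration, or whose dynamic
range is indistinguishable from noise, are censored ("> max tested") rather
than reported as numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares

__all__ = [
    "ZPrimeResult",
    "LinearFit",
    "DoseResponseFit",
    "zprime",
    "linear_fit_r2",
    "four_pl",
    "fit_4pl",
    "recovery_study",
]


@dataclass(frozen=True)
class ZPrimeResult:
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    z_prime: float
    valid: bool = True


def zprime(pos_values, neg_values) -> ZPrimeResult:
    """Screening-window coefficient between positive and negative controls.

    Uses sample standard deviations (ddof=1).  Equal arm means leave the
    window undefined; the result is then flagged invalid with NaN rather
    than raising, so plate-level summaries can carry the flag along.
    """
    pos = np.asarray(pos_values, dtype=np.float64)
    neg = np.asarray(neg_values, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two values per arm")
    mp, mn = float(pos.mean()), float(neg.mean())
    sp, sn = float(pos.std(ddof=1)), float(neg.std(ddof=1))
    if mp == mn:
        return ZPrimeResult(mp, sp, mn, sn, float("nan"), valid=False)
    z = 1.0 - 3.0 * (sp + sn) / abs(mp - mn)
    return ZPrimeResult(mp, sp, mn, sn, z)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def linear_fit_r2(x, y) -> LinearFit:
    """Ordinary least squares with R^2 and the two-sided slope t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if np.ptp(y) == 0:  # flat response: no variance explained
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0)
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def four_pl(x, top: float, bottom: float, log10_mid: float, hill: float) -> np.ndarray:
    """Four-parameter logistic response at concentrations ``x`` (molar).

    With ``hill > 0`` the curve falls from ``top`` at low concentration to
    ``bottom`` at high concentration (inhibitor orientation); ``hill < 0``
    rises (enhancer orientation).
    """
    logx = np.log10(np.asarray(x, dtype=np.float64))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log10_mid)))


@dataclass
class DoseResponseFit:
    """4PL fit result with censoring status.

    After orientation normalisation ``bottom <= top``; ``hill_slope > 0``
    then means response falls with concentration.  ``censored`` marks fits
    whose midpoint lies beyond the tested range or whose amplitude is within
    noise; their potency should be read as "> max tested", available as
    ``ic50_label``.
    """

    top: float
    bottom: float
    hill_slope: float
    ic50: float  # molar (fitted midpoint, even when censored)
    r_squared: float
    censored: bool
    n_points: int
    converged: bool
    max_tested: float
    residual_sd: float = float("nan")
    diagnostics: str = ""

    @property
    def ic50_label(self) -> str:
        if self.censored:
            return f"> {self.max_tested:.3g} M"
        return f"{self.ic50:.3g} M"


def fit_4pl(
    concentrations,
    responses,
    flat_amplitude_sds: float = 2.0,
    max_tested: float | None = None,
) -> DoseResponseFit:
    """Fit the 4PL model by bounded least squares in log10 concentration.

    Three deterministic multi-starts (falling and rising orientation at the
    median log concentration, plus an endpoint-slope-informed start) guard
    against the local minima of logistic fitting.  A fit is censored when the
    midpoint exceeds the highest tested concentration (``max_tested``; by
    default the highest concentration present, but callers that exclude
    wells upstream should pass the designed maximum) or when the fitted
    amplitude is below ``flat_amplitude_sds`` residual standard deviations —
    a curve flat within noise carries no potency information.
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(responses, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("concentrations and responses must align")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        keep = np.isfinite(y)
        x, y = x[keep], y[keep]
    if np.unique(x).size < 4:
        raise ValueError("need at least four distinct concentrations")

    logx = np.log10(x)
    lo, hi = logx.min(), logx.max()
    y_lo = float(y[np.argsort(logx)[:4]].mean())  # mean at lowest doses
    y_hi = float(y[np.argsort(logx)[-4:]].mean())
    span = float(y.max() - y.min()) or 1.0

    def residual(theta):
        top, bottom, log_mid, hill = theta
        return four_pl(x, top, bottom, log_mid, hill) - y

    bounds = (
        [y.min() - span, y.min() - span, lo - 3.0, -6.0],
        [y.max() + span, y.max() + span, hi + 3.0, 6.0],
    )
    starts = [
        np.array([y.max(), y.min(), np.median(logx), 1.0]),
        np.array([y.max(), y.min(), np.median(logx), -1.0]),
        np.array([y_lo, y_hi, 0.5 * (lo + hi), 1.0 if y_lo >= y_hi else -1.0]),
    ]
    best, best_cost = None, np.inf
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            sol = least_squares(residual, theta0, bounds=bounds, xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost

    n = int(x.size)
    if max_tested is None:
        max_tested = float(x.max())
    if best is None:
        return DoseResponseFit(
            *(float("nan"),) * 4,
            r_squared=float("nan"),
            censored=False,
            n_points=n,
            converged=False,
            max_tested=max_tested,
            diagnostics="all optimizer starts failed",
        )

    top, bottom, log_mid, hill = best.x
    if top < bottom:  # normalise orientation: bottom <= top
        top, bottom, hill = bottom, top, -hill
    resid = best.fun
    dof = max(1, n - 4)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    ic50 = float(10.0**log_mid)
    amplitude = float(top - bottom)
    flat = amplitude < flat_amplitude_sds * residual_sd
    censored = flat or ic50 > max_tested
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        hill_slope=float(hill),
        ic50=ic50,
        r_squared=r2,
        censored=censored,
        n_points=n,
        converged=bool(best.success),
        max_tested=max_tested,
        residual_sd=residual_sd,
        diagnostics="flat within noise" if flat else "",
    )


def recovery_study(
    model,
    n_reps: int = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    sim_config=None,
    concentrations=None,
    wells_per_concentration: int = 4,
) -> pd.DataFrame:
    """Monte-Carlo potency recovery through the full imaging pipeline.

    For each replicate a dose-response plate for one compound is simulated
    (``noise_sd`` sets the per-well response jitter as a fraction of the
    compound's dynamic range), every well is segmented and its pooled mean
    OPD measured, the four fields per well are averaged, and a 4PL curve is
    fitted to the well responses.  Returns one row per replicate with the
    true and estimated midpoint, relative error and censoring status.
    """
    from . import synth
    from .phase import aggregate_well, count_cells, fixed_threshold_segment, mean_opd

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = sim_config or synth.SimulationConfig(render_fluor=False)
    cfg = synth_replace_noise(cfg, noise_sd)
    conc = (
        np.asarray(concentrations, dtype=np.float64)
        if concentrations is not None
        else synth.dose_series()
    )
    wells = tuple(
        synth.WellSpec(
            well_id=f"c{i:02d}_r{r}",
            compound="test",
            concentration=float(c),
            induced=model.direction == "antagonist",
            n_fields=cfg.fields_per_well,
        )
        for i, c in enumerate(conc)
        for r in range(wells_per_concentration)
    )
    layout = synth.PlateLayout(wells=wells)
    response_model = {"test": model}

    synth.check_layout_compounds(layout, response_model)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        xs, ys = [], []
        # one well at a time: fields are quantified and discarded immediately
        for well in layout.wells:
            fields, _ = synth.simulate_dose_well(well, response_model, cfg, rng)
            opds, counts = [], []
            for fs in fields:
                mask = fixed_threshold_segment(fs.phase)
                opds.append(mean_opd(fs.phase, mask))
                counts.append(count_cells(mask))
            wm = aggregate_well(opds, counts, well_id=well.well_id)
            if not wm.no_cells:
                xs.append(well.concentration)
                ys.append(wm.mean_opd)
        fit = fit_4pl(xs, ys)
        est = fit.ic50
        rows.append(
            {
                "rep": rep,
                "true_ec50": model.true_ec50,
                "estimated_ec50": est,
                "relative_error": est / model.true_ec50 - 1.0,
                "censored": fit.censored,
                "converged": fit.converged,
                "r_squared": fit.r_squared,
                "hill_slope": fit.hill_slope,
            }
        )
    return pd.DataFrame(rows)


def synth_replace_noise(cfg, noise_sd: float):
    """Return a SimulationConfig copy with the well response jitter set."""
    import dataclasses

    return dataclasses.replace(cfg, well_noise_sd=noise_sd)
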