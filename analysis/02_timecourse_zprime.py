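#!/usr/bin/env python
"""Six-day differentiation time course: screening window and stain agreement.

Simulates induced vs non-induced wells over six days (four imaging fields
per well), quantifies every well by pooled OPD and by the two fluorescence
lipid readouts, and reports the per-day Z' screening window plus the
label-free-vs-stain correlations.  A staged Nile-Red staining failure on
day 4 demonstrates why the flagged cytoplasm-mask readout matters.
"""

from pathlib import Path

from phasedrop import pipeline, synth

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    shape = (360, 360)
    tc = synth.TimecourseConfig(
        geometry=synth.PhantomGeometry(field_shape=shape).scaled(0.5),
        optics=synth.OpticsConfig(field_shape=shape),
        cells_per_field=50,
        fields_per_well=2,
        n_wells_per_arm=8,
        render_fluor=True,
        nile_red_failure_day=4,
    )
    config = pipeline.RunConfig(seed=2, timecourse=tc, days=6)
    # perinuclear measurement radius follows the half-scale cell geometry
    config.lipid_radius_um = 10.0
    result = pipeline.run_timecourse(config, outdir=OUT / "timecourse")

    print("per-day screening window (Z') between induced and control arms:")
    print(result.zprime[["day", "z_prime"]].round(2).to_string(index=False))
    print(
        "\nThe window opens as lipid droplets accumulate: negative/near-zero "
        "while the arms overlap, above 0.5 once differentiation plateaus."
    )
    print("\nlabel-free OPD vs fluorescence lipid readouts (well-level):")
    print(result.correlations.round(3).to_string(index=False))
    print(f"\ntables under {OUT / 'timecourse'}")


if __name__ == "__main__":
    main()
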