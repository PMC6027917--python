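#!/usr/bin/env python
"""Render ground-truthed example fields of the three cell phenotypes.

Writes a small set of phase + fluorescence fields (float32 TIFF) with the
matching per-cell truth table, and prints the per-phenotype OPD summary
that motivates the whole assay: undifferentiated cells read low, lipid
droplet-bearing adipocytic cells read high, dead cells read small/round/high.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from phasedrop import io, synth

OUT = Path(__file__).resolve().parents[1] / "results" / "example_fields"


def main() -> None:
    geom = dataclasses.replace(
        synth.PhantomGeometry(field_shape=(384, 384)),
        min_separation_frac=1.05,
        placement_margin_frac=0.1,
    )
    optics = synth.OpticsConfig(field_shape=(384, 384))
    mix = {"undifferentiated": 0.45, "adipocytic": 0.4, "dead": 0.15}
    rng = np.random.default_rng(0)

    rows = []
    for i in range(4):
        phantom = synth.make_phantom_field(8, mix, geom, rng)
        fs = synth.FieldSet(
            phantom=phantom,
            phase=synth.render_phase_image(phantom, optics, rng),
            fluor=synth.render_fluor_channels(phantom, seed=rng),
        )
        io.write_field_set(OUT / f"field{i:02d}", fs)
        opd = phantom.noiseless_opd
        for cell in phantom.truth_cells:
            pixels = opd[phantom.truth_label_map == cell.cell_id]
            rows.append(
                {
                    "field": i,
                    "cell_id": cell.cell_id,
                    "phenotype": cell.phenotype,
                    "area_um2": cell.area_um2,
                    "droplet_volume_fraction": cell.droplet_volume_fraction,
                    "mean_opd_nm": pixels.mean() if pixels.size else np.nan,
                }
            )
    truth = pd.DataFrame(rows)
    truth.to_csv(OUT / "truth_cells.csv", index=False)

    summary = truth.groupby("phenotype").agg(
        n=("cell_id", "size"),
        mean_area_um2=("area_um2", "mean"),
        mean_opd_nm=("mean_opd_nm", "mean"),
    )
    print(f"wrote 4 fields + truth table to {OUT}")
    print(summary.round(1).to_string())
    print(
        "\nAdipocytic cells out-read undifferentiated ones by "
        f"{summary.loc['adipocytic', 'mean_opd_nm'] - summary.loc['undifferentiated', 'mean_opd_nm']:.0f} nm "
        "of mean OPD - the label-free differentiation signal."
    )


if __name__ == "__main__":
    main()
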