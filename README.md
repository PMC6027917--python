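# phasedrop

Label-free quantification of lipid droplets in differentiating adipocytes
from quantitative phase images, rebuilt as a tested analysis pipeline over
ground-truthed synthetic data.

## The problem

In-vitro differentiating adipocytes are fragile: staining and washing
perturb them, and mature cells detach and float.  Quantitative phase
imaging (digital holographic microscopy) sidesteps all liquid handling by
measuring, per pixel, the optical path difference

```
OPD(x, y) = d(x, y) · (n_c(x, y) − n_m)      [nm]
```

— cell thickness `d` times the contrast between the z-averaged
intracellular refractive index `n_c` and the medium index `n_m`.  Lipid
droplets have a high refractive index, so differentiation is readable
directly from the phase image.  This package is for anyone who wants to
analyse (or stress-test analyses of) such assays: it implements the full
measurement chain — segmentation at a fixed threshold above background,
pooled per-cell OPD, four-fields-per-well averaging, per-cell phenotype
classification (undifferentiated / adipocytic / dead / error), the
fluorescence comparison branch, Z′ screening statistics and
censoring-aware four-parameter-logistic (4PL) dose-response fits with
IC50 — together with a physics-based synthetic generator that provides
ground truth for every step.

## Layout

```
src/phasedrop/        the library
  synth.py            optical phantoms, stains, time courses, dose plates
  phase.py            segmentation, intermeans threshold, OPD, well aggregation
  classify.py         per-cell features, rules, RF/k-NN classifiers
  fluor.py            illumination correction, nuclei, lipid & death stains
  stats.py            Z', OLS, 4PL fitting, Monte-Carlo potency recovery
  pipeline.py         end-to-end time-course / dose-response drivers
  evaluate.py         IoU matching and truth scoring of simulated fields
  io.py, cli.py       float32 TIFF + CSV + YAML I/O, `phasedrop` CLI
analysis/             numbered narrative drivers (01–05), write results/
tests/                pytest suite incl. end-to-end validation
scripts/acceptance.py recomputes the potency-recovery benchmarks
```

## Worked example

Simulate a mixed field, segment it, and read the label-free signal:

```python
import numpy as np
from phasedrop import synth, phase, classify

geom = synth.PhantomGeometry()           # 512x512 px, 0.65 um/px
phantom = synth.make_phantom_field(
    25, {"undifferentiated": 0.55, "adipocytic": 0.4, "dead": 0.05},
    geom, seed=1)
image = synth.render_phase_image(phantom, seed=2)

mask = phase.fixed_threshold_segment(image)      # median + 3 robust SD
print(f"threshold {mask.threshold:.1f} nm, "
      f"{phase.count_cells(mask)} cells, "
      f"mean OPD {phase.mean_opd(image, mask):.1f} nm")

records = classify.classify_cells_rules(
    classify.extract_cell_features(image, mask))
by_class = {p: sum(r.phenotype == p for r in records)
            for p in ("undifferentiated", "adipocytic", "dead")}
print(by_class, f"dead fraction {classify.dead_fraction(records):.2f}")
```

prints

```
threshold 36.4 nm, 12 cells, mean OPD 154.1 nm
{'undifferentiated': 4, 'adipocytic': 8, 'dead': 0} dead fraction 0.00
```

The threshold sits just above the 4 nm phase noise and 8 nm background
drift; the pooled mean OPD (154 nm here, ~92 nm for the same field
rendered fully undifferentiated) is the differentiation readout, and the
small/round/high-OPD rule scores dead cells without any stain.  (Counts
are objects after border exclusion; touching cells merge, as in the
original workflow, and the single dead cell of this field merged into a
neighbour.)

The numbered analyses tell the full story — `python analysis/02_timecourse_zprime.py`
simulates the six-day induced-vs-control course and prints the per-day
screening window, e.g.

```
 day  z_prime
   1    -3.76
   2     0.25
   3     0.30
   4     0.52
   5     0.65
   6     0.40
```

(negative while the arms overlap, > 0.5 once differentiation plateaus)
plus the label-free-vs-stain correlations (R² ≈ 0.76 for the perinuclear
lipid readout, ≈ 0.44 for the nonlinear cytoplasm-mask readout);
`03` reproduces the dead-cell concordance (R² ≈ 0.95 against the
death stain on 32 toxicity wells); `04` fits the six-compound PPARγ
modulator panel end to end, censoring the compound whose potency lies
beyond the tested range; `05` runs the Monte-Carlo potency recovery.

## Scope

The pipeline starts from reconstructed phase maps: hologram recording,
numerical reconstruction, PSF/diffraction modelling and refractive-index
tomography are out of scope, as are FACS, RT-PCR and biochemical assays
that the imaging readout is compared against in the wet lab.
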