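# Methods

`phasedrop` reimplements, as a tested pipeline over synthetic ground truth,
a label-free assay of adipocyte differentiation read out by quantitative
phase imaging.  This note records the models, the parameters that matter,
and the design choices made where the underlying experimental description
left the design open.

## The optical model

A quantitative phase image reports, per pixel, the optical path difference

    OPD(x, y) = d(x, y) * (n_c(x, y) - n_m)        [nm]

where `d` is the cell thickness, `n_c` the z-averaged intracellular
refractive index and `n_m` the medium index.  The assay rests on one fact:
neutral-lipid droplets have a markedly higher refractive index than
cytoplasm, so differentiating adipocytes light up without any stain.

The phantom generator composes fields of three phenotypes:

| phenotype        | footprint radius | max thickness | refractive structure |
|------------------|------------------|---------------|----------------------|
| undifferentiated | 15–30 µm         | 3–6 µm        | cytoplasm only       |
| adipocytic       | 15–30 µm         | 3–6 µm        | cytoplasm + droplets |
| dead             | 4–8 µm           | 6–10 µm       | cytoplasm, high cap  |

Thickness profiles are spherical caps; droplets are spherical inclusions
(radius 1–5 µm, covering 15–45% of the cell footprint) whose chord length,
clipped to the local cell thickness, contributes optical path at the
droplet index.  The droplet excess is folded into the refractive-index map
so that `d × (n_c − n_m)` reproduces the full OPD identically — this
identity is an invariant of the test suite.  Index defaults are
literature-typical: medium 1.337, cytoplasm 1.365, droplet 1.470.  No
absolute OPD calibration exists for these cells, so the simulated
magnitudes are conventions that preserve the qualitative contrast ordering
(droplet ≫ cytoplasm > background), not calibrated values.

Noise is additive Gaussian phase noise (default SD 4 nm) plus a smooth
low-order polynomial background drift (default peak 8 nm), which is what
makes "a threshold slightly above the background" a nontrivial operation.
Hologram recording, numerical reconstruction, diffraction and PSF physics
are out of scope; the generator produces already-reconstructed OPD maps.

Cell density defaults to 25 cells per 512×512 field at 0.65 µm/pixel
(≈35% area coverage), the density implied by plating ~2,000 cells per
384-well and imaging four fields covering about a fifth of the well.
Where studies need more measured cells per well, the geometry can be
scaled down (cell footprints shrink; droplets keep their physical size,
since organelle scale does not follow cell spread) at constant coverage.

## The measurement chain

* **Segmentation for OPD quantification** — a fixed threshold slightly
  above background: `median + offset_sd × 1.4826 × MAD` over the whole
  image (default `offset_sd = 3`).  The robust estimators require the
  background to be the majority phase of the image, which holds up to
  roughly 50% cell coverage.  Components below 20 µm² are dropped;
  8-connectivity; no declumping (touching cells count as one object, as in
  the original workflow).
* **Pooled OPD** — the arithmetic mean OPD over all segmented-cell pixels.
  Objects touching the field border stay in this pool; border exclusion
  applies only to counting and classification, where partial objects would
  corrupt per-cell features.  An empty mask yields NaN, never a silent 0.
* **Well aggregation** — the four fields imaged per well are averaged;
  fields without cells are dropped and a well with no cells anywhere is
  flagged rather than numbered.
* **Ridler–Calvard (intermeans) threshold** — iterated
  `t ← (mean(values ≤ t) + mean(values > t))/2` from the midrange, to
  |Δt| < 1e-8.  A histogram can admit several fixed points in adjacent
  gaps; the midrange-initialised iteration selects one of them, and the
  test suite verifies the result against exhaustive fixed-point
  enumeration (and against an independent isodata implementation).  On
  these phase images the intermeans cut lands between background and the
  bright cell cores, so per-cell phenotyping uses the fixed
  background-offset mask, which preserves full cell footprints; the
  intermeans threshold drives nucleus detection and the cytoplasm mask in
  the fluorescence branch.
* **Per-cell features** — area, Crofton perimeter, form factor
  (4π·area/perimeter², 1 for a circle), eccentricity, mean/integrated OPD,
  and two droplet-sensitive summaries (within-cell OPD SD and 90th
  percentile): droplet-bearing cells carry bright puncta that mark them
  even when their mean OPD is ambiguous.
* **Phenotype rules** — dead ⇔ small (< 200 µm²) ∧ round (form factor
  > 0.85) ∧ high OPD; adipocytic ⇔ large ∧ high OPD; undifferentiated ⇔
  large ∧ low OPD; anything else (e.g. small dim debris) is `error` and is
  excluded from fraction denominators.  The OPD cut (120 nm) sits midway
  between the simulated cytoplasm-only and droplet-bearing per-cell means
  under the default geometry; all three cuts are configuration, calibrated
  once against simulator truth because the source workflow defines the
  classes only qualitatively.  Trained classifiers (Random Forest, 100
  trees, or k-NN, k = 5, fixed seed) learn the same classes from simulator
  truth labels and are evaluated on held-out fields.
* **Fluorescence branch** — channels are divided by a Gaussian blur of
  themselves (kernel FWHM 100 µm — division, not subtraction, because the
  simulated gradient is multiplicative) and rescaled to preserve the
  median; residual gradients survive within ~2 kernel widths of the field
  edge.  Nuclei come from an intermeans threshold on the corrected nuclear
  channel.  The neutral-lipid readout is the median intensity in a 20 µm
  disk around each nucleus (nucleus region included; the disk radius
  should follow the cell scale when the geometry is scaled), summarised as
  median-over-cells and mean-over-fields.  The cytoplasm-mask readout
  thresholds the log-intensity histogram to build the mask from faint
  membrane staining and reports the field median of per-cell medians; an
  empty mask — the signature of a failed staining round — yields a flagged
  NaN instead of a number.  Death-stain positivity uses a fixed cutoff set
  at the 99.9th percentile of pooled negative-control fields.

The two lipid readouts behave differently by construction: the
perinuclear-disk median responds roughly linearly to the adipocytic
fraction, while the mask-median readout is nearly flat until
droplet-bearing cells become the majority of a field (a median of
per-cell medians only moves once most cells move).  The simulated
time course accordingly shows a strong OPD-vs-disk correlation and a
weaker, nonlinear OPD-vs-mask correlation — the same ordering the
stain-based reference methods show in practice.

## Screening statistics

* **Z′** — `1 − 3(σ₊ + σ₋)/|μ₊ − μ₋|` with sample SDs, computed between
  induced and non-induced wells per day (well-level replicates).  Equal
  means leave the window undefined and are flagged, not raised.
* **Linear concordance** — ordinary least squares with R² and the
  two-sided slope t-test; single planned comparisons, so no multiplicity
  correction.
* **Dose response** — the four-parameter logistic in log10 concentration,
  `r(x) = bottom + (top − bottom)/(1 + 10^(h(log x − log m)))`, fitted by
  bounded least squares from three deterministic starts (both
  orientations at the median log-dose plus an endpoint-informed start);
  the reported potency is the fitted inflection `m` (relative IC50/EC50).
  A fit is **censored** ("> max tested") when `m` exceeds the highest
  tested concentration or when the fitted amplitude is below twice the
  residual SD — a curve flat within noise carries no potency information.
  Orientation is normalised so `bottom ≤ top`; `h > 0` then means the
  response falls with concentration.

## The simulated experiments

**Time course** — induced wells follow
`b + (m − b)(1 − exp(−(day − 1)/τ))` with spontaneous baseline `b = 0.05`
(confluent preadipocytes differentiate at ~5% on their own), plateau
`m = 0.70` and τ = 1.5 days: no differentiation yet on day 1, plateau by
day ~5.  Non-induced wells stay at baseline.  With four fields per well
and realistic cell counts the per-day Z′ reproduces the canonical
trajectory of this assay: deeply negative on day 1, climbing above 0.5 by
the plateau days.

**Dose-response plates** — wells whose label-free dead fraction exceeds a
QC cutoff (default 0.15) are excluded from the 4PL fits, because
cytotoxicity confounds the differentiation readout — without this
exclusion a flat compound's toxicity bump above 10 µM is fitted as a
spurious rising curve.  Censoring always compares the fitted midpoint
against the *designed* maximum concentration, not the post-QC maximum.
The cost of the exclusion is visible in the simulated panel: an inhibitor
whose bottom plateau falls inside the toxic range has its midpoint
estimated by extrapolation and biased high on a single plate.  Each
compound acts through a Hill curve in
concentration on the adipocytic fraction: enhancers raise non-induced
wells from baseline toward the plateau, inhibitors pull induced wells
back down.  The default panel uses the published potencies as generating
truth: T0070907 1.49 µM, GW9662 4.49 µM, BADGE beyond the tested range
(truth placed at 10 mM so the pipeline must censor it), rosiglitazone
19.5 nM, pioglitazone 1.23 µM, indomethacin 2.77 µM.  Inhibitors are
additionally toxic above 10 µM: the dead fraction rises smoothly above
that threshold (up to +0.25 at high dose).  Fourteen concentrations span
100 µM to 4.6 nM geometrically (dilution ratio ≈2.16, fixed by the
endpoints, which are all the dose design specifies).

**Potency recovery** (`pipeline.potency_recovery`, `analysis/05`,
`scripts/acceptance.py`) — per replicate: simulate a plate (4 wells per
concentration, 4 fields per well, per-well Gaussian response jitter at 5%
of the compound's dynamic range on top of the multinomial cell sampling),
segment, measure pooled OPD, average fields, fit the 4PL, record the
midpoint; the study reports the median over 20 replicates.  The recovery
protocol runs the pure Hill response (toxicity term off): it isolates the
dose-response machinery, while toxicity handling is exercised separately
by the dead-cell concordance analyses.  The study runs on 512 px fields
with half-scale cell footprints at ~35% coverage (≈400 measured cells per
well), which keeps the binomial component of the well noise near 2% of
the dynamic range.  Under these conditions the two antagonist potencies
are recovered essentially without bias (median within ~1% of truth,
per-replicate SD 9–16%).  The enhancer benchmark is harder: its midpoint
sits only ~0.6 decades above the lowest tested dose, so the bottom
asymptote is always extrapolated; the measurement chain adds a small
systematic (about −7% on the noise-free mean curve, from the mild
nonlinearity of the pooled-OPD response map) and the per-replicate spread
is 25–35%, so 20-replicate medians scatter roughly ±10% around that
value.  The 4PL optimiser keeps the three deterministic starts; denser
start grids were evaluated and do not reduce this spread — it is
statistical, not an optimisation artifact.

## What the synthetic data does and does not show

The generator emulates the statistical structure the analysis relies on —
phenotype-dependent OPD contrast, monotone stain response, field-to-field
and well-to-well sampling noise, illumination gradients, staged staining
failures, dose-dependent mixtures — but not real optics (speckle,
diffraction halos, reconstruction artifacts), real biology (cell shape
irregularity, droplet size evolution, detachment of mature adipocytes) or
real stain chemistry.  Passing tests therefore certify the measurement
chain's correctness and statistical behaviour on data that obey its
assumptions; they do not certify instrument-specific robustness.  Two
known idealisations matter most: truth footprints are disks (segmentation
recall is easier than on ragged real cells), and the phenotype classes are
generated from exactly the feature axes the classifier uses.

## Numerical details and degenerate inputs

Intermeans on a constant image raises a degenerate-histogram error.  Empty
masks, zero-nucleus fields, empty cytoplasm masks and wells with no cells
anywhere propagate as flagged NaNs, never as zeros.  4PL fitting clips
start points into bounds, reports `converged = False` with diagnostics on
optimizer failure, and treats non-finite responses by dropping the points.
All generators are bitwise-reproducible under a fixed seed; simulation
studies derive per-replicate seeds from a seed sequence so replicates are
independent but replayable.  The large simulation drivers stream well by
well — fields are quantified and discarded immediately — so memory stays
flat (~250 MB) regardless of plate size; the all-at-once simulators that
return every rendered field are kept for small plates and tests.  Simulation sizes used by the tests and the
acceptance study (field size, cells per field, wells per arm, replicate
counts) are stated in the corresponding drivers and were chosen as the
smallest sizes at which the Monte-Carlo error of each summary is small
against the margin it is compared to.
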