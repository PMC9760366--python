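# Methods

This note documents the models, operators, defaults and design choices
behind `exomod`, and what the synthetic data do and do not establish
about real screens.

## The screening model

A compound's effect on exosome traffic is observed through two
complementary readouts measured on the same plate:

* **Extracellular signal** — a proximity assay counts tetraspanin
  (CD9/CD63) double-positive vesicles in the supernatant. The raw
  per-well count is proportional to released vesicles times the number
  of live cells, so it is first divided by the well's nuclei count and
  then expressed as percent of the vehicle-control mean within the same
  cell-line context. By construction the control group's mean is exactly
  100%.
* **Intracellular signal** — LBPA-positive puncta per cell, a proxy for
  vesicles retained in multivesicular bodies, normalized to percent of
  control the same way.

Hit calling reduces each percent value to LOW (< 80), HIGH (> 120) or
UNCHANGED. The cut-offs are strict inequalities (exactly 80.0 is
UNCHANGED) and configurable. On the extracellular side LOW needs no
significance test (the published rule attaches "significantly" only to
the activator direction) while HIGH requires a significant Dunnett
comparison; on the LBPA side both directions require significance.
Both behaviours are parameters of `readout_state`.

The mechanism call is a total function of the state pair. Three pairs
carry biological labels (release inhibitor = LOW/HIGH, biogenesis
inhibitor = LOW/LOW, biogenesis activator = HIGH/HIGH). Pairs with an
unchanged extracellular readout are INACTIVE regardless of the LBPA
state — an intracellular change alone is not a hit. The remaining pairs
(LOW/UNCHANGED, HIGH/UNCHANGED, HIGH/LOW) are UNCLASSIFIED: an
extracellular hit without a coherent intracellular signature should not
be forced into one of the three defined mechanisms, and we deliberately
do not invent a fourth label for HIGH/LOW.

## Statistics

* **Z'-factor**: `1 − 3(σp + σn)/|μp − μn|` with sample standard
  deviations (n−1). Computed on the per-nucleus signal scale from
  positive (exosome-rich supernatant) and negative (medium-only
  background) assay-control wells. Z' ≤ 1 always; > 0.5 is conventionally
  an excellent assay and the synthetic defaults sit near 0.9.
* **Dunnett many-to-one**: two-sided, via the multivariate-t
  distribution of the pooled-variance comparison statistics
  (`scipy.stats.dunnett`, quasi-Monte-Carlo integration seeded for
  reproducibility). Raw per-comparison p-values use the same pooled-t
  statistics uncorrected; the adjusted value is clamped to never fall
  below the raw one. A permutation max-T oracle re-derives the adjusted
  p-values independently in the test suite.
* **Trend test**: Jonckheere–Terpstra ordered-alternative statistic over
  increasing doses (ties count half), with a two-sided label-permutation
  p-value, default 10 000 permutations, seeded. The "monotone" flag
  requires p ≤ 0.05 *and* a decreasing direction, i.e. dose-dependent
  inhibition. This statistic is implemented in-package because no
  installed library provides it.
* **Viability gate**: a condition is excluded when its mean nuclei count
  falls below (1 − max_toxicity) of the control's. Default
  max_toxicity = 0.20; 0.15 reproduces the stricter gate used for the
  final hit table. Exclusions are flagged and logged, never dropped
  silently; lowering the threshold can only exclude more conditions.
* α = 0.05 throughout, with `*`/`**`/`***` at 0.05/0.01/0.001.

## Synthetic plates

`generate_screen_plate` draws, per well,
`alpha = baseline_alpha · multiplier · viability · LN(1, cv)` and
`nuclei = round(baseline_nuclei · viability · LN(1, cv))` with
independent unit-mean log-normal factors. Log-normal noise was chosen
because plate-reader counts are positive and noise is multiplicative.
Defaults: 6 wells per condition, baseline 100 000 counts and 5 000
nuclei per well, noise_cv = 0.03. The noise default follows from the
assay's own quality claim: a screening-grade plate with Z' ≥ 0.75 and a
signal-level positive control implies a control CV below roughly 8%, and
3% is typical of a well-optimized AlphaScreen plate. Positive controls
are simulated at 2× the vehicle signal, negative controls at 0.02×
(medium background); which wells serve as Z' controls is configuration,
since the source protocol does not name them.

With noise off, normalization recovers the effect multipliers exactly
(percent of control = 100 · multiplier); this identity anchors the
noiseless unit tests.

## Synthetic fields

`generate_field_image` draws non-overlapping elliptical cells (axis
ratio 0.75–1, random orientation) each containing one nuclear disk, on a
512×512 16-bit canvas: nuclei ~7 000 grey levels over a 200-level
background, cytoplasm ~2 500, Gaussian granule spots of amplitude 3 000
and σ = radius/1.5, plus Gaussian read noise (σ = 10). Granule counts
per cell are Poisson (default mean 5). Granules are placed in the
cytoplasm with a minimum centre separation of one granule diameter: they
model *resolvable* puncta, matching what a connected-component counter
(the original analyzer or this package) can enumerate. Artifact spots
use the same profile but are placed at least 1.3 cell radii from every
cell centre. Cell placement uses bounded rejection sampling and fails
loudly, reporting the achieved count, when the field is overcrowded.

The generator intentionally omits: optical PSF and illumination falloff,
cell-shape irregularity, touching/confluent monolayers, z-structure, and
intensity heterogeneity between granules beyond placement randomness.
Passing tests therefore demonstrate that the quantification chain is
*correct* (it recovers known truth under its stated assumptions), not
that it is *robust* to the full variability of real micrographs —
segmentation parameters will need retuning on real data.

## Image quantification

* Nuclei: Gaussian smoothing (σ = 2) → Otsu threshold → hole filling →
  area filter (≥ 150 px) → distance-transform watershed seeded at local
  maxima ≥ 10 px apart, which splits touching nuclei.
* Cells: Otsu foreground of the smoothed cytoplasm channel united with
  the nucleus pixels, then seeded watershed on inverted cytoplasm
  intensity with the nucleus labels as seeds, so every cell inherits its
  nucleus label; a nucleus outside the stained foreground degrades to a
  nucleus-only cell and is logged.
* A blank-image guard declares a channel empty when the Otsu split
  separates fore- from background by less than 4 background standard
  deviations; Otsu on pure noise otherwise fabricates objects.
* Granules: white top-hat (disk radius 6 px) → threshold at the top-hat
  median + 5·MAD (raw MAD, not rescaled to σ) → watershed declumping
  seeded at intensity maxima ≥ 4 px apart → components kept in
  [4, 400] px. The MAD threshold makes detection invariant to global
  intensity rescaling. Saturated fields (> 50% of pixels at 65 535) are
  flagged low-confidence.
* Assignment: a granule belongs to the cell label under its rounded
  centroid; label 0 granules are extracellular artifacts, counted but
  excluded from every per-cell metric. Centroid assignment (rather than
  area overlap) is unambiguous for spots much smaller than cells.
* Well aggregation pools all fields first and reports the ratio of
  totals (in-cell granules / nuclei), which is robust to fields with few
  cells; mean-of-ratios would overweight sparse fields.

Pixel coordinates are 0-based (row, col); label images use positive
integers with 0 background.

## Reference screen fixture

The deterministic fixture encodes the published qualitative outcome of
the 14-compound breast-cancer screen in two contexts (MDA-MB-453 and
MCF7): four extracellular hits in MDA-MB-453 (docetaxel, biscurcumin,
primaquine, doxorubicin), five in MCF7 (plus dinaciclib), the remaining
compounds as activators, Go6983 as release-inhibitor control and
GW4869/spiroepoxide as biogenesis-inhibitor controls, with matched
intracellular LBPA levels (elevated for release inhibitors, depleted
for biogenesis inhibitors, elevated for corroborated activators).
Effect multipliers are invented magnitudes placed safely on the correct
side of the cut-offs, because the source reports these values only
graphically; the per-compound qualitative classes ship as metadata that
no analysis code reads. MCF7 dose ladders follow the published
narrative: biscurcumin decreases at every dose, doxorubicin and
dinaciclib rebound at the highest dose, docetaxel and primaquine are
flat. The fixture uses an internal fixed seed and 3% well noise, so
regeneration is byte-identical.

## Problem sizes

Test- and acceptance-scale runs use 512×512 fields with ~12 cells each
(20 fields per simulated well), 6 wells per condition, 10⁴ trend-test
permutations and 2·10⁴ oracle permutations — sizes chosen so the full
suite completes in about a minute on one core while leaving Monte-Carlo
error well below the tolerances being asserted.

## Known limitations

* The classifier consumes only granule *counts*; granule area and
  intensity are emitted for audit but not used downstream.
* Dunnett comparisons are computed per readout and per context;
  no joint model across readouts, and no plate-effect (edge/drift)
  correction or mixed-effects structure.
* The decision table treats cut-offs as hard boundaries; compounds near
  80%/120% flip states with small changes in normalization.
* Segmentation defaults target the synthetic geometry; real micrographs
  need parameter review (they are all exposed on
  `SegmentationParams`/`GranuleParams`).
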