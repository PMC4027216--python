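# Methods

This note documents the models, the tunable parameters, the synthetic-data
design and the numerical choices behind `hdrscreen`, in the order the
pipeline runs.

## Segmentation

Nuclei are detected on the DAPI channel by Gaussian pre-smoothing
(`smoothing_sigma`, default 1 px), Otsu's histogram threshold, hole
filling, and a distance-transform watershed seeded at smoothed
distance-map maxima (`min_distance`, default 8 px) to split touching
nuclei. Regions touching the image border are discarded (their cytoplasmic
ring cannot be measured), as are regions outside `[min_area, max_area]`
(defaults 80–2000 px²; these size limits are configuration, not constants,
because the bounds used at screen time were instrument-software settings).
Because the threshold is histogram-based, segmentation is invariant to a
constant additive intensity offset.

The cytoplasmic ring of a nucleus is the set of background pixels at
Euclidean distance `(inner_gap, inner_gap + ring_width]` from it
(defaults 1 px gap, 4 px width), with contested pixels assigned to the
nearest nucleus and every nucleus pixel excluded from every ring. A
nucleus crowded in so tightly that no ring pixel remains is flagged
`ring_failed` and excluded from the translocation gate rather than
dividing by a missing cytoplasm.

Perimeters use the Crofton (smooth-contour) estimator. This matters: naive
boundary-pixel counting inflates a digitized disk's perimeter by ~13%,
which would push the form factor of a perfect circle to ~1.27 and silently
re-interpret the 1.48 cutoff. With the Crofton estimator a digitized
r = 20 px disk lands within a few percent of 2πr and its form factor
within 0.05 of 1.

## Per-cell features and the selection cascade

* `form_factor = P²/(4πA)` — 1 for a perfect circle, larger for irregular
  shapes.
* `nuc_cv` — population SD over mean of the nuclear DAPI pixels
  ("population of pixels" read literally, hence `ddof = 0`; with a sample
  SD the 0.19 cutoff would mean something slightly different).
* `nc_ratio` — mean nuclear mCherry over mean ring mCherry. Per-field
  background (median of pixels outside all nuclei and rings) is subtracted
  from each channel's means first, so ratios are comparable across fields
  with different baselines.

The cascade applies, in order: translocation (`nc_ratio` strictly
**greater than** 1.05 required), form factor (strictly **below** 1.48
required), CV (strictly **above** 0.19 rejected — exactly 0.19 is kept).
Boundary strictness follows the screen's published wording; the order only
affects which rejection class a cell is attributed to, never the final
selected set, and the rejection classes plus `selected` always partition
the detected cells (auditable in the log and the cells table).

GFP positivity is not defined by an instrument constant; the default rule
calibrates a threshold per plate as median + k·1.4826·MAD (k = 3) of the
nuclear GFP of selected cells in no-break control wells — robust to the
few true positives that contaminate any real negative population — with a
fixed-threshold mode as the escape hatch when no calibration wells exist.

## Well scoring, normalization and hit calling

Per well: `hdr_frequency = n_gfp_positive / n_selected`. The bounded
fraction is used rather than a positive:negative odds ratio; at
screen-typical frequencies (< 5%) the two differ by < 5% relative. Wells
with fewer than `min_cells` (default 50) selected cells are flagged
`low_count` and excluded from control statistics instead of imputed.

Each plate is normalized to its own vehicle-control mean
(`normalized_hdr = 100 · hdr / mean(DMSO hdr)`), requiring at least two
usable DMSO wells; this removes multiplicative plate effects exactly (a
tested invariance). Compound wells are then averaged across replicate
plates (unweighted; under-replication flagged below `min_replicates`).

Hits: `z = (compound mean − DMSO mean)/DMSO SD`, activator for `z > 4`,
repressor for `z < −4`, both strict; a 3-SD near-hit band is reported. The
SD is taken by default over the individual normalized DMSO well values
pooled across every plate of the run (`dmso_sd_mode="pooled"`); a
`"dots"` mode first averages each control well position over its replicate
plates, matching a reading in which every point of the screen's scatter —
controls included — is a three-plate average. Pooled is the more
conservative default (the per-well SD is √3 larger than the SD of
three-plate averages, so the same k guards harder against false calls).
No multiple-testing correction is applied beyond the fixed-SD rule — that
is the screen's criterion, not an FDR procedure. Plate QC compares edge
(rows A/H, columns 1/12) versus interior vehicle wells with a two-sided
Mann–Whitney test at α = 0.01.

**Power note.** With the pooled SD, a repressor at 1% against a 3%
vehicle baseline (a 67% drop) clears 4 SD only when the per-well binomial
noise is small enough: the normalized per-well SD is
≈ 100·√(0.97/(0.03·n_sel)) %, and requiring the lower calling boundary
100 − 4·SD to sit above 33.3 (with margin for the compound's own
replicate noise) gives n_sel ≳ 2000 selected cells per well. The
count-level screen simulations therefore use `n_cells = 2500` per well at
translocation fraction 0.8 (≈ 2000 selected) — far above the `min_cells`
= 50 usability floor.

## Dose-response

The symmetric 4PL on log₁₀-dose is fit by least squares
(`scipy.optimize.curve_fit`), parameterised in `log10(ec50)` with slope
sign and midpoint initialised from the data. Constant responses and
failed optimisations return an explicit non-convergence flag, never a
silent answer; a fitted `top ≈ bottom` is likewise degenerate. IC50 is the
fitted midpoint (= ec50 of the symmetric model); an absolute-50%
definition against a stated reference is available as an option.
Uncertainty comes from a seeded residual bootstrap (default 1000
resamples, percentile interval); no asymptotic SEs are reported. The fit
is invariant to row order and, up to parameter rescaling, to uniform
response rescaling (ec50 unchanged) — both tested.

The synthetic titration used for recovery testing is
`FourPL(bottom = 0, top = 100, hill = 2.5, ec50 = 15 µM)` sampled on an
8-point 2-fold dilution series from 120 µM with Gaussian noise of SD 5
(percent-of-control units) and 3 replicates. The steep slope and the
bracketing 2-fold series reflect the assay this models — a repressor that
nearly abolishes HDR within a factor of ~3 above its midpoint — and a
Fisher-information check shows midpoint recovery to ±10% is only reliably
achievable (≥ 95% of fits) for slopes ≳ 2 at this noise level; with
hill ≈ 1 the median midpoint error alone is ~9%.

## Synthetic data: what it emulates, what it does not

The generator draws, per well, cell phenotypes (healthy / apoptotic /
dead), translocation state and HDR state, then renders three channels:

* **DAPI**: elliptical nuclei, healthy mean radius ~ U(8, 14) px with axis
  ratio ≤ 1.6 (form factors ≲ 1.1, well below 1.48); apoptotic nuclei
  condensed (radius U(4, 6) px), 1.6× brighter, with multiplicative
  chromatin texture of relative SD 0.24 versus 0.06 for healthy — 4× the
  healthy texture, set so the measured nuclear CV (which also absorbs
  boundary-ramp pixels of the segmented mask) falls cleanly above 0.19
  for apoptotic and below for healthy nuclei. Dead cells render as
  scattered low-DAPI debris fragments with broadband signal, mostly below
  the nuclear threshold.
* **mCherry**: a cytoplasm ellipse (2.2× nuclear radii) at U(800, 1200)
  intensity; nuclear level = cytoplasm × U(1.4, 2.2) for translocated
  cells and × U(0.4, 0.8) for resident cells.
* **GFP**: nuclear signal (~1500) only in cells drawn translocated *and*
  HDR-positive; no-break wells are modelled as translocated but never cut
  (nuclease-dead), so they still yield selected cells for GFP calibration.

Shapes are painted hard-edged, softened with a σ = 0.5 px Gaussian (an
optics stand-in, applied before the chromatin texture, which is structure
rather than blur), then background (≈ 100), Gaussian read noise (SD 40)
and shot-like noise (SD = 2·√intensity) are added; 16-bit clipped output.
Cell placement is rejection sampling with a 3 px margin between nuclei
(an `overlap_fraction` option permits controlled overlap to exercise
watershed splitting). Default noise is deliberately set so that
classification against ground truth is very good but not perfect —
noiseless images would make the threshold tests vacuous.

Determinism: one plate seed; per-well/per-field seeds derive from
`crc32(plate_seed : well : field)`, so identical specs reproduce
bit-identical images and any single field can be regenerated alone.

Not emulated: point-spread-function optics, 3-D structure, time-lapse,
cell-cycle or line-specific morphology, spatial plate gradients (except
when injected deliberately for QC tests), focus failures, illumination
shading. Passing tests therefore demonstrate the *analysis* is correct
under the assay's assumed statistics, not that segmentation would survive
arbitrary real-microscope pathology.

## Problem sizes used in the test suite

Image-based checks run at 512×512 px fields with 60–150 cells: selection
fidelity uses three fields per phenotype class; per-well frequency
recovery images a full 96-well plate at 2 fields/well and compares each
well's called GFP⁺ count to the exact binomial 95% interval of its true
rate. Screen-level statistics (spike recovery over 20 seeded screens, and
null calibration with 1280 inert compounds × 20 screens) run on the
count-level simulator — the identical binomial structure the renderer
draws from, through the identical statistics code path — because rendered
pixels add nothing to a property of well-level counts. IC50 recovery uses
100 seeded titrations. All randomness is seeded; the suite is
deterministic end to end.

## Known limitations

* The segmentation stand-in (Otsu + watershed) is a reproducible
  replacement for the original instrument software, whose algorithm is
  proprietary; absolute feature values (and hence the printed thresholds)
  are only guaranteed meaningful relative to this pipeline's estimators.
* The ring (nucleus-mask vs cytoplasm-annulus) is a declared convention;
  other region pairs would shift the 1.05 boundary's effective meaning.
* The HDR-frequency denominator (fraction of selected cells) and the
  percent-of-DMSO normalization are the simplest readings consistent with
  the assay; odds-ratio and per-plate-SD variants exist as options but are
  not the tested defaults.
* 4PL fits are symmetric; strongly asymmetric curves (5PL territory) are
  out of scope.
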