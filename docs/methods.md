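# Methods

## Measurement model

The package operates purely on binary segmentation masks. Physical
quantities are exact count-times-size conversions: luminal area is
set-pixel count × pixel area (default pixel 200/140 ≈ 1.429 mm, i.e.
2.041 mm² per pixel), gastric content volume is set-voxel count × voxel
volume. Masks containing values outside {0, 1} are rejected rather than
thresholded: segmentation quality control belongs upstream, and silent
coercion would hide faults there. Pixel/voxel sizes are read from the
NIfTI header; if a JSON sidecar disagrees, the sidecar wins and a
warning is logged (acquisition metadata is usually curated more
carefully than resampled headers).

## Spectral frequency detection

Area–time curves (n = ⌊duration × frame rate⌋ samples; 1123 at the
default 180 s × 6.24 fps) are mean-removed and linearly detrended, then
the one-sided discrete amplitude spectrum 2|X_k|/n is evaluated at the
bin frequencies k·f_s/n. Band membership is a bin-center test, inclusive
at both edges; the default band 0.03–0.07 Hz contains 7 bins (k = 6…12)
for a 180 s record.

Numerical choices, all of which are assumptions where the measurement
convention is stated only to band/bin precision:

- **Detrending** (mean + linear) is applied because slow physiological
  drift otherwise leaks into the bins adjacent to the band. The
  subtracted ramp itself has small spectral content at every bin, so a
  noiseless on-bin sinusoid shows a dominance factor slightly below the
  ideal bin-count value (≈ 6.7 rather than 7 with 7 bins); the recovered
  frequency is unaffected.
- **No zero-padding or peak interpolation**: the reported frequency is
  an exact bin center (resolution f_s/n ≈ 0.33 cpm at 180 s). A
  measured 3.12 cpm-scale precision does not warrant sub-bin estimation,
  and interpolation would complicate the dominance definition.
- **Dominance factor** = peak amplitude / mean amplitude over *all*
  in-band bins, peak included (the definition "ratio of peak amplitude
  to the mean amplitude within the band" does not exclude it). Peaks
  below 1e-9 mm² are treated as an empty band (dominance 0, invalid) so
  that float round-off on a constant curve cannot manufacture a
  dominance ratio.
- **Ties** between equal peak amplitudes resolve to the lower frequency
  (deterministic).
- **Validity**: dominance ≥ 2.0; a timepoint frequency exists only when
  ≥ 2 of 3 slices are valid, and averages the *valid* slices only —
  invalid slices carry no trustworthy peak. Frequencies are averaged in
  cpm (identical to averaging Hz and converting, since the mean is
  linear). Velocity is reported only where the timepoint frequency is
  defined.
- **Record length matters**: below ~120 s the band holds so few bins
  that the dominance factor is capped near the bin count and the 2.0
  criterion becomes hard to clear even for clean signals. This is a
  property of the criterion, not a defect; the default protocol's 180 s
  records are the intended operating point.

## Apparent propagation speed

Speed is a closed form of frequency and slice geometry: with thickness
h, distance factor c (gap g = c·h) and propagation distance
D = 3h + 2g, v = f/60 × D. It assumes one contraction wave traverses
the slice extent per period — an *apparent* speed, not a tracked wave
front. The speed/frequency ratio is D/60 for every record, which the
pipeline tests as an identity.

## Occlusion

Reference area per sequence: the median of the k = max(1, ⌈0.10 n⌉)
largest areas (ceil keeps the set non-empty for short curves; an even k
takes the midpoint of the two central values). Occlusion is
max(0, 100 × (1 − A/ref)) per frame; negative values (frames larger than
the reference) are clipped because the lumen cannot be "more relaxed
than relaxed". Occlusion and the dominance factor are invariant under
rescaling all areas by a positive constant.

## Volumetry

The emptying rate is the OLS slope over the closed window [41, 81] min
(with exactly two points this is the difference quotient; with the
default three, "linear slope" means a fit). The caloric rate rescales
volumes by anchor/V(baseline) with a 300 kcal anchor at the −5 min
pre-water measurement; by OLS linearity the caloric rate equals the
volumetric rate × anchor / V(baseline) to machine precision, which is
asserted as an identity. The anchor is a deliberate crude convention —
it ignores secretion and early digestion — and is exposed as a
parameter, as are the window and the baseline label (a protocol may
place the pre-water reference at −3 min; the formula is applied to
whatever single negative-labelled timepoint the series carries).

ΔGCV(t) = GCV(t) − GCV(baseline) is returned as its own series type
because it legitimately goes negative once the meal has emptied below
the pre-water content; forcing it into the non-negative volume container
would corrupt late timepoints.

## The digital phantom

The generator emulates the statistical structure of a two-arm crossover
study: 12 subjects × 2 meal arms (solid / liquid), 6 volumetric
timepoints (−5, 3, 21, 41, 61, 81 min) and 5 real-time timepoints
(7, 25, 45, 65, 85 min) of 3 sagittal slices — 144 volumetric and 360
dynamic records.

**Peristalsis.** Per-slice area is
A(t) = μ + drift·t + a·sin(2π f₀/60 t − φ_s) + a_r·sin(2π f_r/60 t) + ε,
clipped at 0. Phase offsets place one wavelength across the propagation
distance (slice centers h + g apart, φ_s = 2π s (h+g)/D), so the
frequency-times-geometry apparent speed is the generative truth by
construction. Cohort defaults: f₀ ~ N(3.1, 0.25) cpm clipped to the
band interior; baseline areas ~ N(600, 60) mm² per slice; relative
contraction depth grows from ~0.22 to ~0.55 across the postprandial
timepoints (emulating the observed progressive occlusion increase);
respiration at 15 cycles/min (0.25 Hz — outside the detection band, so
band restriction is actually exercised; amplitude 5% of baseline);
drift ~ N(0, 0.2) mm²/s; area noise SD 15 mm². Distance factors are
drawn per subject × arm uniformly from the protocol's 1.5–3.0 range.

**Emptying.** V(t < 0) = v_meal0; for t ≥ 0,
V(t) = max(0, v_meal0 − r·t) + water0·e^(−k t) + ε: linear caloric-meal
emptying under a fast first-order water phase (the Magenstrasse route).
Arm defaults are the reported cohort means: meal volume 298 ± 31 mL
(solid) / 263 ± 26 mL (liquid), linear rate 2.24 ± 0.65 / 2.23 ± 0.58
mL/min, water 240 mL, k ~ U(0.12, 0.20) /min (water essentially gone by
41 min, and the 3 min measurement lands in the reported post-water
range), volume noise SD 8 mL applied to post-ingestion measurements
(the baseline is the bare meal volume by definition of the model).

**Rasterization.** Areas become centered filled 2:1 ellipses
(pixel-center membership; the estimators are shape-agnostic, any convex
shape would do), so the pixel-count area differs from the requested one
by at most the boundary-pixel ring — asserted frame-wise. Areas too
large for an inscribed 2:1 ellipse fall back to a rank-based center-out
fill, which covers the degenerate full-grid mask exactly. Volumes become
center-out voxel balls with exactly round(V / voxel volume) voxels
(single connected component). Noise is additive Gaussian on the *area*,
not on pixels: sufficient for recovery testing, and pixel-level boundary
noise would only re-measure the quantization bound.

**Reproducibility.** Every record's seed is
SHA-256("master|subject|arm|timepoint[|slice]") truncated to 4 bytes, so
any record regenerates in isolation; identical (design, raster, seed)
yields a bit-identical bundle, asserted down to file bytes.

**What the phantom does not emulate** — and what passing tests therefore
do not show about scanner data: MR contrast, reconstruction and
segmentation error (masks are geometrically clean); antral anatomy
(ellipses, not lumen shapes); non-sinusoidal or intermittent
peristalsis; respiration-induced through-plane motion (respiration is
additive in area only); secretion volume; correlated noise across
slices or timepoints. Recovery results bound estimator error under the
stated signal model, not segmentation robustness.

## Pipeline behavior

Bundles carry masks (NIfTI + JSON sidecars) and always also the
curve/volume tables; `write_masks=False` produces a table-only bundle
that the analysis consumes directly — the full default cohort then
simulates and analyzes in a few seconds, whereas full-resolution mask
stacks (1123 × 140 × 140 per record × 360 records) are multi-gigabyte
and reserved for reduced designs or real deployments. The test suite
exercises the mask path on a reduced design and the table path on the
full design; all defaults are identical in both.

Records failing analysis (all-zero mask, too-short curve, corrupt file)
are skipped with machine-parsable reason codes (`zero_reference_area`,
`corrupt_mask`, …), listed in `exclusions.csv`, and flag the run as
partially complete; timepoints failing the two-of-three rule remain in
the tables with NaN frequency/velocity so inclusion counts are directly
readable. Aggregation uses sample SD (n − 1); a single contributing
subject reports SD as missing.
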