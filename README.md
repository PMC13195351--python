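# gastromri

Quantitative postprandial gastric motility and emptying from MRI
segmentation masks — with a seeded digital phantom so the whole pipeline
can be developed and validated without scanner data.

## Who this is for

Researchers quantifying gastric motor function from dynamic MRI: after a
test meal, free-breathing real-time MRI of the antrum (three sagittal
slices, ~6.24 frames/s for 180 s) and breath-hold volumetric imaging of
the gastric contents are segmented into binary masks. This package takes
those masks and turns them into the standard motility and emptying
metrics, handling all the validity bookkeeping along the way. Because
subject-level imaging data usually cannot be shared, the package also
ships a phantom generator that emits complete synthetic study cohorts
(masks, metadata, ground truth) with the same statistical structure, so
every estimator is testable end to end against known truth.

## What it computes

**Contraction frequency.** Each slice's luminal cross-sectional area
A(t) (pixel count × pixel area) is mean-removed, linearly detrended, and
Fourier transformed. The dominant peak is searched in the peristalsis
band 0.03–0.07 Hz (1.8–4.2 cpm) and accepted only if its *dominance
factor* — peak amplitude over mean in-band amplitude — reaches 2.0. A
subject × timepoint yields a frequency only when at least two of the
three slices carry a valid peak (their valid peaks are averaged).

**Apparent propagation speed.** With slice thickness *h* and inter-slice
gap *g* (distance factor × *h*), the slices span a propagation distance
*D* = 3*h* + 2*g*. Assuming one wave period traverses *D*,

    v (mm/s) = f (cpm) / 60 × D (mm).

**Occlusion.** Per sequence, the reference area is the median of the
top-10% largest areas; each frame scores

    occlusion % = 100 × (1 − A / A_ref),  clipped below at 0,

so 100% is complete antral closure. Occlusion is an imaging surrogate of
contraction amplitude.

**Volumetry.** Gastric content volume (GCV) is voxel count × voxel
volume. ΔGCV(t) = GCV(t) − GCV(−5 min) removes the pre-water baseline.
The emptying rate is the OLS slope of GCV over 41–81 min (after the
co-ingested water has emptied), sign-flipped so positive = emptying; the
caloric rate anchors the baseline volume at 300 kcal and takes the same
windowed slope, which equals the volumetric rate × 300 / GCV(−5 min)
exactly.

## Worked example

```python
from gastromri import (PeristalsisTruth, RasterSpec, SliceGeometry,
                       simulate_area_series, band_spectrum, dominant_frequency,
                       occlusion_series, apparent_speed)

truth = PeristalsisTruth(f0_cpm=3.0, mean_area_mm2=600.0, amp_mm2=120.0)
curve = simulate_area_series(truth, RasterSpec())

result = dominant_frequency(band_spectrum(curve))
occ = occlusion_series(curve)
geom = SliceGeometry(slice_thickness_mm=5.0, distance_factor=2.5)

print(f"frequency: {result.peak_freq_cpm:.2f} cpm "
      f"(dominance factor {result.dominance_factor:.1f}, valid={result.valid})")
print(f"mean occlusion: {occ.mean_occlusion_pct:.1f} % "
      f"(reference area {occ.reference_area_mm2:.0f} mm^2)")
print(f"apparent speed: {apparent_speed(result.peak_freq_cpm, geom):.2f} mm/s")
```

prints

```
frequency: 3.00 cpm (dominance factor 6.7, valid=True)
mean occlusion: 16.5 % (reference area 718 mm^2)
apparent speed: 2.00 mm/s
```

A noiseless 3 cpm phantom slice is recovered at the 3 cpm bin with a
dominance factor of 6.7 (7 bins lie in the band, one carries the
signal), its sinusoidal area swing of ±20% produces 16.5% mean
occlusion against the top-decile reference of 718 mm², and at the
reference geometry (5 mm slices, 12.5 mm gaps, D = 40 mm) 3 cpm
corresponds to a 2 mm/s apparent wave speed — the canonical healthy
fed-state values.

Full cohorts run from the shell:

```bash
gastromri simulate --out bundle/ --seed 1          # 144 volumetric + 360 dynamic records
gastromri analyze  --bundle bundle/ --out results/
gastromri summarize --results results/             # cohort mean ± SD tables
gastromri report    --results results/             # inclusion counts, recovery vs truth
```

## Layout

- `gastromri.phantom` — synthetic cohort generator (study design, raster,
  peristalsis/emptying ground truth, NIfTI rasterization)
- `gastromri.extraction` — masks → areas/volumes, NIfTI + CSV IO
- `gastromri.motility` — band spectrum, dominance rule, speed, occlusion
- `gastromri.volumetry` — ΔGCV, windowed volumetric and caloric rates
- `gastromri.summary` — cohort mean ± SD tables, inclusion counts,
  correction-rate bookkeeping, ground-truth recovery reports
- `gastromri.config` / `gastromri.pipeline` / `gastromri.cli` — run
  configuration, end-to-end orchestration, command-line entry points

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
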