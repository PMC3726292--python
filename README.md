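# filodetect

Automated detection, counting and length measurement of **filopodia** —
the thin (≲ 0.4 µm) finger-like actin protrusions at the edge of a cell
— in single-cell fluorescence confocal microscopy images.

Filopodia number and length are read-outs for cell motility and are
elevated in many invasive cancers, but they are usually quantified by
hand: slow, tedious, and not entirely objective. `filodetect` replaces
the manual count with a deterministic morphological pipeline, and ships
a seeded synthetic-image generator plus evaluation metrics so the whole
system can be validated without proprietary microscopy data. It is
aimed at cell biologists quantifying protrusion phenotypes and at image
analysts who need a reproducible, scriptable baseline.

## Method

Given a calibrated grayscale image (µm/pixel supplied by the user), the
pipeline runs three steps:

1. **Cell segmentation.** A global threshold is computed from the
   256-bin intensity histogram by a *modified triangle method*: draw the
   chord from the histogram peak *b* to the last non-zero level *a* on
   the longer tail, take the level maximising the perpendicular distance
   between histogram and chord, then move to the lowest-count level
   within the 10 gray levels to its right. The valley search discards
   background pixels whose intensities crowd against the dim foreground
   — the typical failure of Otsu-style thresholds on these images.
   Pixels strictly above the threshold are foreground; the largest
   8-connected object is kept as the cell body and its holes are filled.

2. **Filopodia extraction.** A morphological opening with a disk of
   radius 0.5 µm strips thin protrusions off the cell body; fragments
   whose moment-ellipse major axis is less than 1.5× the minor axis are
   discarded, and the mean minor-axis length *L* of the remaining
   filament-like fragments gives a cell-specific width estimate. A
   second opening with a disk of radius *L* pixels produces the final
   candidate set, filtered to remove objects shorter than 0.4 µm.

3. **Classification and measurement.** Each candidate is thinned to a
   one-pixel skeleton. Its length is the skeleton pixel count × pixel
   size. If the skeleton has more than one branch point and at least
   four endpoints the object is a *combined* group (filopodia fused at
   the base or crossing in projection) and is counted as one object,
   its length being the total length of the group.

Accuracy against annotations is summarised by the mean absolute count
error, MAE = (1/N) Σᵢ |Mᵢ − Fᵢ| / Mᵢ (a percentage over N cells, Mᵢ
manual and Fᵢ automated counts), together with the Pearson correlation
and best-fit slope of automated on manual values.

## Worked example

```python
from filodetect import SyntheticSpec, generate_cell_image, detect_filopodia
from filodetect.metrics import score_against_truth

spec = SyntheticSpec(n_filopodia=24, n_crossing_pairs=2, seed=42)
image, truth = generate_cell_image(spec)
result = detect_filopodia(image)
print(f"objects detected : {result.n_total} "
      f"({result.n_single} single, {result.n_combined} combined)")
print(f"threshold level  : {result.threshold_level}")
print(f"mean length (um) : {result.mean_length_um:.2f}")
m = score_against_truth(truth, result, match_radius_um=1.0, pixel_size_um=0.1)
print(f"matched to truth : {m.n_matched}/{truth.n_filopodia} "
      f"(missed {m.n_missed}, spurious {m.n_spurious})")
```

prints

```
objects detected : 22 (20 single, 2 combined)
threshold level  : 57
mean length (um) : 2.74
matched to truth : 20/24 (missed 4, spurious 2)
```

The generator drew 24 filaments of which 2 pairs cross outside the cell
body; each crossing pair merges into one *combined* object, so 22
countable objects is the correct answer and both pairs are flagged. The
one-to-one base matching pairs each merged detection with one of its
two true members, which is why 4 members appear "missed" and the 2
merged objects "spurious" in the strict per-filament bookkeeping.

The same pipeline is available from the shell:

```sh
filodetect simulate --out cell.tif --truth truth.json --n 20 --seed 1
filodetect run cell.tif --pixel-size 0.1 --out results.csv --overlay overlay.png
filodetect batch images/ --pixel-size 0.1 --out-dir results/
filodetect evaluate --manual manual.csv --auto auto.csv
```

`run` writes a per-filopodium CSV (id, length, single/combined, skeleton
features, centroid) with a JSON summary sidecar, and an optional RGB
overlay with single filopodia in red and combined groups in yellow.

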