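# Methods

This note documents the detection model, its parameters, the synthetic
validation data, and the numerical and design choices behind
`filodetect`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Detection model

The detector assumes a single fluorescently labelled cell (e.g.
phalloidin-stained F-actin) imaged as a bright body on a dark
background, with filopodia appearing as thin, mostly straight,
unbranched protrusions of roughly ≤ 0.4 µm width. All geometric
parameters are expressed in microns and converted to pixels through the
user-supplied calibration; the method itself never inspects image
metadata beyond a consistency warning for TIFF resolution tags.

### Thresholding

Histograms are always 256 bins; 16-bit images are rebinned by integer
division (levels map back to native depth at the bin midpoint). The
triangle threshold draws the chord from the histogram peak to the last
non-zero level of the *longer tail* — the side of the peak whose
non-zero support spans more gray levels, which for these images is the
bright side — and picks the level with maximum perpendicular distance
between the (level, count) curve and the chord. Counts are normalised
by the peak count and levels by the chord span before the distance
computation; without this the "perpendicular distance" depends on the
units of the two axes. The modified variant then takes the argmin of
the counts over the closed window of 10 levels to the right of the
triangle point. We use an argmin rather than a strict local-minimum
test because a strict local minimum need not exist in the window; the
argmin realises the same intent (slide the threshold into the valley
between background and dim foreground) and degrades gracefully to the
triangle point when counts rise monotonically. Ties everywhere break
toward the lower gray level, with one deliberate exception: the Otsu
baseline returns the centre of the maximal between-class-variance
plateau, because with well-separated modes the variance is exactly flat
across the zero-count gap and any plateau level is an equally valid
maximiser (the centre is the conventional report).

The foreground test is strict (`intensity > level`). Baseline
thresholds (Otsu, mean, IsoData, maximum entropy) are provided for
comparison only; the pipeline default is the modified triangle method.

### Segmentation

Foreground objects are 8-connected; the largest is kept as the cell
body (ties broken by raster order of the first pixel, components
touching the border are eligible). Hole filling flood-fills the
4-connected background from the image border and turns everything
unreached ON — the 8/4 foreground/background pairing avoids the usual
topological paradox. The output contract, asserted on every run, is a
single 8-connected, hole-free mask.

### Filopodia extraction and measurement

The first opening uses a disk of radius 0.5 µm (default
`opening_radius_um`), chosen above the ~0.4 µm filopodium width so the
erosion removes them entirely and the dilation restores only the body.
Candidate fragments are the connected components of `cell AND NOT
opened`. Fragment shape is summarised by the moment-equivalent ellipse;
axes derive from the eigenvalues of the pixel-coordinate covariance
with a 1/12 per-axis variance term (each pixel treated as a unit
square), so a one-pixel-wide line has a finite minor axis near 1 px and
a single pixel fits a unit circle. Fragments with major < 1.5× minor
axis (default `axis_ratio_min`) are discarded as too thick; the mean
minor axis *L* of the survivors estimates the cell's filopodium width.
If nothing survives the elongation filter, *L* falls back to the
first-pass radius in pixels, with a warning. The second opening is
applied to the segmented cell mask with a disk of radius *L* pixels
(bounded below by 1 px); we read "opening the original image again" as
operating on the segmented binary cell, since the opening used here is
defined on binary masks and the whole of step 2 operates downstream of
segmentation. The elongation filter applies only to the first pass
(whose sole purpose is estimating *L*); the minimum-length filter only
to the second.

Skeletons come from topology-preserving thinning (Zhang's algorithm as
implemented in scikit-image) run on the fragment's bounding-box crop.
Length is the skeleton pixel count times the pixel size — a pure count,
not a Euclidean path length, so diagonal runs are *not* weighted by √2.
Endpoints are skeleton pixels with exactly one 8-neighbour, branch
points those with three or more; an isolated pixel is one endpoint. A
fragment with more than one branch point **and** at least four
endpoints is a combined group. The rule is applied literally: a perfect
X-crossing that thins to a single 4-valent pixel has one branch point
and is therefore *not* combined. Records shorter than 0.4 µm (default
`min_length_um`) are dropped — human annotators cannot agree on whether
such small objects are filopodia.

### Parameters

| parameter | default | unit | role |
| --- | --- | --- | --- |
| `opening_radius_um` | 0.5 | µm | first-pass disk radius; must exceed half the filopodium width |
| `min_length_um` | 0.4 | µm | shortest reported filopodium (skeleton-count length) |
| `axis_ratio_min` | 1.5 | – | elongation cut for width estimation |
| `local_min_window` | 10 | gray levels | valley search window right of the triangle point |
| `threshold_method` | modified_triangle | – | global threshold selector |

## Synthetic data

The generator renders one cell per image: a disk of radius 10 µm with a
low-frequency radial perturbation (harmonics 2–5, amplitudes 0.5–2%),
and straight filaments of width 0.3 µm and length 1–5 µm rooted on the
boundary at evenly spaced angles with small jitter, pointing outward.
Filaments are drawn as distance-to-segment coverage maps with a
sub-pixel (0.7 px) soft edge so sub-pixel widths are controllable;
intensities are background 30 / foreground 200 on an 8-bit scale with
Gaussian fluctuation (σ = 6) and are fully reproducible from the seed.
The defaults (0.1 µm/px sampling, 10–64 filopodia per cell in the
validation batches) mirror the imaging regime of 100× oil-immersion
confocal data of fibroblast-like cells. Exact per-filament lengths can
be pinned with `fixed_lengths_um` for probe experiments.

Crossing pairs are engineered, not random: members start 14 px apart on
the boundary, tilt 0.42 rad toward each other, and extend at least
20 px past their computed ray intersection. These constants guarantee
(validated over seeded batches in the test suite) that the rendered
masks merge outside the body and thin to a skeleton with ≥ 2 branch
points and ≥ 4 endpoints, which is what the combined classifier keys
on. Shorter overhangs let thinning absorb a free tip; much shallower
crossings let the two strands fuse into one.

Two corruptions model acquisition noise: per-pixel Poisson resampling
(photon shot noise, mean = the clean intensity) and salt-&-pepper
corruption at a given density (dead/saturated pixels). The generator
does **not** simulate a microscope PSF, depth-dependent blur, uneven
illumination, curved or branching filopodia, or internal cytoskeletal
texture (stress fibres) — so passing the synthetic validation shows the
morphological logic is correct under the stated geometry, not that the
detector handles every real-image pathology.

## Validation design and problem sizes

The validation batches were sized to run on one CPU in well under a
minute each: 1000 random histograms for the brute-force triangle check,
100 accepted bimodal mixtures for valley recovery, 200 images (a third
Poisson-corrupted, a third salt-&-pepper) for the segmentation
contract, 50 noise-free cells spanning 10–64 filopodia for count and
length recovery, 20-image batches for the probe, crossing and noise
experiments. Length accuracy is scored on detections matched one-to-one
to ground truth by base position (greedy by distance within 1 µm, ties
by length difference).

## Known limitations

* **Length resolution at the 0.4 µm cut.** Detected length is the
  skeleton pixel count of the second-pass residue. For a protrusion of
  generated length *l* this count scatters about ±1.5 px around
  *l*/pixel-size: the global threshold sits near the background, so the
  rendered stub spills ~0.5 px outward; thinning erodes roughly half a
  width at each end; diagonal runs undercount under pixel-count
  semantics; and the opening leaves a small fillet where the protrusion
  roots into the body. Filaments generated 1–2 px from the 4-px
  minimum-length cut (0.3 µm and 0.6 µm at 0.1 µm/px) therefore do not
  separate cleanly: some 0.3 µm probes are reported and some 0.6 µm
  probes are dropped, and this persists with the Gaussian texture
  disabled, so it is a geometric quantisation limit rather than a noise
  effect. The corresponding probe experiment is reported as measured
  (and the matching acceptance test fails by design rather than being
  weakened); the detector's own output contract — every *reported*
  length ≥ 0.4 µm — always holds. For filaments ≥ 1 µm the same ±1.5 px
  scatter is the ~12% mean relative length error the recovery batch
  measures, consistent with the known base-point ambiguity of
  morphological length estimates.
* **Combined groups are not untangled**: a crossing pair is one object
  with the summed length, matching the manual annotation convention the
  detector emulates.
* Single-cell images only; multi-cell fields, 3-D stacks and live-cell
  sequences are out of scope.
* The triangle geometry assumes a dominant background peak with a
  longer bright tail; images without that histogram shape (e.g. mostly
  foreground) would need a different threshold method, which the
  `threshold_method` parameter exposes.
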