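# Methods

## Problem and model

Facial vitiligo burden is quantified from Wood's-light photographs.  Under
long-wave UV-A illumination the metabolites produced by melanocyte breakdown
fluoresce, so depigmented patches appear bright bluish-white against dark,
weakly fluorescent pigmented skin.  The measurement model is deliberately
simple and auditable: an operator delimits the face and roughly circles
candidate patches; the algorithm refines those regions to pixels and reduces
them to a single number per patient and timepoint, the Face Vitiligo Index

    FVI = (1/n) Σᵢ p_v,i / p_f,i ,

the mean over the available views i of the vitiligo-pixel count divided by
the face-pixel count.  Normalising per view by face area makes the index
invariant to image size, resolution and face dimensions; averaging over
views summarises patches in different facial regions.  The canonical
acquisition has n = 3 views (frontal, left, right); with fewer views the
divisor is the number supplied — imputing zeros for a missing view would
understate disease, and refusing would discard usable data.  Reports flag
n < 3.

Treatment response is the percent decline 100·(before − after)/before,
applied uniformly to FVI, F-VASI and questionnaire scores so that positive
numbers always mean improvement.  Percent changes are rounded to one decimal
for reporting; cohort summaries average the rounded per-patient percentages
(the convention that reproduces printed clinical summaries exactly) and are
rounded to one decimal again.

## Pipeline stages and their defaults

**Channel combination.**  The catalogue contains `red`, `green`, `blue`,
`luminance` (0.299 R + 0.587 G + 0.114 B), `blue_minus_red` and
`blue_over_sum` (B/(R+G+B+1)).  Under Wood's light the fluorescence signal
is blue-dominant, so `blue` is the default.  The combined image is min-max
rescaled to [0, 1] per image (not per ROI) so that thresholds are
comparable across images of the same session; a constant image maps to all
zeros (no contrast carries no patch evidence).

**CLAHE.**  Contrast-limited adaptive histogram equalisation is implemented
in-package: the image is divided into a tile grid (default 8×8), each
tile's 256-bin histogram is clipped at a normalised contrast limit (default
0.01 — the fraction of the tile's pixel count, beyond the uniform level,
that a bin may keep; clipped mass is redistributed uniformly) and converted
to its CDF; per-pixel outputs bilinearly interpolate the mappings of the
four surrounding tiles.  The mapping is the raw empirical CDF — a grey level
maps to the fraction of tile pixels at or below it — so with a single tile
and the clip limit at 1 the transform reduces exactly to global histogram
equalisation, which the test suite checks against an independently coded
oracle.  Images whose dimensions are not divisible by the tile grid are
reflect-padded and cropped back.

A note on what CLAHE does and does not buy: for a *faint* patch, tile-local
equalisation spreads the patch and skin modes far apart (their output gap is
the local pixel mass between them), and it also flattens smooth illumination
gradients; this is the regime the enhancer targets and the regime in which
the test suite asserts a contrast gain over the raw blue channel.  For an
already well-separated bimodal image, any equalisation *compresses* the
inter-mode distance for the same reason, while leaving the modes trivially
separable — Otsu thresholding downstream is unaffected, as the recovery
tests show.

**Binarisation.**  Within each patch ROI, a pixel is vitiligo iff its
enhanced intensity strictly exceeds the threshold (strictness makes
threshold 1 the safe, empty case).  Threshold precedence per ROI: a manual
per-ROI override, else the global threshold if one was given, else Otsu's
method computed over the ROI's own intensities with an explicit 256-bin
histogram spanning the ROI's range (the explicit histogram pins the binning
convention and makes the statistic reproducible).  A constant ROI raises an
error instructing a manual override rather than guessing.  The view mask is
the union of per-ROI masks intersected with the rasterised face outline, so
the FVI numerator can never exceed its denominator; per-ROI pixel counts are
reported as-is and may double-count overlapping ROIs.

**Rasterisation.**  Polygons live in continuous pixel coordinates with the
origin at the top-left corner; a pixel (x, y) is inside iff its centre
(x+0.5, y+0.5) is inside the closed polygon under the even-odd rule,
implemented as a vectorised ray cast.  This rule is reproducible and
orientation-independent; an axis-aligned w×h rectangle with integer corners
rasterises to exactly w·h pixels.  Degenerate (zero-area) polygons rasterise
to an empty mask with a warning.

**F-VASI and questionnaires.**  F-VASI is a clinician estimate: the package
records the fingertip-unit count and applies the 0.1 %-BSA-per-unit
conversion; it does not attempt to derive F-VASI from images.  vDLQI is the
10-item DLQI (0–3 each) plus four vitiligo items on the same scale, summed
(range 0–42); VitiQoL is 15 items on a 0–6 scale, summed (range 0–90) — the
15 × 6 structure is forced by the instrument's printed maximum.  "Not
relevant" DLQI answers are entered as 0, the instrument's standard rule.
Item texts are not bundled (the DLQI is copyrighted); responses are integer
vectors.

## Synthetic patients

The generator emulates the features of Wood's-light photographs that the
pipeline actually exploits, with defaults chosen as a plausible clinical
middle ground: 256×256 images, three views, 15 % coverage per view, 3
patches, patch/skin contrast 0.5 (on [0, 1]), Gaussian pixel noise with
sd 0.02, optional linear illumination gradient (off by default).

* Face: a filled ellipse (frontal) or half-ellipse (side views), polygonal
  outline with semi-axes 0.38 w × 0.44 h; background skin RGB ≈ (20, 20, 60),
  non-face surround darker.
* Patches: unions of randomly walked discs seeded inside the face — blob-like
  macroscopic morphology, not pixel noise.  The union's signed Euclidean
  distance transform is thresholded to hit the requested coverage to within
  a pixel shell (selection among distance ties is by row-major order), which
  is why realised coverage tracks the request almost exactly.
* Appearance: patches add contrast×255 to the blue and green channels
  (bluish-white fluorescence); noise is added after the optional gradient
  and the result clipped to 8 bits.
* Annotations: each connected patch gets the convex hull of its pixels
  dilated by 5 px — deliberately rough and over-covering, so segmentation,
  not annotation, does the pixel-level work.
* Longitudinal pairs: the follow-up reuses the baseline geometry with every
  patch uniformly eroded (again via the distance transform) until total
  coverage is (1 − repigmentation fraction) × baseline; the operator
  re-circles the patches still visible, so a fully repigmented patch has no
  follow-up ROI.
* Reproducibility: all randomness derives from the spec's integer seed via
  per-view seed sequences; identical specs give bit-identical images, masks
  and annotations.

What the generator does **not** emulate: facial anatomy (eyes, lips, hair),
perifollicular repigmentation patterns, specular reflections, camera
vignetting beyond a linear ramp, or motion blur.  Passing recovery tests
therefore demonstrates the correctness of the algorithmic chain under the
stated appearance model, not segmentation performance on clinical
photographs, which remains operator-audited through the ROI/threshold
controls.

## Verification

* Rasterisation and binarisation are checked pixel-for-pixel against
  independent brute-force implementations (and shapely for point-in-polygon)
  on random instances up to 64×64.
* CLAHE with one tile and clipping disabled must match an independently
  coded global histogram equalisation exactly.
* Otsu thresholds must attain the maximum between-class variance found by a
  brute-force scan over the same 256-bin histogram (cuts through empty
  valley bins tie; the attained variance, not the cut position, is
  compared).
* End-to-end, across 20 seeds and requested coverages {0.05, 0.15, 0.3}
  (contrast 0.5, noise 0.02, 192×192, three views), automatic segmentation
  achieves Dice ≥ 0.90 per view against ground truth and recovers the FVI
  within ±10 % relative; observed performance is far inside both bounds
  (Dice ≈ 0.999, relative error < 1 %).
* Longitudinal pairs generated with repigmentation fraction 0.789 yield a
  pipeline FVI percent change within 78.9 ± 5.
* The arithmetically self-consistent printed percent changes of the three
  documented clinical courses (FVI 55.95→11.83 = 78.9 %, F-VASI 5.1→1.3 =
  74.5 % and 4.4→0.2 = 95.5 %, the six questionnaire reductions, and the
  cohort means 57.6 %/68.4 %) are reproduced exactly from their printed
  inputs.  Printed figures that contradict the percent-decline formula
  applied to their own printed before/after values are not reproduced and
  are excluded from the reported surface.

Simulation sizes in the test suite and acceptance script (192×192 images,
10–20 seeds per condition) are the package's own choice: large enough that
per-view pixel counts are in the thousands and recovery margins are stable,
small enough to keep the whole suite interactive.

## Numerical choices and edge cases

* Thresholds always refer to the [0, 1]-rescaled enhanced image, so stored
  thresholds are transferable across images.
* FVI view averaging uses exact summation (`math.fsum`), making the index
  bit-identical under view reordering.
* 16-bit inputs are reduced to 8 bits by integer division by 257, mapping
  the range endpoints to endpoints; grayscale inputs are replicated to three
  channels; alpha is dropped.
* Annotation JSON round-trips vertices bit-exactly (plain decimal floats).
* Empty face masks, duplicate view labels, mismatched view labels,
  out-of-range thresholds and malformed questionnaire vectors all raise
  typed errors that map to distinct CLI exit codes (2 validation, 3 I/O,
  4 configuration).

## Known limitations

* The face outline is taken as drawn; whether eyes, lips or hair are
  excluded is the annotator's responsibility, and the index's denominator
  inherits that choice.
* Otsu replaces the interactive threshold choice of a human operator; on
  ROIs that contain no real patch it will still split the noise
  distribution, so operators should drop or override ROIs that no longer
  contain visible patches (the synthetic follow-up annotations model
  exactly this behaviour).
* Per-ROI counts may double-count overlapping ROIs; only the union mask
  feeds the index.
* No morphological post-processing (hole filling, opening) is applied.
* Cohort summaries are descriptive means; no inferential statistics are
  attempted on three-patient cohorts.
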