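# Methods

## Localization model

The pipeline converts a 2D detection plus a depth frame into metric
camera-frame coordinates in three steps.

**Box center.** The detection rectangle is anchored at its upper-left
corner (x_a, y_a) with extent (w, h); the sampling point is the exact
center (x_a + w/2, y_a + h/2). Fractional centers from odd extents are
kept as-is for the metric conversion and rounded to the nearest pixel
(ties away from zero) only when indexing the depth grid.

**Robust depth.** A single depth pixel is unreliable: strong lighting
makes individual measurements fail, which the camera encodes as values
at or below 1 mm. D_z is therefore the arithmetic mean of the values
strictly greater than 1 mm within the 3×3 neighborhood of the rounded
center. Neighborhood cells outside the frame are treated like dropout —
excluded from the mean rather than raising — because the validity filter
already exists for exactly that purpose. When no cell survives, the
result is an explicit localization failure carrying the pixel center,
not an exception and not a zero: downstream consumers (a harvester
controller) must distinguish "fruit at the origin" from "no range".

**Metric conversion.** The camera is modelled by its field of view
alone; at range D_z one pixel spans `tan(FOV/2)·D_z·2/resolution`
millimetres along each axis, so

    D_x = tan(H/2)·D_z·2/m·(x_b − x_1),  D_y = tan(V/2)·D_z·2/n·(y_b − y_1)

relative to a reference pixel (x_1, y_1) that defaults to the frame
center (m/2, n/2). The model assumes a flat (non-curvilinear) mapping
between pixel offset and lateral distance, ignores lens distortion, and
assumes the target is fronto-parallel enough that the 3×3 depth patch is
representative. Those assumptions hold to within 2% over the 300–800 mm
working band the device is validated in.

**Bias correction.** Against a laser rangefinder the depth camera reads
systematically long, by roughly +4 to +12 mm over the working band. A
constant 6 mm is subtracted to form ΔD_z, reported alongside the raw
value. The raw D_z — not ΔD_z — feeds the lateral conversion, because
the validated lateral offsets are reproduced from the raw range. The
bias is a `CameraModel` field, so a recalibrated device only needs a
config change.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| fov_h_deg / fov_v_deg | degrees | 64 / 41 | reference device (D435i-class) |
| width_px / height_px | px | 1920 / 1080 | reference device depth resolution |
| z_bias_mm | mm | 6 | midpoint of the observed +4…+12 mm systematic offset |
| invalid-depth threshold | mm | > 1 (strict) | camera encodes failures as 0/1 |
| checkerboard cell | mm | 21 | validation target geometry |
| working range | mm | 200–10000 | device specification |
| detection text dialect classes | — | 0=bag, 1=ripe, 2=ripening, 3=unripe | fixed here; the upstream convention is undefined |

Angles are stored in degrees and converted to radians once at
computation time. Pixel indexing is 0-based internally; reference-table
coordinates are used verbatim because only coordinate *differences*
enter the conversion, making the result basis-independent.

## Evaluation protocols

**Range accuracy.** Each measurement pairs a standard distance (laser
rangefinder) with the camera value. The signed difference is the
calculation error; the error rate is |difference| / reference × 100.
Corrected variants subtract the bias first. Summaries report the maximum
and mean rates over a reference band (the validated claim concerns the
300–800 mm band). Percentages are computed at full precision and
displayed to two decimals with round-half-away; tests compare at 0.01
percentage points because published reference values mix rounding and
truncation. The packaged indoor reference table contains one raw
error-rate cell that is inconsistent with its own difference and
reference distance (it repeats the previous row's value); consumers
should recompute rates from the raw readings, as the loader's docstring
notes.

**Detection metrics.** Box selection accuracy (BA) is the fraction of
annotated images in which the fruit was correctly framed, over all
records. Classification accuracy (CA) uses only the correctly boxed
records as its denominator — a misframed fruit has no class prediction
to score — which is the only denominator consistent with the published
arithmetic (324/335 = 96.71%, 20/21 = 95.24%). CA is reported as
undefined, not zero, when nothing was boxed. Box correctness is a binary
human judgment taken as input; no IoU matching is performed.

## Synthetic data

No public image database exists for this system, so all end-to-end
testing runs on generated scenes. The generators emulate the study
conditions:

* **Checkerboard targets** — a flat 21 mm-cell board at a fixed distance
  within the 200 mm–10 m working range, rendered over a constant depth
  plane. Intersection pixel positions are computed by the closed-form
  *inverse* projection, so they are an exact oracle for the forward
  conversion: any disagreement is a defect in one of the two paths, and
  the tests bound it at 0.05 mm after pixel quantization (a half-pixel
  footprint at ≤ 800 mm).
* **Depth noise** — dropout (pixels zeroed with a given probability,
  emulating failure under strong lighting), a constant positive bias
  (default matching the 6 mm systematic offset), and optional zero-mean
  Gaussian jitter. The real device's jitter magnitude is not published;
  the jitter default is synthetic, not measured.
* **Fruit mock-ups** — at most two elliptical fruit per frame (the
  acquisition constraint of the reference system), colored by class:
  dark green (unripe), uniform light green (ripe), a yellow-to-green
  gradient running bottom-to-top (ripening — yellowing proceeds
  upward), and a paper tone (bag), over a soil-brown background with
  slight seeded color noise. Fruit pixels carry the fruit range;
  the background is a farther constant plane (real scene depth
  composition is not documented; this is the simplest useful choice).

All generators are pure functions of (spec, seed). The mock-ups make no
attempt at photorealism: passing tests demonstrate that the geometry,
metrics, I/O and plumbing are correct, **not** that any detector would
perform comparably on real orchard imagery — real fruit texture,
occlusion, illumination and background complexity are all absent.

## Baseline detector

The production detector is a YOLO-style CNN whose training data are
private; its value is the weights, so it is represented here by an
interface (`DetectorConfig` metadata, the normalized text-dialect
loader) plus a deliberately simple stand-in: pixels vote for the nearest
class anchor color (background beyond a 60-unit RGB radius), connected
components above 200 px are kept, the two largest become detections with
tight boxes, majority-vote class and in-class pixel fraction as
confidence. The two-object cap mirrors the acquisition constraint. Its
regression bound (≥ 95% of ground-truth boxes recovered with ≤ 5 px
center error over 100 seeded scenes) was measured once on the synthetic
fixtures and frozen; it is a plumbing guarantee, not a field accuracy
claim. Detections produced at the 448×448 network input size are mapped
to the depth-frame resolution by independent linear x/y scale factors,
isolated in `rescale_box`.

## Numerical choices and degenerate inputs

* Invalid depth is *strictly* greater than 1 mm; exactly 1 mm is
  invalid.
* Zero-extent boxes are legal (the center is the corner); negative
  extents are rejected.
* A sampling point outside the frame is an input error; a neighborhood
  that merely overhangs the edge is not.
* Depth frames are nonnegative by construction; the 16-bit image codecs
  require integer values in [0, 65535] and refuse 8-bit sources rather
  than silently rescaling, while the CSV codec is lossless for floats.
* Robust depth on a constant integer-millimetre plane is exact for any
  dropout pattern with at least one survivor (IEEE division of k·a by k
  returns a); exactness is only claimed for integer depths, which is
  what depth cameras emit.

## Problem sizes

The default suite exercises: all 12 indoor protocol rows and 9 outdoor
pairs; 243 checkerboard intersections across three ranges; 10,000-point
dropout sampling on a 120×120 plane; 100 seeded fruit scenes at 448×448;
and 2,000-point projection round trips in the acceptance script. These
sizes keep the full suite under a minute while the bounds being checked
(1e−9 mm round trip, 0.05 mm oracle agreement, exact plane depth) leave
no room for undetected drift at larger n.

## Known limitations

* The FOV model has no lens-distortion terms; accuracy degrades toward
  frame corners on real optics.
* The 6 mm bias is a constant; the observed offset actually varies
  (+4…+12 mm) across the band, so corrected errors up to ~1.1% remain.
* Absolute detector accuracies and frame rates of the reference system
  are not reproducible without its private database and hardware; the
  property-based checks above are the substitute.
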