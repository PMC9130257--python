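# pineloc

RGB-D fruit maturity detection and metric 3D localization, built for
orchard harvesting automation (the reference crop is field-grown
pineapple). Given a 2D fruit detection — a bounding box with a maturity
class among *bag*, *ripe*, *ripening*, *unripe* — and a per-pixel depth
frame in millimetres, `pineloc` computes where the fruit sits in metric
camera coordinates, decides whether it is harvestable, and provides the
evaluation protocols used to validate both the geometry and the detector.

## The model

The camera is described only by its field of view (H = 64°, V = 41°),
pixel resolution (m × n = 1920 × 1080) and a constant range bias
(6 mm). For a detection box anchored at its upper-left corner
(x_a, y_a) with extent (w, h):

1. **Box center** — (x_b, y_b) = (x_a + w/2, y_a + h/2).
2. **Robust depth** — D_z is the mean of the values in the 3×3 pixel
   neighborhood of (x_b, y_b) that exceed 1 mm; values ≤ 1 mm are failed
   measurements (dropout under strong lighting). If none survive, the
   localization fails explicitly.
3. **Metric conversion** — relative to a reference pixel (x_1, y_1),
   normally the frame center (m/2, n/2):

       D_x = tan(H/2) · D_z · 2/m · (x_b − x_1)
       D_y = tan(V/2) · D_z · 2/n · (y_b − y_1)

   so D_x > 0 right of the reference and D_y > 0 below it. A corrected
   range ΔD_z = D_z − 6 mm accounts for the camera's systematic
   overestimate versus a laser rangefinder; the raw D_z drives the
   lateral conversion.

Ripe and ripening fruit are harvestable, unripe fruit is not, and bagged
fruit is indeterminate (the bag hides the maturity). The trained CNN
that produces detections in the field is not part of this package (its
training database is private); `pineloc` ships a color-blob baseline
detector for end-to-end testing and a loader for the normalized
`class cx cy w h [conf]` text dialect that external detectors emit.

## Worked example

```python
from pineloc import BoundingBox, CameraModel, DepthFrame, localize

cam = CameraModel()                            # 64°/41°, 1920x1080, 6 mm bias
frame = DepthFrame.constant(1920, 1080, 255)   # flat target at 255 mm
result = localize(BoundingBox(1200, 150, 196, 102), frame, cam)
p = result.point
print(f"dx={p.dx:.2f} mm dy={p.dy:.2f} mm dz={p.dz:.0f} mm (corrected {p.dz_corrected:.0f})")
```

prints

```
dx=56.10 mm dy=-59.85 mm dz=255 mm (corrected 249)
```

the box center (1298, 201) lies 338 px right of and 339 px above the
frame center, which at 255 mm range is 56.10 mm right and 59.85 mm up
(negative D_y) of the optical axis.

The same operations are available from a shell:

```sh
pineloc simulate checkerboard --seed 1 --out scene/
pineloc localize --depth scene/depth.png --box 1278,181,40,40
pineloc evaluate-range --input ranges.csv --bias 6 --band 300:800
pineloc detect-and-localize --image scene/image.png --depth scene/depth.png
```

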