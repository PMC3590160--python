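# uavweed

Tools for planning and analysing low-altitude UAV surveys aimed at
**early-season weed mapping in row crops** — the stage at which
site-specific weed management pays off, and at which weeds and crop
seedlings are only centimetres across, so that flight altitude, camera
optics, band registration and spectral separability together decide
whether a weed map is even possible.

The package has four parts, usable as a library or through the `uavweed`
command-line tool:

* **Mission geometry** (`uavweed.mission`) — pinhole-camera survey
  planning. For a camera with focal length *f*, sensor width *s<sub>w</sub>*
  and *n<sub>x</sub>* pixels flown at altitude *h*:
  GSD = *h*·(*s<sub>w</sub>*/*n<sub>x</sub>*)/*f*, footprint = *h*·*s*/*f*
  per axis. Waypoint grids for a rectangular field follow from the
  forward/side overlaps with a ceiling convention per axis, serpentine
  ordering, plus an image-density and flight-duration estimate.
* **Band alignment** (`uavweed.alignment`) — registration of the six
  channels of a multi-lens multispectral camera onto the master channel:
  per-band affine (translation, rotation, scale) plus a
  distance-dependent parallax term *b·f*/(*p·d*) for lens baseline *b*,
  pixel pitch *p* and subject distance *d*; model estimation from imagery;
  quality scoring with 45-sample spatial profiles across a reference edge.
* **Spectral separability** (`uavweed.separability`) — reflectance
  calibration against a bright reference panel; the NDVI, NGRDI and ExG
  vegetation indices; class sampling from ROIs; one-way ANOVA with
  Fisher's protected LSD test; and the histogram-separability statistic
  **M = (μ₁ − μ₂)/(σ₁ + σ₂)** (M > 1 ⇒ moderate separability).
* **Synthetic fields** (`uavweed.synthetic`) — a generator for
  ground-truthed test scenes: crop rows 0.7 m apart at a configurable
  direction angle, weed patches between rows, bare-soil background, white
  sampling frames and a calibration panel, rendered as a six-band stack
  (450–780 nm) with controllable per-class band statistics and injectable
  band misalignment.

## Worked example

Plan a survey of a 100 × 100 m field with the six-band camera
(9.6 mm lens, 6.66 × 5.32 mm sensor, 1280 × 1024 px) at 60 % forward-lap
and 30 % side-lap:

```
$ uavweed plan-mission --altitude 30
camera            multispectral
altitude          30 m
gsd               1.63 cm/px
footprint         21 x 17 m (0.03 ha)
grid              9 lines x 13 images = 117 images
images/ha         117
est. duration     11.0 min

$ uavweed plan-mission --altitude 100
camera            multispectral
altitude          100 m
gsd               5.42 cm/px
footprint         69 x 55 m (0.38 ha)
grid              3 lines x 4 images = 12 images
images/ha         12
est. duration     1.8 min
```

At 30 m each pixel covers 1.63 cm of ground — fine enough to resolve
individual seedlings (≈4 px across a 6 cm plant) — but the field needs
117 images; at 100 m a dozen images suffice but a pixel covers 5.42 cm,
adequate only for weed *patch* detection. `altitude_for_gsd` inverts the
relation: a 1–4 cm pixel corresponds to altitudes of 19–74 m for this
camera.

The same API drives the image side:

```python
from uavweed import (SceneConfig, generate_scene, misalign_stack,
                     estimate_alignment_model, apply_alignment,
                     compute_index, sample_class_pixels, m_statistic)

scene = generate_scene(SceneConfig(field_size=(10, 10), gsd=5, n_frames=1,
                                   weed_patch_density=400, seed=0))
ndvi = compute_index(scene.stack, "NDVI")
veg = sample_class_pixels(ndvi, scene.masks["crop"] | scene.masks["weed"],
                          "vegetation")
soil = sample_class_pixels(ndvi, scene.masks["bare_soil"], "bare_soil")
print(round(m_statistic(veg, soil), 2))   # ≈ 10.7: easily separable
```

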