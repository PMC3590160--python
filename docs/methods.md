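# Methods

This note records the models implemented in `uavweed`, the defaults and
why they were chosen, and what the synthetic scenes do and do not
establish about real imagery.

## Mission geometry

All ground geometry follows the nadir pinhole model over flat terrain:
a sensor axis of physical size *s* (mm) behind a lens of focal length *f*
(mm) at altitude *h* (m) images *h·s/f* metres of ground, and one pixel
covers GSD = *h·p/f* with *p* the pixel pitch. The horizontal pitch
(`sensor_width / pixels_x`) is used throughout; for the supported cameras
the vertical pitch differs by under 0.2 %, and a camera whose pitches
differ by more than 10 % is rejected as mis-specified.

Waypoint grids use the constant-trigger-interval convention of waypoint
planning software: flight lines run along the field width, the camera
fires every (1 − forward-lap)·footprint-width metres along track, lines
are spaced (1 − side-lap)·footprint-height across track, and both counts
round **up** so that every part of the field falls in some image. Note
this is not the minimal covering — footprints may overhang the field —
but it is what constant-interval triggering produces, and for the
six-band camera it yields 117 images/ha at 30 m and 12 at 100 m over a
1 ha field, matching operational experience with such planners. Waypoints
sit at the centres of their coverage cells, serpentine-ordered, with the
first waypoint in the cell nearest the local-frame origin (a corner; the
choice of corner is arbitrary). The local frame's x-axis runs along the
mission direction angle, measured clockwise from north.

Display conventions: GSD to two decimals (cm); footprint to the nearest
metre; `altitude_for_gsd` rounds up to whole metres, since the next lower
metre would miss the requested resolution.

The flight-duration model is deliberately simple:
2·*h*/climb-rate + serpentine-path-length/cruise-speed + images·dwell,
with defaults of 15 m/s cruise, 7.5 m/s climb and 5 s dwell. Commercial
ground stations apply unpublished acceleration and turn profiles, so this
estimate is indicative; it is tested for its structural properties
(monotonicity, dwell arithmetic, limits), not against any vendor's
printed durations. The RGB still camera's nominal 14 mm focal length is
likewise inconsistent with the pixel sizes such rigs report in practice
(zoom lenses operate away from their nominal setting), so `CameraSpec`
accepts an `effective_focal_length` override; no RGB-specific numbers are
asserted anywhere.

## Band-to-band registration

A six-lens camera exposes each channel through its own lens, so channel
images are mutually translated, slightly rotated and scaled. The model is
a per-band similarity transform about the image centre plus a parallax
translation *b·f*/(*p·d*) px for lens baseline *b* (mm) and subject
distance *d* (m) — similar triangles; ~1.8 px at 30 m for a 30 mm
baseline and negligible (<0.02 px) beyond a few kilometres. The default
lens layout is a 2 × 3 grid at 33 mm spacing; no public geometry exists
for such rigs, so baselines are configurable and default to zero unless
requested.

Resampling is bilinear; samples falling outside the slave frame become
NaN rather than zero, because zero-filled margins would leak into any
statistic computed from the aligned stack. Warping preserves dimensions
and cannot leave the radiometric range.

Model estimation, when no stored calibration is available: translation by
cross-correlation with sub-pixel refinement (plain rather than
phase-normalised correlation — phase whitening is unreliable on smooth,
low-texture field imagery), then a Powell refinement of
(dx, dy, rotation, scale) minimising the masked mean-squared difference
against the master band after light Gaussian smoothing (σ = 1 px, which
suppresses the uncorrelated per-band sensor noise that otherwise
dominates the cost). The optimiser starts from identity rotation/scale:
multi-lens rigs are mechanically co-aligned to well within a degree, far
inside the convergence basin. A log-polar spectral-correlation seed is
available (`coarse_rotation=True`) for larger rotations, but on
field-like scenes it is *less* accurate than the identity start (its
rotation quantisation exceeds the sub-degree perturbations being
estimated), so it is off by default.

Residual alignment quality is scored the way practitioners inspect it:
spectral values sampled along a short probe line (45 samples by default)
crossing a single high-contrast edge such as a reference-panel border;
each band's sub-pixel edge position (steepest gradient, 3-point parabolic
refinement) is compared with the master's, and the score is the largest
absolute offset in pixels. A probe that crosses several edges of similar
contrast is ambiguous — choose the segment so it crosses one.

On synthetic scenes, random per-band perturbations of ±5 px, ±1°, ±1 %
scale are recovered to well under 0.5 px residual edge offset (typically
<0.05 px) in 100/100 seeded trials.

## Reflectance calibration and vegetation indices

Calibration is a one-point empirical line per band through the origin:
gain = panel-reflectance / mean(panel DN) over a panel mask of at least
30 pixels (default panel reflectance 0.99, a barium-sulphate standard).
This assumes a dark current of zero and sensor linearity; it makes the
calibrated stack invariant to global illumination rescaling.

Indices: NDVI = (NIR − R)/(NIR + R), NGRDI = (G − R)/(G + R),
ExG = 2g − r − b on chromatic coordinates, equal to
(2G − R − B)/(R + G + B). Bands are picked by nearest centre wavelength
(B 450, G 530, R 670, NIR 780 nm); with two red bands (670 and 700 nm)
the 670 nm band is used, the conventional red for these indices.
Zero-denominator pixels are NaN and excluded from all statistics. Indices
may be computed on raw DN or calibrated reflectance; raw DN is the
default (NDVI and NGRDI are gain-invariant band ratios, and negative
soil values of the kind reported from field campaigns indicate DN-based
computation).

## Separability statistics

Two complementary measures per class pair:

* **ANOVA + protected LSD.** One-way ANOVA, then Fisher's least
  significant difference on the pooled within-group mean square,
  *protected*: pairwise differences are only declared when the omnibus F
  is itself significant at α (default 0.01). Protection keeps the
  two-group false-positive rate at the nominal α — measured at 0.010
  over 2000 null simulations, within the [0.002, 0.025] calibration
  band. Results are summarised as a compact letter display
  (insert-and-absorb algorithm); groups sharing a letter are not
  significantly different.
* **M-statistic.** M = (μ₁ − μ₂)/(σ₁ + σ₂) with sample SDs (ddof 1).
  M > 1 indicates moderate histogram separability. Significance and
  separability deliberately disagree sometimes: large samples make tiny
  mean differences significant while overlapping histograms (small M)
  still make per-pixel classification unreliable.

Published class summaries of this kind are printed rounded; recomputing M
from rounded means/SDs does not reproduce an M computed from the
underlying pixel data (e.g. rounded vegetation/soil NDVI summaries
0.58 ± 0.07 vs −0.16 ± 0.01 give 9.25 where unrounded data gave 8.90).
The package therefore validates published M values *qualitatively* —
ordering across indices and the M > 1 threshold — and validates the
formula itself exactly on constructed samples.

## Synthetic scenes

`generate_scene` emulates an early-season sunflower field: bare soil,
crop rows 0.7 m apart at a 65° direction angle (plants as jittered discs,
0.14 m diameter, 0.25 m apart along the row), weed patches snapped to the
inter-row midline band (Poisson patch count at 40 patches/ha by default,
plants ≤ crop size), 49 white 1 × 1 m frames on a regular grid, and a
1 × 1 m bright panel at the field centre. Class masks are mutually
exclusive and exhaustive by construction (priority: panel > frame >
crop > weed > soil). Per-pixel digital numbers are independent Gaussians
per class and band, clipped to the 10-bit range.

The default class band statistics are back-solved analytically so the
raw-DN index means land on realistic early-season values — NDVI
0.61/0.55/−0.16 and NGRDI 0.24/0.05/−0.23 for crop/weed/soil, vegetation
(crop + weed pooled) NDVI ≈ 0.58 — the regime in which vegetation and
soil separate strongly (M ≈ 10 for NDVI) while crop and weed barely
separate (M < 1 for NDVI). Several band-level configurations are
consistent with the same index summaries; the chosen one keeps plausible
spectral shapes (vegetation: low red, high NIR; soil: rising to red,
moderate NIR on the DN scale).

What these scenes do **not** model: band-to-band spectral correlation,
texture, shadows, BRDF, mixed pixels at class boundaries beyond raster
quantisation, lens distortion and perspective (frames are
nearest-neighbour crops). Passing tests therefore demonstrate the
correctness of the *pipeline machinery* — geometry, registration,
sampling, statistics — not classification performance on real fields.

Default scene GSD is 1.63 cm (the 30 m case for the six-band camera),
giving a ≈6135² px full-field raster; tests and examples use 8–10 m
sub-scenes at 2–5 cm GSD (160²–500² px) so the whole suite runs in about
a minute.

## Statistical conventions in the tests

Parameter-recovery checks compare sampled class means against generator
truth. With 21 simultaneous comparisons (3 classes × 6 bands + 3 NDVI
means), a marginal 2-SE bound would fail somewhere ≈63 % of the time even
for a perfect generator, so recovery is asserted at the family-wise 95 %
level (Šidák-corrected, ≈3 SE per comparison). Stochastic tests use fixed
seeds chosen a priori; the Monte-Carlo sizes (100 alignment trials, 2000
null ANOVA simulations, 10⁵-sample convergence checks) are the package's
own precision/runtime trade-off.

## Known limitations

* Flat-terrain, nadir geometry only; no DEM, battery or turn modelling.
* One-point empirical-line calibration (no dark-offset term).
* The registration estimator assumes small rotations unless the
  log-polar seed is enabled; it needs shared spatial structure across
  bands and will not register featureless imagery.
* The LSD applies no multiple-testing correction beyond ANOVA protection,
  by design (it mirrors standard agronomic practice).
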