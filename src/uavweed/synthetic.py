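"""Synthetic early-season crop-field scenes with ground truth.

Generates the kind of imagery a low-altitude UAV survey of a row crop
produces a few weeks after sowing: a bare-soil background crossed by
parallel crop rows (small plants rendered as discs along each row), weed
patches scattered between the rows, a grid of white 1 x 1 m sampling
frames, and a bright reference panel at the field centre — rastered into a
six-band stack whose per-class, per-band digital numbers are drawn from
configurable Gaussians.  Every pixel carries a ground-truth class label, so
sampling, calibration and separability statistics can be validated against
the generating parameters, and controlled band misalignment can be injected
to exercise the registration pipeline.

The default per-class band statistics are back-solved so that the raw-DN
vegetation indices of the three covers land on realistic early-season
values (strongly positive NDVI for vegetation, negative for this soil,
crop and weed separated far less than vegetation and soil).  Bands are
independent Gaussians: real canopies have correlated bands and textured
surfaces, so these scenes test the *pipeline*, not radiative realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .alignment import BandAlignmentModel, DEFAULT_BAND_CENTERS, MultibandStack
from .mission import CameraSpec, MissionPlan

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "DEFAULT_CLASS_BAND_STATS",
    "generate_scene",
    "generate_class_samples",
    "misalign_stack",
    "render_frames",
    "row_centerline_offsets",
]

#: Per-class (mean, sd) digital numbers for the six bands
#: (450, 530, 670, 700, 740, 780 nm), 10-bit range.  Solved so the raw-DN
#: index means approximate an early-season sunflower field at 30 m:
#: NDVI ~ 0.61 / 0.55 / -0.16 and NGRDI ~ 0.24 / 0.05 / -0.23 for
#: crop / weed / soil.
DEFAULT_CLASS_BAND_STATS: dict[str, tuple[tuple[float, float], ...]] = {
    "bare_soil": ((44.6, 2.0), (75.1, 2.0), (120.0, 2.0), (110.0, 2.0),
                  (95.0, 2.0), (86.9, 2.0)),
    "crop": ((97.5, 8.0), (97.9, 8.0), (60.0, 8.0), (80.0, 8.0),
             (170.0, 12.0), (247.7, 15.0)),
    "weed": ((80.2, 8.0), (77.4, 8.0), (70.0, 8.0), (90.0, 8.0),
             (165.0, 12.0), (241.1, 15.0)),
    "panel": ((950.0, 4.0),) * 6,
    "frame": ((900.0, 6.0),) * 6,
}

_CLASS_ORDER = ("bare_soil", "crop", "weed", "panel", "frame")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic row-crop field.

    Distances in metres, the raster ground sampling distance ``gsd`` in cm.
    ``row_direction`` is the angle of the crop rows from the raster x-axis,
    in degrees.  ``class_band_stats`` maps each class to per-band
    (mean DN, sd DN) tuples.
    """

    field_size: tuple[float, float] = (100.0, 100.0)
    row_spacing: float = 0.7
    row_direction: float = 65.0
    crop_plant_diameter: float = 0.14
    crop_plant_spacing: float = 0.25
    weed_patch_density: float = 40.0     # patches per ha
    weed_plants_per_patch: int = 8
    weed_patch_radius: float = 0.5
    weed_plant_diameter: float = 0.12
    n_frames: int = 49
    frame_size: float = 1.0
    panel_size: float = 1.0
    gsd: float = 1.63
    class_band_stats: dict = dc_field(default_factory=lambda: dict(DEFAULT_CLASS_BAND_STATS))
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS
    bit_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.gsd <= 0:
            raise ValueError("row_spacing and gsd must be > 0")
        if self.weed_plant_diameter > self.crop_plant_diameter:
            raise ValueError("weed plants must not exceed crop plants in size")
        missing = [c for c in _CLASS_ORDER if c not in self.class_band_stats]
        if missing:
            raise ValueError(f"class_band_stats missing classes: {missing}")


@dataclass
class SyntheticScene:
    """A rendered field with mutually exclusive, exhaustive class masks."""

    stack: MultibandStack
    masks: dict[str, np.ndarray]
    truth: SceneConfig


def row_centerline_offsets(config: SceneConfig) -> np.ndarray:
    """Signed perpendicular offsets (m) of every row centreline crossing
    the field rectangle.

    A row is the line {p : p . n = offset} with n the unit normal to the
    row direction; offsets are integer multiples of the row spacing.
    """
    th = math.radians(config.row_direction)
    nx, ny = -math.sin(th), math.cos(th)
    fw, fh = config.field_size
    corners = [(0.0, 0.0), (fw, 0.0), (0.0, fh), (fw, fh)]
    proj = [x * nx + y * ny for x, y in corners]
    lo, hi = min(proj), max(proj)
    s = config.row_spacing
    k0 = math.ceil(round(lo / s, 9))
    k1 = math.floor(round(hi / s, 9))
    return np.arange(k0, k1 + 1) * s


def _stamp_discs(label: np.ndarray, centers: np.ndarray, radius_px: float,
                 value: int, free: np.ndarray) -> None:
    """Mark discs into the label map where ``free`` allows it."""
    h, w = label.shape
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (xx ** 2 + yy ** 2) <= radius_px ** 2
    for cx, cy in centers:
        ci, cj = int(round(cy)), int(round(cx))
        i0, i1 = max(ci - r, 0), min(ci + r + 1, h)
        j0, j1 = max(cj - r, 0), min(cj + r + 1, w)
        if i0 >= i1 or j0 >= j1:
            continue
        d = disc[i0 - (ci - r):i1 - (ci - r), j0 - (cj - r):j1 - (cj - r)]
        sub = label[i0:i1, j0:j1]
        ok = d & free[i0:i1, j0:j1]
        sub[ok] = value


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a synthetic field; deterministic for a given config seed."""
    rng = np.random.default_rng(config.seed)
    g = config.gsd / 100.0  # m per pixel
    fw, fh = config.field_size
    W, H = max(1, round(fw / g)), max(1, round(fh / g))
    label = np.zeros((H, W), dtype=np.uint8)  # 0 = bare_soil
    codes = {c: i for i, c in enumerate(_CLASS_ORDER)}

    th = math.radians(config.row_direction)
    u = np.array([math.cos(th), math.sin(th)])   # along-row unit vector
    n = np.array([-math.sin(th), math.cos(th)])  # row normal

    # crop plants: discs along each row centreline, jittered slightly
    half_diag = 0.5 * math.hypot(fw, fh)
    mid = np.array([fw / 2.0, fh / 2.0])
    crop_centers = []
    for off in row_centerline_offsets(config):
        base = off * n
        t_mid = float((mid - base) @ u)
        t = np.arange(t_mid - half_diag, t_mid + half_diag,
                      config.crop_plant_spacing)
        pts = base + np.outer(t + rng.uniform(-0.03, 0.03, t.size), u)
        pts += np.outer(rng.uniform(-0.01, 0.01, t.size), n)
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] < fw)
                & (pts[:, 1] >= 0) & (pts[:, 1] < fh))
        crop_centers.append(pts[keep])
    crop_centers = (np.concatenate(crop_centers) if crop_centers
                    else np.empty((0, 2)))

    # weed plants: clustered patches, snapped to the inter-row midline band
    area_ha = fw * fh / 1e4
    n_patches = rng.poisson(config.weed_patch_density * area_ha)
    weed_centers = []
    for _ in range(n_patches):
        cx, cy = rng.uniform(0, fw), rng.uniform(0, fh)
        offs = rng.normal(0.0, config.weed_patch_radius / 2.0,
                          size=(config.weed_plants_per_patch, 2))
        pts = np.array([cx, cy]) + offs
        s = pts @ n
        k = np.floor(s / config.row_spacing)
        s_mid = (k + 0.5) * config.row_spacing \
            + rng.uniform(-0.08, 0.08, s.size)
        pts = pts + np.outer(s_mid - s, n)
        keep = ((pts[:, 0] >= 0) & (pts[:, 0] < fw)
                & (pts[:, 1] >= 0) & (pts[:, 1] < fh))
        weed_centers.append(pts[keep])
    weed_centers = (np.concatenate(weed_centers) if weed_centers
                    else np.empty((0, 2)))

    free = np.ones((H, W), dtype=bool)
    _stamp_discs(label, crop_centers / g, config.crop_plant_diameter / 2.0 / g,
                 codes["crop"], free)
    free = label == 0
    _stamp_discs(label, weed_centers / g, config.weed_plant_diameter / 2.0 / g,
                 codes["weed"], free)

    # white sampling frames on a regular grid, panel at the field centre
    side = max(1, round(math.sqrt(config.n_frames)))
    rows_n = math.ceil(config.n_frames / side)
    placed = 0
    for i in range(rows_n):
        for j in range(side):
            if placed >= config.n_frames:
                break
            cx = (j + 0.5) * fw / side
            cy = (i + 0.5) * fh / rows_n
            _fill_square(label, cx / g, cy / g, config.frame_size / g,
                         codes["frame"])
            placed += 1
    _fill_square(label, (fw / 2.0) / g, (fh / 2.0) / g,
                 config.panel_size / g, codes["panel"])

    # per-class Gaussian digital numbers, clipped to the sensor range
    n_bands = len(config.band_centers)
    dn_max = 2 ** config.bit_depth - 1
    pixels = np.empty((H, W, n_bands), dtype=float)
    for cls, code in codes.items():
        m = label == code
        cnt = int(m.sum())
        if cnt == 0:
            continue
        stats_c = config.class_band_stats[cls]
        if len(stats_c) != n_bands:
            raise ValueError(f"class {cls!r} has {len(stats_c)} band stats, "
                             f"expected {n_bands}")
        for b, (mu, sd) in enumerate(stats_c):
            pixels[:, :, b][m] = np.clip(rng.normal(mu, sd, cnt), 0, dn_max)

    stack = MultibandStack(pixels=pixels, band_centers=config.band_centers,
                           bit_depth=config.bit_depth,
                           master_index=n_bands - 1)
    masks = {cls: label == code for cls, code in codes.items()}
    return SyntheticScene(stack=stack, masks=masks, truth=config)


def _fill_square(label: np.ndarray, cx: float, cy: float, side: float,
                 value: int) -> None:
    h, w = label.shape
    half = side / 2.0
    i0, i1 = max(int(round(cy - half)), 0), min(int(round(cy + half)), h)
    j0, j1 = max(int(round(cx - half)), 0), min(int(round(cx + half)), w)
    label[i0:i1, j0:j1] = value


def generate_class_samples(class_stats, n: int, seed: int,
                           bit_depth: int = 10) -> np.ndarray:
    """Draw n per-band DN samples for one class: an (n, B) array.

    Gaussian per band, clipped to the sensor range; reproducible by seed.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    dn_max = 2 ** bit_depth - 1
    out = np.empty((n, len(class_stats)))
    for b, (mu, sd) in enumerate(class_stats):
        if sd < 0:
            raise ValueError("sd must be >= 0")
        out[:, b] = np.clip(rng.normal(mu, sd, n), 0, dn_max)
    return out


def misalign_stack(stack: MultibandStack, model: BandAlignmentModel,
                   seed: int | None = None, noise_sd: float = 0.0,
                   distance: float | None = None) -> MultibandStack:
    """Apply the inverse of each band's calibration, so that
    ``apply_alignment(result, model, distance)`` restores the stack.

    Out-of-frame samples are filled by edge replication (the real camera
    sees past the master frame's edges); optional additive Gaussian sensor
    noise on top.
    """
    from skimage.transform import AffineTransform, warp

    out = np.empty(stack.pixels.shape, dtype=float)
    for i in range(stack.n_bands):
        band = stack.band(i).astype(float)
        if i == model.master_index:
            out[:, :, i] = band
            continue
        tform = model.band_transform(i, stack.shape, distance)
        inv = AffineTransform(matrix=np.linalg.inv(tform.params))
        out[:, :, i] = warp(band, inv, order=1, mode="edge",
                            preserve_range=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return MultibandStack(pixels=out, band_centers=stack.band_centers,
                          bit_depth=stack.bit_depth,
                          master_index=stack.master_index)


def render_frames(scene: SyntheticScene, camera: CameraSpec,
                  plan: MissionPlan) -> list[MultibandStack]:
    """Cut one sub-image per waypoint out of the scene raster.

    Nearest-neighbour crops at the footprint implied by the camera and the
    plan altitude, clipped to the scene extent; the plan's local frame is
    taken to coincide with the scene raster axes (nadir, flat terrain).
    """
    g = scene.truth.gsd / 100.0
    h_px, w_px = scene.stack.shape
    fp = plan.footprint
    fw_px = max(1, round(fp.width / g))
    fh_px = max(1, round(fp.height / g))
    frames = []
    for (x, y, _alt) in plan.waypoints:
        j0 = int(round(x / g - fw_px / 2.0))
        i0 = int(round(y / g - fh_px / 2.0))
        j0c, j1c = max(j0, 0), min(j0 + fw_px, w_px)
        i0c, i1c = max(i0, 0), min(i0 + fh_px, h_px)
        sub = scene.stack.pixels[i0c:i1c, j0c:j1c, :]
        frames.append(MultibandStack(pixels=sub.copy(),
                                     band_centers=scene.stack.band_centers,
                                     bit_depth=scene.stack.bit_depth,
                                     master_index=scene.stack.master_index))
    return frames
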