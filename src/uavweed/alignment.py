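"""Band-to-band registration for multi-lens multispectral frames.

A multi-lens camera exposes each spectral channel through its own lens onto
its own sensor, so the six raw channel images of one frame are mutually
shifted, slightly rotated and scaled.  Registration maps every slave channel
onto the master channel's pixel grid with a per-band affine (translation,
rotation about the image centre, isotropic scale) plus a distance-dependent
parallax term: lenses laterally separated by a baseline :math:`b` see a
subject at distance :math:`d` shifted by :math:`b f / (p d)` pixels (focal
length :math:`f`, pixel pitch :math:`p`), which vanishes at long range and
matters for low-altitude imagery.

Residual misalignment is scored with spatial profiles: band values sampled
along a short line crossing a high-contrast edge (a reference panel border),
where per-band sub-pixel edge positions expose any remaining offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp, warp_polar

__all__ = [
    "MultibandStack",
    "BandParams",
    "BandAlignmentModel",
    "ProfileReport",
    "parallax_offset_px",
    "apply_alignment",
    "estimate_translation",
    "estimate_band_transform",
    "estimate_alignment_model",
    "spatial_profile",
    "misalignment_score",
    "DEFAULT_BAND_CENTERS",
]

#: Centre wavelengths (nm) of the six-band camera: blue, green, two reds,
#: red edge, near infrared.
DEFAULT_BAND_CENTERS = (450.0, 530.0, 670.0, 700.0, 740.0, 780.0)

#: Default profile-line length in pixels.
PROFILE_LENGTH = 45


@dataclass
class MultibandStack:
    """B-band image with band wavelengths and radiometric depth.

    ``pixels`` is H x W x B, float or integer; NaN marks invalid pixels
    (out-of-frame samples after warping).
    """

    pixels: np.ndarray
    band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS
    bit_depth: int = 10
    master_index: int = 5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(f"pixels must be H x W x B, got shape {self.pixels.shape}")
        if self.pixels.shape[2] != len(self.band_centers):
            raise ValueError(
                f"{self.pixels.shape[2]} bands but {len(self.band_centers)} band centers"
            )
        if not 0 <= self.master_index < self.n_bands:
            raise ValueError(f"master_index {self.master_index} out of range")

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def dn_max(self) -> int:
        return 2 ** self.bit_depth - 1

    def band(self, i: int) -> np.ndarray:
        return self.pixels[:, :, i]

    def band_index(self, wavelength: float, tol: float = 60.0) -> int:
        """Index of the band whose centre is nearest ``wavelength`` (nm)."""
        centers = np.asarray(self.band_centers)
        i = int(np.argmin(np.abs(centers - wavelength)))
        if abs(centers[i] - wavelength) > tol:
            raise KeyError(f"no band within {tol} nm of {wavelength} nm")
        return i


@dataclass(frozen=True)
class BandParams:
    """Affine calibration of one slave band relative to the master.

    ``dx, dy`` in pixels (x = column, y = row), ``rotation`` in degrees,
    ``scale`` dimensionless, ``baseline`` the lateral lens offset from the
    master lens in mm as (bx, by) — it drives the distance-dependent
    parallax correction.
    """

    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0
    scale: float = 1.0
    baseline: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def _lens_grid_baselines(n_bands: int, master_index: int,
                         spacing: float = 33.0) -> list[tuple[float, float]]:
    """Lens-centre offsets (mm) for a 2 x 3 lens array, relative to master."""
    pos = [(spacing * (i % 3), spacing * (i // 3)) for i in range(n_bands)]
    mx, my = pos[master_index]
    return [(x - mx, y - my) for x, y in pos]


@dataclass
class BandAlignmentModel:
    """Per-band affine + parallax calibration for a multi-lens frame."""

    bands: tuple[BandParams, ...]
    master_index: int = 5
    focal_length: float = 9.6   # mm
    pixel_pitch: float = 0.0052  # mm

    def __post_init__(self) -> None:
        m = self.bands[self.master_index]
        if (m.dx, m.dy, m.rotation, m.scale) != (0.0, 0.0, 0.0, 1.0):
            raise ValueError("master band must have identity parameters")

    @classmethod
    def identity(cls, n_bands: int = 6, master_index: int = 5,
                 with_baselines: bool = False, **kw) -> "BandAlignmentModel":
        if with_baselines:
            baselines = _lens_grid_baselines(n_bands, master_index)
        else:
            baselines = [(0.0, 0.0)] * n_bands
        return cls(bands=tuple(BandParams(baseline=b) for b in baselines),
                   master_index=master_index, **kw)

    def band_transform(self, i: int, shape: tuple[int, int],
                       distance: float | None = None) -> AffineTransform:
        """Forward affine for band ``i``: master coords -> slave coords.

        Built so that ``warp(slave, tform)`` resamples the slave band onto
        the master grid.  Parallax (when ``distance`` is given) adds a pure
        translation proportional to baseline / distance.
        """
        p = self.bands[i]
        dx, dy = p.dx, p.dy
        if distance is not None:
            bx, by = p.baseline
            dx += parallax_offset_px(bx, self.focal_length, self.pixel_pitch, distance)
            dy += parallax_offset_px(by, self.focal_length, self.pixel_pitch, distance)
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        center = AffineTransform(translation=(cx, cy))
        core = AffineTransform(scale=p.scale, rotation=np.deg2rad(p.rotation),
                               translation=(dx, dy))
        # slave = C o core o C^-1 (master): rotate/scale about image centre,
        # then shift
        m = center.params @ core.params @ np.linalg.inv(center.params)
        return AffineTransform(matrix=m)


def parallax_offset_px(baseline: float, focal_length: float,
                       pixel_pitch: float, distance: float) -> float:
    """Parallax shift in pixels between two lenses separated by ``baseline``.

    offset = baseline * focal_length / (pixel_pitch * distance), with the
    baseline, focal length and pitch in mm and the subject distance in m.
    Inversely proportional to distance; signed with the baseline.
    """
    if focal_length <= 0 or pixel_pitch <= 0:
        raise ValueError("focal_length and pixel_pitch must be > 0")
    if distance <= 0:
        raise ValueError(f"distance must be > 0, got {distance}")
    return baseline * focal_length / (pixel_pitch * distance * 1000.0)


def apply_alignment(stack: MultibandStack, model: BandAlignmentModel,
                    distance: float | None = None) -> MultibandStack:
    """Resample every slave band onto the master grid.

    Bilinear interpolation; samples falling outside the slave frame become
    NaN rather than zero (zeros would bias any statistic computed from the
    aligned stack).  The master band and the stack dimensions are unchanged.
    """
    if len(model.bands) != stack.n_bands:
        raise ValueError(
            f"model has {len(model.bands)} bands, stack has {stack.n_bands}"
        )
    out = np.empty(stack.pixels.shape, dtype=float)
    for i in range(stack.n_bands):
        band = stack.band(i).astype(float)
        if i == model.master_index:
            out[:, :, i] = band
            continue
        tform = model.band_transform(i, stack.shape, distance)
        out[:, :, i] = warp(band, tform, order=1, mode="constant",
                            cval=np.nan, preserve_range=True)
    return replace(stack, pixels=out)


def estimate_translation(master: np.ndarray, slave: np.ndarray,
                         upsample: int = 100) -> tuple[float, float]:
    """Sub-pixel translation (dx, dy) of ``slave`` relative to ``master``.

    Returns the shift such that the slave's content sits at
    (x + dx, y + dy) where the master's sits at (x, y); equivalently the
    translation an alignment model needs to bring the slave back onto the
    master.  Cross-correlation with sub-pixel refinement; accuracy is a
    small fraction of a pixel on clean imagery.
    """
    master = np.asarray(master, dtype=float)
    slave = np.asarray(slave, dtype=float)
    if master.shape != slave.shape:
        raise ValueError("images must have equal dimensions")
    if np.ptp(master) == 0 or np.ptp(slave) == 0:
        raise ValueError("constant image: translation is undefined")
    # plain cross-correlation: phase whitening is brittle on smooth imagery
    shift, _, _ = phase_cross_correlation(master, slave,
                                          upsample_factor=upsample,
                                          normalization=None)
    # skimage returns the (row, col) displacement registering slave -> master
    return float(-shift[1]), float(-shift[0])


def _rotation_scale_logpolar(master: np.ndarray, slave: np.ndarray
                             ) -> tuple[float, float]:
    """Coarse rotation (deg) and scale of slave vs master via log-polar
    correlation of the FFT magnitude spectra (translation-invariant)."""
    h, w = master.shape
    radius = min(h, w) // 2
    win = np.outer(np.hanning(h), np.hanning(w))
    fm = np.abs(np.fft.fftshift(np.fft.fft2(master * win)))
    fs = np.abs(np.fft.fftshift(np.fft.fft2(slave * win)))
    pm = warp_polar(fm, radius=radius, scaling="log", output_shape=(360, radius))
    ps = warp_polar(fs, radius=radius, scaling="log", output_shape=(360, radius))
    # keep low-to-mid frequencies; the outer rings are noise-dominated
    pm, ps = pm[:, : radius // 2], ps[:, : radius // 2]
    shift, _, _ = phase_cross_correlation(pm, ps, upsample_factor=20,
                                          normalization=None)
    rot = -shift[0]  # degrees, 1 deg per polar row
    if rot > 90:
        rot -= 180
    elif rot < -90:
        rot += 180
    klog = radius / np.log(radius)
    scale = float(np.exp(shift[1] / klog))
    return float(rot), scale


def estimate_band_transform(master: np.ndarray, slave: np.ndarray,
                            refine: bool = True,
                            coarse_rotation: bool = False,
                            smooth: float = 1.0) -> BandParams:
    """Estimate (dx, dy, rotation, scale) mapping a slave band to the master.

    Initialisation: sub-pixel phase correlation for translation, identity
    rotation/scale — multi-lens rigs are mechanically co-aligned to within
    a degree or so, well inside the optimiser's convergence basin.  Set
    ``coarse_rotation`` to seed rotation/scale from log-polar spectral
    correlation when larger rotations are possible.  Refinement: Powell
    minimisation of the masked mean-squared intensity difference between
    the warped slave and the master, after light Gaussian smoothing
    (``smooth``, px) to suppress uncorrelated per-band sensor noise.
    """
    master = ndimage.gaussian_filter(np.asarray(master, dtype=float), smooth)
    slave = ndimage.gaussian_filter(np.asarray(slave, dtype=float), smooth)
    if coarse_rotation:
        rot, scale = _rotation_scale_logpolar(master, slave)
        trial = _warp_params(slave, 0.0, 0.0, rot, scale)
        trial = np.nan_to_num(trial, nan=float(np.nanmean(trial)))
        dx, dy = estimate_translation(master, trial)
    else:
        rot, scale = 0.0, 1.0
        dx, dy = estimate_translation(master, slave)
    if not refine:
        return BandParams(dx=dx, dy=dy, rotation=rot, scale=scale)

    big = float(np.mean(master ** 2)) * 1e6 + 1e6

    def cost(theta: np.ndarray) -> float:
        tdx, tdy, trot, tscale = theta
        if tscale <= 0.5:
            return big
        moved = _warp_params(slave, tdx, tdy, trot, tscale)
        valid = ~np.isnan(moved)
        if valid.sum() < moved.size // 4:
            return big
        d = moved[valid] - master[valid]
        return float(np.mean(d * d))

    res = optimize.minimize(cost, x0=[dx, dy, rot, scale], method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 100})
    dx, dy, rot, scale = res.x
    return BandParams(dx=float(dx), dy=float(dy), rotation=float(rot),
                      scale=float(scale))


def _warp_params(img: np.ndarray, dx: float, dy: float, rot: float,
                 scale: float) -> np.ndarray:
    h, w = img.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    center = AffineTransform(translation=(cx, cy))
    core = AffineTransform(scale=scale, rotation=np.deg2rad(rot),
                           translation=(dx, dy))
    m = center.params @ core.params @ np.linalg.inv(center.params)
    return warp(img.astype(float), AffineTransform(matrix=m), order=1,
                mode="constant", cval=np.nan, preserve_range=True)


def estimate_alignment_model(stack: MultibandStack,
                             refine: bool = True) -> BandAlignmentModel:
    """Estimate a full alignment model from a (misaligned) stack."""
    master = stack.band(stack.master_index).astype(float)
    params = []
    for i in range(stack.n_bands):
        if i == stack.master_index:
            params.append(BandParams())
        else:
            params.append(estimate_band_transform(master, stack.band(i), refine))
    return BandAlignmentModel(bands=tuple(params),
                              master_index=stack.master_index)


@dataclass
class ProfileReport:
    """Per-band spectral values sampled along a short probe line."""

    segment: tuple[tuple[float, float], tuple[float, float]]  # (x, y) ends
    length: int
    values: np.ndarray = field(repr=False)  # length x B
    edge_offsets: np.ndarray = field(repr=False)  # px, per band, vs master
    master_index: int = 5


def _subpixel_edge(profile: np.ndarray) -> float:
    """Position of the steepest gradient with 3-point parabolic refinement."""
    g = np.abs(np.gradient(profile))
    k = int(np.argmax(g))
    if 0 < k < len(g) - 1:
        denom = g[k - 1] - 2 * g[k] + g[k + 1]
        if denom != 0:
            k = k + 0.5 * (g[k - 1] - g[k + 1]) / denom
    return float(k)


def spatial_profile(stack: MultibandStack,
                    segment: tuple[tuple[float, float], tuple[float, float]],
                    length: int = PROFILE_LENGTH) -> ProfileReport:
    """Sample all bands along a probe line and localise the edge per band.

    ``segment`` is ((x0, y0), (x1, y1)) in pixel coordinates.  The default
    line is 45 samples long, the length used when profiling reference-panel
    edges.  Each band's edge offset is the sub-pixel position of its
    steepest gradient minus the master band's.
    """
    (x0, y0), (x1, y1) = segment
    h, w = stack.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise IndexError(f"segment endpoint ({x}, {y}) outside image")
    t = np.linspace(0.0, 1.0, length)
    rows = y0 + t * (y1 - y0)
    cols = x0 + t * (x1 - x0)
    values = np.empty((length, stack.n_bands))
    for i in range(stack.n_bands):
        band = np.nan_to_num(stack.band(i).astype(float))
        values[:, i] = ndimage.map_coordinates(band, [rows, cols], order=1)

    # sample spacing in pixels: edge positions are reported in px, not samples
    spacing = math.hypot(x1 - x0, y1 - y0) / max(length - 1, 1)
    offsets = np.zeros(stack.n_bands)
    master_prof = values[:, stack.master_index]
    if np.ptp(master_prof) > 0:
        ref = _subpixel_edge(master_prof)
        for i in range(stack.n_bands):
            if np.ptp(values[:, i]) > 0:
                offsets[i] = (_subpixel_edge(values[:, i]) - ref) * spacing
    return ProfileReport(segment=segment, length=length, values=values,
                         edge_offsets=offsets, master_index=stack.master_index)


def misalignment_score(report: ProfileReport) -> float:
    """Maximum absolute per-band edge offset (px); 0 iff aligned at the edge."""
    if report.values.shape[1] < 2:
        raise ValueError("need at least two bands to score misalignment")
    return float(np.max(np.abs(report.edge_offsets)))
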