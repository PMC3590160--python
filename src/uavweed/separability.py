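"""Vegetation indices and spectral class-separability statistics.

Early-season weed mapping proceeds in two discrimination phases: vegetation
(crop + weeds together) against bare soil, then crop against weeds.  Both
are assessed here at the pixel level from vegetation indices:

* NDVI = (NIR - R) / (NIR + R)
* NGRDI = (G - R) / (G + R)
* ExG = 2g - r - b on chromatic coordinates (r = R/(R+G+B), etc.)

Class samples are pooled index pixels drawn from regions of interest; the
separability of two classes is quantified two ways:

* a one-way ANOVA followed by Fisher's protected LSD test (pairwise least
  significant differences on the pooled within-group variance), and
* the M-statistic, M = (mean1 - mean2) / (sd1 + sd2), a histogram-overlap
  measure: M > 1 indicates moderate separability, larger is easier.

The two can disagree — group means may differ significantly while wide,
overlapping histograms (small M) still make per-pixel classification
unreliable — which is exactly why both are reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon2mask

from .alignment import MultibandStack

__all__ = [
    "ClassSample",
    "PanelCalibration",
    "LsdResult",
    "calibrate_reflectance",
    "compute_index",
    "sample_class_pixels",
    "m_statistic",
    "anova_lsd",
    "separability_table",
    "INDEX_NAMES",
    "CLASS_LABELS",
]

INDEX_NAMES = ("NDVI", "NGRDI", "ExG")
CLASS_LABELS = ("bare_soil", "crop", "weed", "vegetation")

#: Nominal band-centre wavelengths (nm) each index pulls from a stack.  With
#: two red bands available (670 and 700 nm) the 670 nm band serves as R.
_WL = {"B": 450.0, "G": 530.0, "R": 670.0, "NIR": 780.0}
_INDEX_BANDS = {"NDVI": ("NIR", "R"), "NGRDI": ("G", "R"), "ExG": ("R", "G", "B")}


@dataclass
class ClassSample:
    """Pooled per-pixel index values for one cover class."""

    label: str
    index_name: str
    values: np.ndarray
    n_rois: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[np.isfinite(self.values)]
        if self.values.size == 0:
            raise ValueError(f"empty sample for class {self.label!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    def summary(self) -> dict[str, float]:
        return {"max": float(np.max(self.values)), "min": float(np.min(self.values)),
                "mean": self.mean, "sd": self.sd}


@dataclass
class PanelCalibration:
    """One-point empirical-line calibration against a reference panel.

    The panel (near-Lambertian, known reflectance, default 0.99) is located
    in the image by ``panel_mask``; each band's gain maps its mean panel
    digital number to the panel reflectance.
    """

    panel_mask: np.ndarray
    panel_reflectance: float = 0.99
    min_pixels: int = 30

    def __post_init__(self) -> None:
        self.panel_mask = np.asarray(self.panel_mask, dtype=bool)
        if self.panel_mask.sum() < self.min_pixels:
            raise ValueError(
                f"panel mask has {int(self.panel_mask.sum())} pixels, "
                f"need >= {self.min_pixels}"
            )


def calibrate_reflectance(stack: MultibandStack,
                          cal: PanelCalibration) -> MultibandStack:
    """Convert digital numbers to reflectance via the panel's per-band gain.

    reflectance = DN * panel_reflectance / mean(panel DN), band by band, so
    panel pixels average to the panel reflectance by construction and the
    result is invariant to any global rescaling of the DNs.
    """
    if cal.panel_mask.shape != stack.shape:
        raise ValueError("panel mask shape does not match stack")
    px = stack.pixels.astype(float)
    out = np.empty_like(px)
    for i in range(stack.n_bands):
        mean_dn = np.nanmean(px[:, :, i][cal.panel_mask])
        if not mean_dn > 0:
            raise ValueError(f"band {i}: non-positive mean panel DN")
        out[:, :, i] = px[:, :, i] * (cal.panel_reflectance / mean_dn)
    return replace(stack, pixels=out)


def compute_index(stack: MultibandStack, index_name: str) -> np.ndarray:
    """Per-pixel vegetation index image; invalid pixels are NaN.

    Works on raw DN or calibrated reflectance — all three indices are
    ratios (NDVI, NGRDI) or chromatic combinations (ExG), so a per-band
    global gain cancels for NDVI/NGRDI and a single global gain cancels
    for ExG.  Pixels with a zero denominator are flagged NaN, not imputed.
    """
    if index_name not in INDEX_NAMES:
        raise KeyError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
    try:
        bands = {k: stack.band(stack.band_index(_WL[k])).astype(float)
                 for k in _INDEX_BANDS[index_name]}
    except KeyError as e:
        raise KeyError(f"{index_name} requires a band the stack lacks: {e}") from e

    with np.errstate(divide="ignore", invalid="ignore"):
        if index_name == "NDVI":
            num, den = bands["NIR"] - bands["R"], bands["NIR"] + bands["R"]
        elif index_name == "NGRDI":
            num, den = bands["G"] - bands["R"], bands["G"] + bands["R"]
        else:  # ExG on chromatic coordinates: 2g - r - b = (2G - R - B)/(R+G+B)
            num = 2.0 * bands["G"] - bands["R"] - bands["B"]
            den = bands["R"] + bands["G"] + bands["B"]
        out = num / den
    out[den == 0] = np.nan
    return out


def rois_to_mask(shape: tuple[int, int],
                 rois: list[np.ndarray | list]) -> np.ndarray:
    """Rasterise polygons ((x, y) vertex lists) to a boolean mask.

    A pixel belongs to a polygon when its centre is inside (half-open
    raster convention, 0-based, origin at the top-left).
    """
    mask = np.zeros(shape, dtype=bool)
    for poly in rois:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError("each ROI must be an (n, 2) array of (x, y) vertices")
        mask |= polygon2mask(shape, poly[:, ::-1])  # polygon2mask wants (row, col)
    return mask


def sample_class_pixels(index_image: np.ndarray,
                        rois: list | np.ndarray,
                        label: str,
                        index_name: str = "NDVI") -> ClassSample:
    """Pool valid index pixels across the class's sampling areas.

    ``rois`` is either a list of (x, y) polygons or a boolean mask.  The
    ``vegetation`` class is conventionally the union of crop and weed
    sampling areas (pass the combined ROIs or a combined mask).
    """
    index_image = np.asarray(index_image, dtype=float)
    if isinstance(rois, np.ndarray) and rois.dtype == bool:
        mask, n_rois = rois, 1
    else:
        if len(rois) == 0:
            raise ValueError("no ROIs given")
        mask, n_rois = rois_to_mask(index_image.shape, rois), len(rois)
    vals = index_image[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid pixels for class {label!r} in the given ROIs")
    return ClassSample(label=label, index_name=index_name, values=vals,
                       n_rois=n_rois)


def m_statistic(s1: ClassSample | np.ndarray, s2: ClassSample | np.ndarray) -> float:
    """Histogram separability M = (mean1 - mean2) / (sd1 + sd2).

    Antisymmetric in its arguments.  |M| > 1 marks moderate separability;
    the same mean difference scores lower when the histograms are wider.
    Raises if both samples are degenerate (sd1 + sd2 = 0).
    """
    m1, sd1 = _mean_sd(s1)
    m2, sd2 = _mean_sd(s2)
    if sd1 + sd2 == 0:
        raise ZeroDivisionError("sd1 + sd2 = 0: M-statistic undefined for "
                                "degenerate distributions")
    return (m1 - m2) / (sd1 + sd2)


def _mean_sd(s) -> tuple[float, float]:
    if isinstance(s, ClassSample):
        return s.mean, s.sd
    a = np.asarray(s, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    return float(np.mean(a)), float(np.std(a, ddof=1)) if a.size > 1 else 0.0


@dataclass
class LsdResult:
    """One-way ANOVA + protected LSD outcome for k groups."""

    f_stat: float
    p_value: float
    df_within: int
    ms_within: float
    pairwise_p: pd.DataFrame = field(repr=False)
    letters: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.01

    def distinct(self, a: str, b: str) -> bool:
        """True when groups a and b share no compact-display letter."""
        return not (set(self.letters[a]) & set(self.letters[b]))


def anova_lsd(samples: list[ClassSample], alpha: float = 0.01) -> LsdResult:
    """One-way ANOVA with Fisher's protected LSD pairwise comparisons.

    The LSD criterion for groups i, j uses the pooled within-group mean
    square: |mean_i - mean_j| > t(1-alpha/2, df_w) * sqrt(MSw (1/n_i + 1/n_j)).
    "Protected" means pairwise differences are only declared when the
    overall ANOVA is itself significant at ``alpha``, which keeps the
    two-group false-positive rate at the nominal level.  Results are
    summarised as a compact letter display: groups sharing a letter are
    not significantly different.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for s in samples:
        if s.values.size < 2:
            raise ValueError(f"group {s.label!r} has fewer than 2 values")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    groups = [s.values for s in samples]
    f_stat, p_value = stats.f_oneway(*groups)

    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    df_w = int(ns.sum() - k)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    msw = ssw / df_w

    pmat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
        t = abs(means[i] - means[j]) / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(t, df_w)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
        # protected LSD: pairwise claims require a significant omnibus F
        sig[i, j] = sig[j, i] = (p <= alpha) and (p_value <= alpha)

    letters = _compact_letters(labels, sig, order=np.argsort(-means))
    return LsdResult(f_stat=float(f_stat), p_value=float(p_value),
                     df_within=df_w, ms_within=msw, pairwise_p=pmat,
                     letters=letters, alpha=alpha)


def _compact_letters(labels: list[str], sig: np.ndarray,
                     order: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a significance matrix."""
    k = len(labels)
    groups: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for g in [g for g in groups if i in g and j in g]:
            groups.remove(g)
            groups.extend((g - {i}, g - {j}))
        # absorb: drop empty groups, duplicates and strict subsets
        uniq: list[set[int]] = []
        for g in groups:
            if g and g not in uniq:
                uniq.append(g)
        groups = [g for g in uniq if not any(g < h for h in uniq)]
    groups = sorted(groups, key=lambda g: min(list(order).index(i) for i in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {lab: "" for lab in labels}
    for letter, g in zip(alphabet, groups):
        for i in sorted(g):
            out[labels[i]] += letter
    return out


_PAIRS = (("vegetation", "bare_soil"), ("crop", "weed"))


def separability_table(images: dict, class_rois: dict,
                       indices: tuple[str, ...] = INDEX_NAMES,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Class-separability summary across cameras, altitudes and indices.

    Parameters
    ----------
    images : dict
        ``{(camera_name, altitude): MultibandStack}``.
    class_rois : dict
        ``{(camera_name, altitude): {label: rois-or-mask}}`` with entries
        for ``bare_soil``, ``crop`` and ``weed``; the ``vegetation`` class
        is derived as crop + weed pooled together.
    indices : tuple of str
        Which indices to evaluate; NDVI rows are emitted only for stacks
        that carry a NIR band.

    Returns
    -------
    DataFrame with one row per (camera, altitude, index, class pair):
    per-class max/min/mean/sd, the ANOVA p-value, whether the protected
    LSD separates the pair at ``alpha``, and the M-statistic.  A missing
    class yields an absent row rather than a failure.
    """
    rows = []
    for (camera, altitude), stack in sorted(images.items(), key=lambda kv: str(kv[0])):
        rois = class_rois[(camera, altitude)]
        for index_name in indices:
            try:
                img = compute_index(stack, index_name)
            except KeyError:
                continue  # e.g. NDVI on a camera with no NIR band
            samples: dict[str, ClassSample] = {}
            for label in ("bare_soil", "crop", "weed"):
                if label not in rois:
                    continue
                try:
                    samples[label] = sample_class_pixels(
                        img, rois[label], label, index_name)
                except ValueError:
                    continue
            if "crop" in samples and "weed" in samples:
                veg = np.concatenate([samples["crop"].values,
                                      samples["weed"].values])
                samples["vegetation"] = ClassSample(
                    label="vegetation", index_name=index_name, values=veg,
                    n_rois=samples["crop"].n_rois + samples["weed"].n_rois)
            for c1, c2 in _PAIRS:
                if c1 not in samples or c2 not in samples:
                    continue
                s1, s2 = samples[c1], samples[c2]
                res = anova_lsd([s1, s2], alpha=alpha)
                sm1, sm2 = s1.summary(), s2.summary()
                rows.append({
                    "camera": camera, "altitude": altitude,
                    "index": index_name, "class1": c1, "class2": c2,
                    "max1": sm1["max"], "min1": sm1["min"],
                    "mean1": sm1["mean"], "sd1": sm1["sd"],
                    "max2": sm2["max"], "min2": sm2["min"],
                    "mean2": sm2["mean"], "sd2": sm2["sd"],
                    "anova_p": res.p_value,
                    "lsd_distinct": res.distinct(c1, c2),
                    "M": m_statistic(s1, s2),
                })
    return pd.DataFrame(rows)
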