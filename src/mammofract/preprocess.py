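"""Mammogram enhancement: low-light dehazing and the Hölder α-image.

Dense breast tissue veils microcalcifications much as haze veils a
scene, so the enhancement chain treats density as haze: the image is
inverted, a dark-channel-prior dehazing step removes the "haze", and the
result is re-inverted.  Contrast is then converted to a *local
regularity* representation: for every pixel the mass of the intensity
measure inside centered windows of growing size L is regressed in
log-log coordinates, and the slope — the local Hölder exponent
alpha(m, n) — forms the α-image.  Strong local singularities
(microcalcifications) have alpha well away from the smooth-background
value 2, so the min-max rescaled singularity magnitude |alpha - 2|
yields the enhanced mammogram handed to the spectrum estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter, uniform_filter

__all__ = [
    "HazeParams",
    "HolderMap",
    "dark_channel",
    "enhance_lowlight",
    "alpha_image",
    "preprocess_mammogram",
]

# one 8-bit gray level, in [0, 1] intensity units; added before taking
# logarithms so zero-background pixels have a defined measure
DEFAULT_MEASURE_OFFSET = 1.0 / 255.0


@dataclass(frozen=True)
class HazeParams:
    """Dark-channel-prior dehazing parameters.

    patch_size : side of the local-minimum patch (odd), pixels
    omega : fraction of the estimated haze that is removed, in [0, 1]
    t0 : transmission floor in (0, 1], bounds the recovery divisor
    airlight_frac : top fraction of dark-channel pixels used to estimate
        the atmospheric light
    """

    patch_size: int = 15
    omega: float = 0.8
    t0: float = 0.1
    airlight_frac: float = 0.001

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be an odd integer >= 1")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if not 0.0 < self.t0 <= 1.0:
            raise ValueError("t0 must lie in (0, 1]")
        if not 0.0 < self.airlight_frac <= 1.0:
            raise ValueError("airlight_frac must lie in (0, 1]")


@dataclass(frozen=True)
class HolderMap:
    """Per-pixel Hölder exponents with their regression quality."""

    alpha: np.ndarray
    fit_r2: np.ndarray


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D grayscale array")
    if not np.all(np.isfinite(img)) or img.min() < 0 or img.max() > 1:
        raise ValueError("intensities must be finite and within [0, 1]")
    return img


def dark_channel(img: np.ndarray, patch_size: int) -> np.ndarray:
    """Local minimum of the image over a centered square patch.

    Borders are handled by replicate padding (``nearest`` mode), so the
    patch never reaches outside the image support.
    """
    return minimum_filter(np.asarray(img, dtype=float), size=patch_size, mode="nearest")


def enhance_lowlight(img: np.ndarray, params: HazeParams | None = None) -> np.ndarray:
    """Brighten veiled structure via dehazing of the inverted image.

    Steps: invert; estimate the dark channel (local patch minimum);
    estimate the atmospheric light A as the mean inverted intensity over
    the brightest ``airlight_frac`` of dark-channel pixels; transmission
    ``t = max(t0, 1 - omega * dark / A)``; recover the scene radiance
    ``J = (I - A) / t + A``; re-invert and clip to [0, 1].  Fully
    deterministic; a spatially constant input maps to a constant output.
    """
    params = params or HazeParams()
    img = _check_image(img)
    inv = 1.0 - img
    dark = dark_channel(inv, params.patch_size)
    k = max(1, int(round(params.airlight_frac * dark.size)))
    idx = np.argpartition(dark.ravel(), dark.size - k)[-k:]
    A = float(inv.ravel()[idx].mean())
    if A <= 0:
        return img.copy()  # white input: nothing to dehaze
    t = np.maximum(params.t0, 1.0 - params.omega * dark / A)
    J = (inv - A) / t + A
    return np.clip(1.0 - J, 0.0, 1.0)


def alpha_image(
    img: np.ndarray,
    window_sizes: tuple[int, ...] = (1, 3, 5),
    offset: float = DEFAULT_MEASURE_OFFSET,
) -> HolderMap:
    """Local Hölder exponents from the scaling of window sum-measures.

    For every pixel the measure ``mu(m, n; L)`` is the total intensity in
    the centered L x L window (replicate padding at borders, intensities
    shifted by ``offset`` so every measure is positive); ``alpha(m, n)``
    is the least-squares slope of ``ln mu`` against ``ln L`` over the
    window sizes.  A constant image c > 0 gives ``alpha = 2`` everywhere
    (``mu = c L**2``); an isolated point mass (with offset 0) gives
    ``alpha = 0`` at the point.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale array")
    sizes = tuple(int(w) for w in window_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 window sizes to fit a slope")
    if len(set(sizes)) != len(sizes) or any(w < 1 or w % 2 == 0 for w in sizes):
        raise ValueError("window sizes must be distinct odd integers >= 1")
    shifted = img + offset
    if np.any(shifted <= 0):
        raise ValueError("measure must be positive everywhere; increase offset")
    x = np.log(np.asarray(sizes, dtype=float))
    logmu = np.empty((len(sizes), *img.shape))
    for k, L in enumerate(sizes):
        mu = uniform_filter(shifted, size=L, mode="nearest") * (L * L) if L > 1 else shifted
        # filtering of denormal-range measures can underflow to 0; floor
        # keeps the log finite without affecting any realistic intensity
        logmu[k] = np.log(np.maximum(mu, 1e-300))
    xc = x - x.mean()
    yc = logmu - logmu.mean(axis=0)
    sxx = float((xc**2).sum())
    slope = np.tensordot(xc, yc, axes=(0, 0)) / sxx
    resid = yc - slope[None, :, :] * xc[:, None, None]
    ss_tot = (yc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - (resid**2).sum(axis=0) / ss_tot, 1.0)
    return HolderMap(slope, r2)


def preprocess_mammogram(
    img: np.ndarray,
    haze: HazeParams | None = None,
    window_sizes: tuple[int, ...] = (1, 3, 5),
    bg_threshold: float = 0.0,
    crop: bool = True,
    trace: list | None = None,
):
    """Full enhancement chain: crop -> dehaze -> α-image -> rescale.

    Returns ``(enhanced, flags)`` where ``enhanced`` is the
    singularity-magnitude map |α - 2| min-max rescaled to [0, 1]: smooth
    tissue (α near the regular-surface exponent 2) maps to dark, and
    strong local singularities — microcalcifications — map to bright,
    as in an enhanced mammogram.  ``flags`` is a set of quality warnings
    (``{"constant_alpha"}`` when the α-map is degenerate, in which case
    a zero image is returned).  ``trace``, if given, collects the stage
    names in execution order.
    """
    from .io_roi import crop_breast_field

    img = _check_image(img)
    flags: set[str] = set()
    if crop:
        img, _ = crop_breast_field(img, bg_threshold)
        if trace is not None:
            trace.append("crop")
    img = enhance_lowlight(img, haze)
    if trace is not None:
        trace.append("enhance")
    amap = alpha_image(img, window_sizes).alpha
    if trace is not None:
        trace.append("alpha")
    # singularity magnitude: distance from the regular-surface exponent 2,
    # so a microcalcification (alpha well away from 2) maps to *bright*
    smap = np.abs(amap - 2.0)
    lo, hi = float(smap.min()), float(smap.max())
    if hi - lo <= 1e-12:
        flags.add("constant_alpha")
        return np.zeros_like(smap), flags
    return (smap - lo) / (hi - lo), flags
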