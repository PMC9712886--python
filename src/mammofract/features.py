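"""Per-ROI feature extraction: multifractal spectrum descriptors + GLCM.

Each ROI is reduced to nine ordered scalars: five read off its
singularity spectrum —

* ``alpha0``: the Hölder exponent at the spectrum maximum,
* ``w = alpha_max - alpha_min``: spectrum width (degree of
  multifractality),
* ``R = alpha0 - alpha_min`` and ``Lfeat = alpha_max - alpha0``: left and
  right half-widths,
* ``A = R / Lfeat``: asymmetry —

and four Haralick statistics (contrast, correlation, energy,
homogeneity) of the gray-level co-occurrence matrix at offset (0, +1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .boxcount import (
    DEFAULT_SCALES_64,
    Spectrum,
    chhabra_jensen_spectrum,
    default_qgrid,
    generalized_dimensions,
    legendre_spectrum,
)
from .mfdma import MFDMAConfig, mfdma_spectrum

__all__ = [
    "SpectrumFeatures",
    "GLCMFeatures",
    "FeatureConfig",
    "FeatureVector",
    "spectrum_features",
    "glcm",
    "glcm_stats",
    "feature_vector",
    "feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "alpha0",
    "w",
    "R",
    "L",
    "A",
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
)


@dataclass(frozen=True)
class SpectrumFeatures:
    """The five scalars summarizing a singularity spectrum."""

    alpha0: float
    w: float
    R: float
    Lfeat: float
    A: float  # NaN when Lfeat == 0 (flagged, never silently infinite)
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    correlation: float  # NaN when a marginal is degenerate
    energy: float
    homogeneity: float
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FeatureConfig:
    """Everything needed to turn one ROI into its 9-feature vector."""

    estimator: str = "boxcount"  # boxcount (direct spectrum) | legendre | mfdma
    qgrid: np.ndarray = field(default_factory=default_qgrid)
    scales: tuple[int, ...] = DEFAULT_SCALES_64
    mfdma: MFDMAConfig = field(default_factory=MFDMAConfig)
    glcm_levels: int = 8
    glcm_symmetric: bool = False


@dataclass(frozen=True)
class FeatureVector:
    roi_id: str
    values: tuple[float, ...]  # ordered as FEATURE_COLUMNS
    label: str
    flags: frozenset[str] = frozenset()


def spectrum_features(spec: Spectrum) -> SpectrumFeatures:
    """Read the five descriptors off a spectrum's (alpha, f) pairs.

    ``alpha_min`` / ``alpha_max`` are the grid extremes of alpha(q);
    ``alpha0`` is alpha at the q that maximizes f (ties broken toward the
    q closest to 0).  When the spectrum degenerates to a point
    (``Lfeat = 0``) the asymmetry is NaN and flagged.
    """
    ok = np.isfinite(spec.alpha_q) & np.isfinite(spec.f_q)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite (alpha, f) pairs")
    a, f, q = spec.alpha_q[ok], spec.f_q[ok], spec.q[ok]
    a_min, a_max = float(a.min()), float(a.max())
    best = np.flatnonzero(f == f.max())
    alpha0 = float(a[best[np.argmin(np.abs(q[best]))]])
    R = alpha0 - a_min
    Lfeat = a_max - alpha0
    flags = set()
    if Lfeat > 0:
        A = R / Lfeat
    else:
        A = float("nan")
        flags.add("asymmetry_undefined")
    if a_max - a_min <= 1e-12:
        flags.add("point_spectrum")
    return SpectrumFeatures(alpha0, a_max - a_min, R, Lfeat, A, frozenset(flags))


def quantize(roi: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin intensities into ``levels`` gray levels over [min, max]."""
    roi = np.asarray(roi, dtype=float)
    lo, hi = roi.min(), roi.max()
    if hi - lo <= 0:
        return np.zeros(roi.shape, dtype=np.uint16)
    g = np.floor((roi - lo) / (hi - lo) * levels).astype(np.uint16)
    return np.minimum(g, levels - 1)


def glcm(
    roi: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
) -> np.ndarray:
    """Gray-level co-occurrence matrix, normalized to sum 1.

    Intensities are uniformly quantized to ``levels`` bins over the ROI's
    own [min, max]; ordered pixel pairs at the given (drow, dcol) offset
    are counted (non-symmetric by default).  A constant ROI puts all mass
    at the (0, 0) cell.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dr, dc = offset
    g = quantize(roi, levels)
    if g.shape[0] <= abs(dr) or g.shape[1] <= abs(dc):
        raise ValueError("roi smaller than the co-occurrence offset")
    distance = float(np.hypot(dr, dc))
    angle = float(np.arctan2(-dr, dc))  # skimage angles: 0 is (0, +1)
    P = graycomatrix(
        g, distances=[distance], angles=[angle], levels=levels, symmetric=symmetric, normed=False
    )[:, :, 0, 0].astype(float)
    return P / P.sum()


def glcm_stats(P: np.ndarray) -> GLCMFeatures:
    """Haralick statistics of a normalized co-occurrence matrix.

    contrast = sum |i-j|^2 P(i,j);  energy = sum P^2;
    homogeneity = sum P / (1 + (i-j)^2);
    correlation = sum (i - mu_i)(j - mu_j) P / (sigma_i sigma_j) with the
    marginal means and standard deviations of P — flagged NaN when either
    marginal is concentrated on a single level.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    d2 = (i - j) ** 2
    contrast = float((d2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + d2)).sum())
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mu_i, mu_j = float(np.arange(n) @ pi), float(np.arange(n) @ pj)
    var_i = float(((np.arange(n) - mu_i) ** 2) @ pi)
    var_j = float(((np.arange(n) - mu_j) ** 2) @ pj)
    flags = set()
    if var_i > 0 and var_j > 0:
        corr = float(((i - mu_i) * (j - mu_j) * P).sum() / np.sqrt(var_i * var_j))
    else:
        corr = float("nan")
        flags.add("correlation_undefined")
    return GLCMFeatures(contrast, corr, energy, homogeneity, frozenset(flags))


def roi_spectrum(roi: np.ndarray, config: FeatureConfig) -> Spectrum:
    """Run the configured spectrum estimator on one ROI."""
    if config.estimator == "boxcount":
        return chhabra_jensen_spectrum(roi, config.qgrid, config.scales)
    if config.estimator == "legendre":
        return legendre_spectrum(generalized_dimensions(roi, config.qgrid, config.scales))
    if config.estimator == "mfdma":
        return mfdma_spectrum(roi, config.mfdma)
    raise ValueError(f"unknown estimator {config.estimator!r}")


def feature_vector(
    roi: np.ndarray, config: FeatureConfig | None = None, roi_id: str = "", label: str = "normal"
) -> FeatureVector:
    """Assemble one ROI's ordered 9-feature vector.

    Deterministic given the configuration; undefined components (point
    spectrum, degenerate GLCM marginals) are emitted as NaN with their
    condition recorded in ``flags`` — the classifier stage imputes them
    with training-fold medians.
    """
    config = config or FeatureConfig()
    sf = spectrum_features(roi_spectrum(roi, config))
    gf = glcm_stats(glcm(roi, config.glcm_levels, symmetric=config.glcm_symmetric))
    values = (
        sf.alpha0,
        sf.w,
        sf.R,
        sf.Lfeat,
        sf.A,
        gf.contrast,
        gf.correlation,
        gf.energy,
        gf.homogeneity,
    )
    return FeatureVector(roi_id, values, label, sf.flags | gf.flags)


def feature_table(
    rois,
    labels,
    config: FeatureConfig | None = None,
    roi_ids=None,
) -> pd.DataFrame:
    """Feature vectors for a list of ROIs as a tidy DataFrame.

    Columns: ``roi_id, label, alpha0, w, R, L, A, contrast, correlation,
    energy, homogeneity, flags`` in fixed order.
    """
    config = config or FeatureConfig()
    if roi_ids is None:
        roi_ids = [f"roi_{k:05d}" for k in range(len(rois))]
    rows = []
    for rid, roi, lab in zip(roi_ids, rois, labels):
        fv = feature_vector(roi, config, rid, lab)
        rows.append(
            {"roi_id": fv.roi_id, "label": fv.label}
            | dict(zip(FEATURE_COLUMNS, fv.values))
            | {"flags": ";".join(sorted(fv.flags))}
        )
    return pd.DataFrame(rows, columns=["roi_id", "label", *FEATURE_COLUMNS, "flags"])
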