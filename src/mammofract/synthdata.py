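"""Synthetic textures with known multifractal structure.

Ground-truth generators used both as test oracles and as a stand-in
dataset for mammographic regions of interest (ROIs):

* deterministic / randomized multiplicative cascades, whose mass
  exponents ``tau(q)`` and singularity spectrum ``(alpha(q), f(q))``
  are available in closed form (:func:`cascade_analytic`);
* fractional Brownian surfaces, a monofractal control whose spectrum
  should collapse to a point;
* 64x64 mammogram-like ROIs: a multifractal textured background with
  optional small bright Gaussian blobs emulating microcalcifications
  embedded at known centers.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CascadeSpec",
    "BlobSpec",
    "multiplicative_cascade",
    "cascade_analytic",
    "fbm_surface",
    "synth_roi_dataset",
]


@dataclass(frozen=True)
class CascadeSpec:
    """Specification of a 2D multiplicative (multinomial) cascade.

    The unit square is recursively split into four quadrants; the mass of a
    cell is multiplied by one of the four ``weights`` in each subdivision.
    The image side is ``2**depth`` pixels and total mass is exactly 1.
    """

    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    depth: int = 8
    placement: Literal["fixed", "shuffled"] = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w <= 0):
            raise ValueError("cascade needs 4 positive weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"cascade weights must sum to 1, got {w.sum()!r}")
        if self.depth < 1:
            raise ValueError("cascade depth must be >= 1")
        if self.placement not in ("fixed", "shuffled"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class BlobSpec:
    """Isotropic Gaussian bright blobs emulating microcalcifications.

    ``amplitude`` is expressed as a multiple of the background's
    fluctuation scale — the 99th percentile of the absolute deviation
    from the median intensity — so blob brightness tracks the texture
    contrast of the tissue it sits on rather than the absolute gray
    level (a multiple of absolute intensity could not be represented in
    the [0, 1] gray range without total saturation).
    """

    amplitude: float = 5.0
    sigma: float = 1.5
    count: int = 1
    seed: int = 0
    margin: int = 8  # keep blob centers this far from the ROI border

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("blob amplitude must be >= 0")
        if self.sigma <= 0:
            raise ValueError("blob sigma must be > 0")
        if self.count < 0:
            raise ValueError("blob count must be >= 0")


def multiplicative_cascade(spec: CascadeSpec) -> np.ndarray:
    """Generate a multinomial cascade measure of side ``2**depth``.

    Returns a 2D array whose entries sum to 1.  With ``placement="fixed"``
    every subdivision assigns the weights to quadrants in the same order
    (top-left, top-right, bottom-left, bottom-right); with ``"shuffled"``
    each subdivision draws an independent random permutation of the four
    weights, which randomizes the texture while preserving the analytic
    multifractal spectrum.
    """
    w = np.asarray(spec.weights, dtype=float)
    rng = np.random.default_rng(spec.seed)
    m = np.ones((1, 1))
    for level in range(spec.depth):
        side = m.shape[0]
        out = np.empty((2 * side, 2 * side))
        if spec.placement == "fixed":
            quad = np.broadcast_to(w, (side, side, 4))
        else:
            # independent weight permutation at every node of this level
            quad = rng.permuted(np.broadcast_to(w, (side, side, 4)), axis=2)
        out[0::2, 0::2] = m * quad[..., 0]
        out[0::2, 1::2] = m * quad[..., 1]
        out[1::2, 0::2] = m * quad[..., 2]
        out[1::2, 1::2] = m * quad[..., 3]
        m = out
    return m


def cascade_analytic(
    weights: Sequence[float], q: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form multifractal functions of a multinomial cascade.

    For a quadtree cascade with weights ``p_j`` (box side halves at each
    level, so the natural scale base is 2):

    * ``tau(q) = -log2( sum_j p_j**q )``
    * ``alpha(q) = sum_j w_j(q) * log2(1/p_j)`` with
      ``w_j(q) = p_j**q / sum_j p_j**q``
    * ``f(q) = q*alpha(q) - tau(q)``

    Returns ``(tau, alpha, f)`` evaluated on ``q``.
    """
    p = np.asarray(weights, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    pq = p[None, :] ** q[:, None]
    z = pq.sum(axis=1)
    tau = -np.log2(z)
    wgt = pq / z[:, None]
    alpha = wgt @ np.log2(1.0 / p)
    f = q * alpha - tau
    return tau, alpha, f


def fbm_surface(hurst: float, size: int, seed: int = 0) -> np.ndarray:
    """Fractional Brownian surface by spectral synthesis.

    The surface is synthesized by shaping complex Gaussian white noise with
    an isotropic power spectrum ``S(f) ~ f**-(2H+2)`` (the 2D fBm density)
    and inverting the FFT.  Output is min-max rescaled to [0, 1].
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if size < 2 or size & (size - 1):
        raise ValueError("size must be a power of two >= 2")
    rng = np.random.default_rng(seed)
    f1 = np.fft.fftfreq(size)
    fr = np.hypot(f1[:, None], f1[None, :])
    fr[0, 0] = np.inf  # kill the DC term
    amp = fr ** (-(hurst + 1.0))
    noise = rng.normal(size=(size, size)) + 1j * rng.normal(size=(size, size))
    surf = np.fft.ifft2(noise * amp).real
    lo, hi = surf.min(), surf.max()
    return (surf - lo) / (hi - lo)


def _add_blobs(roi: np.ndarray, blob: BlobSpec, rng: np.random.Generator) -> np.ndarray:
    """Add ``blob.count`` Gaussian bumps at random interior centers.

    The bump amplitude is ``blob.amplitude`` times the background's
    fluctuation scale (99th percentile of |intensity - median|); the
    result saturates at 1 (detector clipping), so a bright blob appears
    as a small dot on the tissue, not as a rescaling of the whole ROI.
    """
    size = roi.shape[0]
    amp = blob.amplitude * np.quantile(np.abs(roi - np.median(roi)), 0.99)
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    out = roi.copy()
    for _ in range(blob.count):
        cr, cc = rng.integers(blob.margin, size - blob.margin, size=2)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        out = out + amp * np.exp(-d2 / (2.0 * blob.sigma**2))
    return np.clip(out, 0.0, 1.0)


def synth_roi_dataset(
    n_per_class: int,
    background: Literal["cascade", "fbm"] = "cascade",
    blob: BlobSpec | None = None,
    seed: int = 0,
    size: int = 64,
    cascade_weights: tuple[float, float, float, float] = (0.3, 0.25, 0.25, 0.2),
    fbm_hurst: float = 0.5,
    density: float = 0.7,
    texture_contrast: float = 0.2,
    psf_sigma: float = 1.5,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate a balanced labeled set of 64x64 synthetic ROIs.

    The background emulates dense tissue: a bright base level
    (``density``, the haze that masks microcalcifications on real
    mammograms) plus a low-amplitude multifractal texture
    (``texture_contrast`` peak-to-peak).  Cascade texture uses the
    *logarithm* of the multiplicative measure — an optical-density-like
    field whose heterogeneity still tracks the cascade weights — so the
    raw ROI is a plausible gray image rather than a spiky measure.  The
    texture is smoothed with a Gaussian of ``psf_sigma`` pixels, the
    imaging system's point-spread scale: tissue has no structure below
    it, while a microcalcification — a near-point object — images as a
    blob of exactly that size.  Abnormal ROIs additionally get
    ``blob.count`` bright Gaussian blobs (clipped at saturation); normal
    ROIs are background only.  Every ROI has an independent background
    realization.

    Returns ``(rois, manifest)`` where ``manifest`` has columns
    ``image_id, center_row, center_col, label`` — the annotation schema the
    ROI-ingestion module consumes.  If ``out_dir`` is given, the ROIs are
    additionally written as PNG tiles next to ``manifest.csv`` and a
    ``dataset.json`` recording all specification fields.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if size < 4 or size & (size - 1):
        raise ValueError("size must be a power of two >= 4")
    if not 0.0 < density < 1.0 or not 0.0 < texture_contrast <= 1.0:
        raise ValueError("density must be in (0,1) and texture_contrast in (0,1]")
    if blob is None:
        blob = BlobSpec()
    depth = int(np.log2(size))
    rng = np.random.default_rng(seed)

    rois: list[np.ndarray] = []
    rows = []
    for label in ("abnormal", "normal"):
        for i in range(n_per_class):
            bg_seed = int(rng.integers(0, 2**31 - 1))
            if background == "cascade":
                tex = np.log(
                    multiplicative_cascade(CascadeSpec(cascade_weights, depth, "shuffled", bg_seed))
                )
            elif background == "fbm":
                tex = fbm_surface(fbm_hurst, size, bg_seed)
            else:
                raise ValueError(f"unknown background {background!r}")
            if psf_sigma > 0:
                from scipy.ndimage import gaussian_filter

                tex = gaussian_filter(tex, psf_sigma)
            tex = (tex - tex.min()) / (tex.max() - tex.min())
            bg = np.clip(density + texture_contrast * (tex - 0.5), 0.0, 1.0)
            roi = _add_blobs(bg, blob, rng) if label == "abnormal" else bg
            rois.append(roi)
            rows.append(
                {
                    "image_id": f"{label[0]}{i:04d}",
                    "center_row": size // 2,
                    "center_col": size // 2,
                    "label": label,
                }
            )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        for roi, row in zip(rois, manifest.itertuples()):
            iio.imwrite(
                out / f"{row.image_id}.png",
                np.round(roi * 65535).astype(np.uint16),
            )
        manifest.to_csv(out / "manifest.csv", index=False)
        meta = {
            "n_per_class": n_per_class,
            "background": background,
            "size": size,
            "cascade_weights": list(cascade_weights),
            "fbm_hurst": fbm_hurst,
            "density": density,
            "texture_contrast": texture_contrast,
            "psf_sigma": psf_sigma,
            "blob": {
                "amplitude": blob.amplitude,
                "sigma": blob.sigma,
                "count": blob.count,
                "seed": blob.seed,
                "margin": blob.margin,
            },
            "seed": seed,
        }
        (out / "dataset.json").write_text(json.dumps(meta, indent=2))
    return rois, manifest
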