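"""Box-counting multifractal analysis of grayscale images.

Implements the generalized-fractal-dimensions route: box mass
probabilities ``P_i(L)``, the partition-function scaling of their q-th
moments giving mass exponents ``tau(q)`` and generalized dimensions
``D_q``, the Legendre transform to the singularity spectrum, and the
Chhabra–Jensen direct estimate of ``(alpha(q), f(alpha))`` that avoids
the numerical Legendre differentiation altogether.

The measure is pixel-intensity mass by default: ``P_i`` is the box's
intensity sum divided by the image's total intensity.  A binary
(occupancy) mode is available via ``threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "default_qgrid",
    "MassDistribution",
    "ScalingFunctions",
    "Spectrum",
    "box_masses",
    "generalized_dimensions",
    "chhabra_jensen_spectrum",
    "legendre_spectrum",
]

DEFAULT_SCALES_64 = (2, 4, 8, 16, 32)


def default_qgrid(qmin: float = -4.0, qmax: float = 4.0, step: float = 0.1) -> np.ndarray:
    """Moment-order grid, default q = -4, -3.9, ..., 4."""
    n = int(round((qmax - qmin) / step))
    q = qmin + step * np.arange(n + 1)
    return np.round(q, 10)


def _check_qgrid(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size < 3:
        raise ValueError("qgrid must be a 1D array with at least 3 entries")
    if np.any(np.diff(q) <= 0):
        raise ValueError("qgrid must be strictly increasing")
    return q


@dataclass(frozen=True)
class MassDistribution:
    """Box mass probabilities of an image at one box size."""

    box_size: int
    probabilities: np.ndarray  # P_i over occupied boxes, sums to 1
    n_occupied: int
    total_mass: float


@dataclass(frozen=True)
class ScalingFunctions:
    """Generalized dimensions and mass exponents over a q grid."""

    q: np.ndarray
    D_q: np.ndarray
    tau_q: np.ndarray
    fit_r2: np.ndarray
    scales: tuple[int, ...]

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"q": self.q, "D_q": self.D_q, "tau": self.tau_q, "r2": self.fit_r2}
        )


@dataclass(frozen=True)
class Spectrum:
    """Singularity spectrum: pairs (alpha(q), f(alpha(q))) over a q grid."""

    q: np.ndarray
    alpha_q: np.ndarray
    f_q: np.ndarray
    fit_r2: np.ndarray
    method: str  # chhabra_jensen | legendre | mfdma

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"q": self.q, "alpha": self.alpha_q, "f": self.f_q, "r2": self.fit_r2}
        )


def _as_measure(roi: np.ndarray, threshold: float | None) -> np.ndarray:
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2:
        raise ValueError("roi must be a 2D array")
    if np.any(roi < 0):
        raise ValueError("roi intensities must be non-negative")
    if threshold is not None:
        roi = (roi > threshold).astype(float)
    total = roi.sum()
    if total <= 0:
        raise ValueError("zero total mass: cannot form box probabilities")
    return roi


def _pad_pow2(roi: np.ndarray) -> np.ndarray:
    """Zero-pad each side up to the next power of two (no-op if already)."""
    side = max(roi.shape)
    p = 1
    while p < side:
        p *= 2
    if roi.shape == (p, p):
        return roi
    out = np.zeros((p, p))
    out[: roi.shape[0], : roi.shape[1]] = roi
    return out


def box_masses(roi: np.ndarray, L: int, threshold: float | None = None) -> MassDistribution:
    """Mass probabilities of disjoint L x L boxes.

    ``P_i`` is the intensity sum of box i over the total image intensity;
    empty boxes are excluded (required for negative moment orders).  The
    image is zero-padded to the next power of two if L does not divide its
    side.
    """
    m = _pad_pow2(_as_measure(roi, threshold))
    if L < 1 or m.shape[0] % L:
        raise ValueError(f"box size {L} must be >= 1 and divide the padded side {m.shape[0]}")
    nb = m.shape[0] // L
    sums = m.reshape(nb, L, nb, L).sum(axis=(1, 3)).ravel()
    total = float(sums.sum())
    p = sums[sums > 0] / total
    return MassDistribution(L, p, int(p.size), total)


def _fit_slopes(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise least-squares slope of Y against x, plus R^2."""
    xc = x - x.mean()
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum()
    slope = (yc * xc).sum(axis=1) / sxx
    ss_res = ((yc - slope[:, None] * xc) ** 2).sum(axis=1)
    ss_tot = (yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return slope, r2


def _check_scales(roi_side: int, scales) -> tuple[int, ...]:
    scales = tuple(int(s) for s in scales)
    if len(scales) < 3:
        raise ValueError("need at least 3 box sizes for a scaling fit")
    for s in scales:
        if s < 1 or s & (s - 1):
            raise ValueError(f"box size {s} is not a power of two")
    return scales


def _moment_curves(
    roi: np.ndarray, q: np.ndarray, scales: tuple[int, ...], threshold: float | None
):
    """log-domain moment sums per (q, L) plus the Chhabra–Jensen numerators.

    Returns ``(logZ, S_alpha, S_f, S_entropy)`` with shapes (nq, nL) for the
    first three and (nL,) for the entropy sum used by the q=1 limit:

    * ``logZ[j, k] = log sum_i P_i(L_k)**q_j``
    * ``S_alpha[j, k] = sum_i mu_i(q_j, L_k) * log P_i(L_k)``
    * ``S_f[j, k] = sum_i mu_i * log mu_i`` with the normalized measures
      ``mu_i = P_i**q / sum P_i**q``
    * ``S_entropy[k] = sum_i P_i * log P_i``
    """
    nq, nL = q.size, len(scales)
    logZ = np.empty((nq, nL))
    S_alpha = np.empty((nq, nL))
    S_f = np.empty((nq, nL))
    S_entropy = np.empty(nL)
    for k, L in enumerate(scales):
        logp = np.log(box_masses(roi, L, threshold).probabilities)
        A = q[:, None] * logp[None, :]
        lz = logsumexp(A, axis=1)
        mu = np.exp(A - lz[:, None])
        logZ[:, k] = lz
        S_alpha[:, k] = mu @ logp
        S_f[:, k] = (mu * (A - lz[:, None])).sum(axis=1)
        S_entropy[k] = np.exp(logp) @ logp
    return logZ, S_alpha, S_f, S_entropy


def generalized_dimensions(
    roi: np.ndarray,
    qgrid: np.ndarray | None = None,
    scales=DEFAULT_SCALES_64,
    threshold: float | None = None,
) -> ScalingFunctions:
    """Generalized dimensions D_q and mass exponents tau(q).

    For q != 1, ``D_q`` is ``1/(q-1)`` times the least-squares slope of
    ``log sum_i P_i(L)**q`` against ``log L`` over the box sizes; at q = 1
    the L'Hopital limit is used: ``D_1`` is the slope of
    ``sum_i P_i log P_i`` against ``log L``.  ``tau(q) = (q-1) D_q``.
    """
    q = _check_qgrid(default_qgrid() if qgrid is None else qgrid)
    scales = _check_scales(max(np.asarray(roi).shape), scales)
    logZ, _, _, S_ent = _moment_curves(roi, q, scales, threshold)
    x = np.log(np.asarray(scales, dtype=float))
    tau, r2 = _fit_slopes(x, logZ)
    d1_slope, d1_r2 = _fit_slopes(x, S_ent[None, :])
    near1 = np.isclose(q, 1.0, atol=1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(near1, d1_slope[0], tau / np.where(near1, np.inf, q - 1.0))
    tau = np.where(near1, 0.0, tau)  # sum P_i = 1 exactly at q=1
    r2 = np.where(near1, d1_r2[0], r2)
    return ScalingFunctions(q, D, tau, r2, scales)


def chhabra_jensen_spectrum(
    roi: np.ndarray,
    qgrid: np.ndarray | None = None,
    scales=DEFAULT_SCALES_64,
    threshold: float | None = None,
) -> Spectrum:
    """Direct (Chhabra–Jensen) estimate of the singularity spectrum.

    For each moment order q the normalized measures
    ``mu_i(q, L) = P_i(L)**q / sum_i P_i(L)**q`` are formed in the log
    domain; ``alpha(q)`` is the slope of ``sum_i mu_i log P_i`` against
    ``log L`` and ``f(q)`` the slope of ``sum_i mu_i log mu_i`` against
    ``log L``.  Any q whose numerators are non-finite (extreme moments of
    tiny probabilities) is dropped with a warning.
    """
    q = _check_qgrid(default_qgrid() if qgrid is None else qgrid)
    scales = _check_scales(max(np.asarray(roi).shape), scales)
    _, S_alpha, S_f, _ = _moment_curves(roi, q, scales, threshold)
    x = np.log(np.asarray(scales, dtype=float))
    ok = np.isfinite(S_alpha).all(axis=1) & np.isfinite(S_f).all(axis=1)
    if not ok.all():
        import warnings

        warnings.warn(
            f"dropping {int((~ok).sum())} non-finite q values from the direct spectrum",
            stacklevel=2,
        )
    alpha, r2a = _fit_slopes(x, S_alpha[ok])
    f, _ = _fit_slopes(x, S_f[ok])
    return Spectrum(q[ok], alpha, f, r2a, "chhabra_jensen")


def legendre_spectrum(scaling: ScalingFunctions) -> Spectrum:
    """Singularity spectrum via the Legendre transform of tau(q).

    ``alpha(q) = d tau / d q`` by central finite differences (one-sided at
    the grid ends); ``f(alpha(q)) = q alpha(q) - tau(q)``.
    """
    q, tau = scaling.q, scaling.tau_q
    if q.size < 3:
        raise ValueError("need at least 3 q values for the Legendre transform")
    if not np.all(np.isfinite(tau)):
        raise ValueError("tau(q) must be finite on the whole grid")
    alpha = np.gradient(tau, q)
    f = q * alpha - tau
    return Spectrum(q, alpha, f, scaling.fit_r2, "legendre")
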