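"""Two-dimensional multifractal detrended moving average (2D MF-DMA).

The estimator quantifies multifractality of a rough surface without box
partitions: at each analysis scale ``n`` a sliding-window sum of the
field is detrended by a moving-average surface, the residual is cut into
disjoint ``n x n`` segments, and the q-th order overall fluctuation
``F_q(n)`` is formed from the per-segment root-mean-square residuals.
The power law ``F_q(n) ~ n**H(q)`` gives the generalized Hurst exponents,
from which mass exponents ``tau(q) = q H(q) - D_f`` (``D_f = 2`` for an
image support) and, via the Legendre transform, the singularity spectrum
follow.

The moving-average position parameters ``theta1, theta2 in [0, 1]``
select backward (0), centered (0.5) or forward (1) windows; backward is
the default, the standard recommendation for DMA estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .boxcount import ScalingFunctions, Spectrum, default_qgrid, legendre_spectrum

__all__ = [
    "MFDMAConfig",
    "HurstFunction",
    "double_increments",
    "mfdma_fluctuation",
    "mfdma_scaling",
    "mfdma_spectrum",
]

DEFAULT_SCALES_64 = (4, 6, 8, 12, 16)

# segments with squared fluctuation below this are treated as degenerate
_F2_FLOOR = 1e-24


def geometric_scales(side: int, n_min: int = 4, ratio: float = 1.5) -> tuple[int, ...]:
    """Roughly geometric scale ladder from ``n_min`` up to ``side // 4``."""
    out, n = [], float(n_min)
    while int(round(n)) <= side // 4:
        v = int(round(n))
        if not out or v > out[-1]:
            out.append(v)
        n *= ratio
    return tuple(out)


@dataclass(frozen=True)
class MFDMAConfig:
    """Parameters of the 2D MF-DMA estimator (square windows, n1 = n2)."""

    theta1: float = 0.0
    theta2: float = 0.0
    scales: tuple[int, ...] = DEFAULT_SCALES_64
    qgrid: np.ndarray = field(default_factory=default_qgrid)
    min_segments: int = 4
    D_f: float = 2.0

    def __post_init__(self) -> None:
        for th in (self.theta1, self.theta2):
            if not 0.0 <= th <= 1.0:
                raise ValueError("theta parameters must lie in [0, 1]")
        s = tuple(self.scales)
        if any(b <= a for a, b in zip(s, s[1:])) or (s and s[0] < 4):
            raise ValueError("scales must be strictly increasing and >= 4")


@dataclass(frozen=True)
class HurstFunction:
    """Generalized Hurst exponents H(q) and mass exponents tau(q)."""

    q: np.ndarray
    H_q: np.ndarray
    tau_q: np.ndarray
    D_f: float
    fit_r2: np.ndarray
    scales: tuple[int, ...]


def _sliding_parts(X: np.ndarray, n: int, theta1: float, theta2: float):
    """Window-sum surface Y, moving-average surface Ytilde, and valid slices.

    The analysis window at position (i1, i2) spans the ``n`` rows
    ``[i1 - (n-1) + s1, i1 + s1]`` with forward offset
    ``s = floor((n-1) * theta)`` (and likewise for columns), so theta = 0
    is a backward window, 0.5 centered, 1 forward.  Y is the plain window
    sum; Ytilde averages the in-window cumulative sums, which weights the
    window element at in-window index (d1, d2) (0-based from the oldest
    corner) by ``(n - d1)(n - d2) / n^2``.
    """
    N1, N2 = X.shape
    s1 = int(np.floor((n - 1) * theta1))
    s2 = int(np.floor((n - 1) * theta2))
    ones = np.ones(n)
    tri = np.arange(n, 0, -1).astype(float)  # weights n, n-1, ..., 1

    def filt(img, w, axis, shift):
        # output[i] = sum_j w[j] * img[i - (n-1) + shift + j] along `axis`:
        # the window [i-(n-1)+shift, i+shift] with w[0] at the oldest element
        origin = (n - 1) // 2 - shift
        return correlate1d(img, w, axis=axis, mode="constant", origin=origin)

    Y = filt(filt(X, ones, 0, s1), ones, 1, s2)
    Yt = filt(filt(X, tri, 0, s1), tri, 1, s2) / (n * n)
    # valid rows: window fully inside [0, N-1]
    r0, r1 = (n - 1) - s1, N1 - 1 - s1
    c0, c1 = (n - 1) - s2, N2 - 1 - s2
    return Y[r0 : r1 + 1, c0 : c1 + 1], Yt[r0 : r1 + 1, c0 : c1 + 1]


def double_increments(X: np.ndarray) -> np.ndarray:
    """Second mixed difference of a surface: the field whose 2D cumulative
    sum recovers ``X``.

    MF-DMA integrates its input through window sums, so a *smooth surface*
    (e.g. fractional Brownian motion with Hurst exponent H) must be handed
    over as its increment field for the estimated H(q) to sit on the
    generator's H scale; measure-like fields (cascades, intensity images)
    are analyzed as-is.  See the methods note for the calibration.
    """
    X = np.asarray(X, dtype=float)
    return np.diff(np.diff(X, axis=0), axis=1)


def segment_fluctuations(X: np.ndarray, n: int, config: MFDMAConfig) -> np.ndarray:
    """Per-segment squared RMS residuals F^2_{v1,v2} at scale n.

    Returns the 2D array of segment mean squared residuals after
    moving-average detrending; raises if the surface is degenerate
    (all residuals identically zero, e.g. a constant input).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be a 2D array")
    if n < 4:
        raise ValueError("scale n must be >= 4")
    if min(X.shape) < 4 * n:
        raise ValueError(f"image side {min(X.shape)} must be >= 4*n = {4*n}")
    Y, Yt = _sliding_parts(X, n, config.theta1, config.theta2)
    eps = Y - Yt
    # a constant surface leaves a spatially constant residual: nothing to
    # analyze, and the fluctuation law would be a pure artifact of n
    if np.ptp(eps) <= 1e-12 * max(1.0, np.abs(eps).max()):
        raise ValueError("degenerate surface: detrended residual has no variation")
    m1, m2 = eps.shape[0] // n, eps.shape[1] // n
    if m1 < 1 or m2 < 1:
        raise ValueError("no complete segment at this scale")
    F2 = (
        eps[: m1 * n, : m2 * n].reshape(m1, n, m2, n).swapaxes(1, 2).reshape(m1, m2, n * n) ** 2
    ).mean(axis=2)
    if np.all(F2 < _F2_FLOOR):
        raise ValueError("degenerate surface: all detrended fluctuations are zero")
    return F2


def mfdma_fluctuation(X: np.ndarray, n: int, config: MFDMAConfig | None = None) -> np.ndarray:
    """q-th order overall fluctuation F_q(n) on the config's q grid.

    For q != 0 this is ``{ mean_v F_v^q }**(1/q)`` over the segment RMS
    fluctuations ``F_v``; the q = 0 entry uses the logarithmic limit
    ``exp( (1/2) * mean_v log F_v^2 )``.  Segments with vanishing
    fluctuation are dropped (they would be singular for q < 0) with a
    warning.
    """
    config = config or MFDMAConfig()
    q = np.asarray(config.qgrid, dtype=float)
    F2 = segment_fluctuations(X, n, config).ravel()
    keep = F2 > _F2_FLOOR
    if not keep.all():
        warnings.warn(
            f"scale {n}: dropping {int((~keep).sum())}/{F2.size} zero-fluctuation segments",
            stacklevel=2,
        )
        F2 = F2[keep]
    logF = 0.5 * np.log(F2)
    out = np.empty(q.size)
    zero = np.isclose(q, 0.0, atol=1e-12)
    nz = ~zero
    qe = q[nz]
    # log-domain power mean for numerical safety at large |q|
    from scipy.special import logsumexp

    out[nz] = np.exp((logsumexp(qe[:, None] * logF[None, :], axis=1) - np.log(logF.size)) / qe)
    out[zero] = np.exp(logF.mean())
    return out


def mfdma_scaling(X: np.ndarray, config: MFDMAConfig | None = None) -> HurstFunction:
    """Generalized Hurst exponents from the power law F_q(n) ~ n**H(q).

    ``H(q)`` is the per-q least-squares slope of ``log F_q(n)`` against
    ``log n`` over the configured scales; ``tau(q) = q H(q) - D_f``.
    Scales where more than 10% of segments are degenerate are discarded;
    at least 3 scales must survive.
    """
    config = config or MFDMAConfig()
    q = np.asarray(config.qgrid, dtype=float)
    used, curves = [], []
    for n in config.scales:
        F2 = segment_fluctuations(X, n, config).ravel()
        bad = F2 <= _F2_FLOOR
        if bad.mean() > 0.10:
            warnings.warn(f"discarding scale {n}: >10% degenerate segments", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves.append(np.log(mfdma_fluctuation(X, n, config)))
        used.append(n)
    if len(used) < 3:
        raise ValueError(f"only {len(used)} usable scales; need >= 3 for the scaling fit")
    Ylog = np.column_stack(curves)  # (nq, n_scales)
    x = np.log(np.asarray(used, dtype=float))
    from .boxcount import _fit_slopes

    H, r2 = _fit_slopes(x, Ylog)
    tau = q * H - config.D_f
    return HurstFunction(q, H, tau, config.D_f, r2, tuple(used))


def mfdma_spectrum(X: np.ndarray, config: MFDMAConfig | None = None) -> Spectrum:
    """Singularity spectrum of a surface via MF-DMA and the Legendre transform."""
    config = config or MFDMAConfig()
    hf = mfdma_scaling(X, config)
    sf = ScalingFunctions(hf.q, np.full_like(hf.q, np.nan), hf.tau_q, hf.fit_r2, hf.scales)
    spec = legendre_spectrum(sf)
    return Spectrum(spec.q, spec.alpha_q, spec.f_q, spec.fit_r2, "mfdma")
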