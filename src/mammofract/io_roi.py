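"""Image and annotation ingestion, breast-field cropping, ROI extraction.

Coordinates are 0-based ``(row, col)`` with row 0 at the top; ROI
windows are half-open, so a window of even size ``s`` centered at
``(r, c)`` covers rows ``[r - s//2, r + s//2)`` and columns likewise
(the center is the pixel at index ``s//2`` of the window).

Annotations are a plain CSV with header
``image_id,center_row,center_col,label`` where label is ``abnormal`` or
``normal``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrayImage",
    "Annotation",
    "ROI",
    "load_grayscale",
    "crop_breast_field",
    "extract_roi",
    "sample_normal_centers",
    "read_annotations",
    "write_roi_tiles",
]

LABELS = ("abnormal", "normal")

# rejection-sampling attempt cap for normal-center placement
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class GrayImage:
    """2D gray-intensity field in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("GrayImage needs a non-empty 2D array")
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("GrayImage intensities must be finite and in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Annotation:
    """A labeled lesion (or sampled-normal) center in image coordinates."""

    image_id: str
    center: tuple[int, int]  # (row, col), 0-based
    label: Literal["abnormal", "normal"]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class ROI:
    """A square window cut from a source image."""

    pixels: np.ndarray
    source_id: str
    center: tuple[int, int]
    label: Literal["abnormal", "normal"]

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def load_grayscale(path: str | Path, format: str = "auto") -> np.ndarray:
    """Read a single-frame grayscale image, rescaled to [0, 1].

    Intensities are divided by the container's stated full-scale value
    (DICOM ``BitsStored``; the dtype's maximum for PNG/TIFF).  Color or
    multi-frame inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {".dcm": "dicom", ".dicom": "dicom", ".png": "png", ".tif": "tiff", ".tiff": "tiff"}.get(
            suffix
        )
        if fmt is None:
            raise ValueError(f"cannot infer image format from suffix {suffix!r}")
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise ValueError("multi-frame DICOM unsupported")
        if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
            raise ValueError("color input unsupported")
        arr = ds.pixel_array.astype(float)
        full_scale = 2 ** int(ds.BitsStored) - 1
    elif fmt in ("png", "tiff"):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            raise ValueError("color input unsupported")
        if arr.ndim != 2:
            raise ValueError("multi-frame input unsupported")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"unsupported pixel dtype {arr.dtype}")
        full_scale = np.iinfo(arr.dtype).max
        arr = arr.astype(float)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return arr / full_scale


def crop_breast_field(
    img: np.ndarray | GrayImage, bg_threshold: float = 0.0
) -> tuple[np.ndarray, tuple[int, int]]:
    """Remove empty border rows/columns (every pixel <= ``bg_threshold``).

    Returns the minimal sub-image containing all tissue and the (row,
    col) offset mapping cropped coordinates back to the original image.
    Idempotent: cropping a cropped image is the identity.
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("expected a non-empty 2D array")
    keep_rows = np.nonzero((pixels > bg_threshold).any(axis=1))[0]
    keep_cols = np.nonzero((pixels > bg_threshold).any(axis=0))[0]
    if keep_rows.size == 0:
        raise ValueError("no breast field found: entire image is at background level")
    r0, r1 = keep_rows[0], keep_rows[-1] + 1
    c0, c1 = keep_cols[0], keep_cols[-1] + 1
    return pixels[r0:r1, c0:c1], (int(r0), int(c0))


def extract_roi(
    img: np.ndarray | GrayImage,
    center: tuple[int, int],
    size: int = 64,
    source_id: str = "",
    label: Literal["abnormal", "normal"] = "normal",
) -> ROI:
    """Cut the half-open ``size`` window centered at ``center``.

    The window covers rows ``[row - size//2, row + size//2)`` and columns
    likewise; it must fit entirely inside the image (no clamping).
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if size < 2 or size % 2:
        raise ValueError("size must be an even positive integer")
    r, c = int(center[0]), int(center[1])
    h = size // 2
    r0, r1, c0, c1 = r - h, r + h, c - h, c + h
    if r0 < 0 or c0 < 0 or r1 > pixels.shape[0] or c1 > pixels.shape[1]:
        raise ValueError(
            f"ROI window rows [{r0},{r1}) cols [{c0},{c1}) crosses the border of "
            f"a {pixels.shape[0]}x{pixels.shape[1]} image"
        )
    return ROI(pixels[r0:r1, c0:c1].copy(), source_id, (r, c), label)


def sample_normal_centers(
    img: np.ndarray | GrayImage,
    annotations: Sequence[Annotation],
    n: int,
    size: int = 64,
    min_dist: float = 64.0,
    min_tissue_frac: float = 0.75,
    bg_threshold: float = 0.0,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Randomly place ``n`` normal-ROI centers away from all annotations.

    Each accepted center yields an in-bounds window whose fraction of
    pixels above ``bg_threshold`` is at least ``min_tissue_frac``, whose
    Chebyshev distance to every abnormal annotation center is at least
    ``min_dist``, and whose window does not overlap previously accepted
    windows.  Rejection sampling is capped at ``MAX_PLACEMENT_ATTEMPTS``;
    running out raises an error stating how many centers were placed.
    Deterministic for a fixed seed.
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)
    if n == 0:
        return []
    h = size // 2
    H, W = pixels.shape
    if H < size or W < size:
        raise ValueError(f"image {H}x{W} cannot host a {size}x{size} ROI")
    abnormal = [a.center for a in annotations if a.label == "abnormal"]
    rng = np.random.default_rng(seed)
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"placed only {len(placed)} of {n} normal centers after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts; relax the constraints"
            )
        attempts += 1
        r = int(rng.integers(h, H - h + 1))
        c = int(rng.integers(h, W - h + 1))
        if any(max(abs(r - ar), abs(c - ac)) < min_dist for ar, ac in abnormal):
            continue
        # nonoverlap with already accepted windows (Chebyshev < size overlaps)
        if any(max(abs(r - pr), abs(c - pc)) < size for pr, pc in placed):
            continue
        window = pixels[r - h : r + h, c - h : c + h]
        if (window > bg_threshold).mean() < min_tissue_frac:
            continue
        placed.append((r, c))
    return placed


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read the annotation CSV (image_id, center_row, center_col, label)."""
    df = pd.read_csv(path)
    required = {"image_id", "center_row", "center_col", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV is missing columns {sorted(missing)}")
    return [
        Annotation(str(t.image_id), (int(t.center_row), int(t.center_col)), str(t.label))
        for t in df.itertuples()
    ]


def write_roi_tiles(rois: Sequence[ROI], out_dir: str | Path) -> Path:
    """Write ROIs as 16-bit PNG tiles plus a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, roi in enumerate(rois):
        name = f"roi_{i:05d}.png"
        iio.imwrite(out / name, np.round(np.clip(roi.pixels, 0, 1) * 65535).astype(np.uint16))
        rows.append(
            {
                "image_id": roi.source_id or name,
                "file": name,
                "center_row": roi.center[0],
                "center_col": roi.center[1],
                "label": roi.label,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
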