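"""Image, contour, mask and manifest I/O with shared channel conventions.

Conventions used throughout the package:

* arrays are indexed ``[row, col]`` (0-based, origin top-left); all contour
  points are stored as ``(x, y)`` = ``(col, row)``;
* images are converted to ``float64`` in ``[0, 1]`` at load time and carry a
  fixed channel order ``(red, green, blue)``;
* SLO (scanning laser ophthalmoscope) images have only red and green optical
  channels — any blue content found in the file is zeroed with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.measure import find_contours

log = logging.getLogger(__name__)

CHANNEL_NAMES = ("red", "green", "blue")

# BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class ChannelError(ValueError):
    """Raised when an image does not have the expected colour channels."""


class DegenerateInputError(ValueError):
    """Raised when an operation receives a constant (zero-range) input."""


class AnnotationParseError(ValueError):
    """Raised when a contour CSV cannot be parsed; carries the line number."""


@dataclass
class RetinalImage:
    """An optic-disc-bearing retinal image.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Floating-point raster in ``[0, 1]``, channel order (red, green, blue).
    modality : str
        ``"fundus"`` or ``"slo"``.
    """

    pixels: np.ndarray
    modality: str = "fundus"
    channels: tuple = CHANNEL_NAMES

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ChannelError(
                f"expected an H x W x 3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64 x 64 pixels")
        self.modality = self.modality.lower()
        if self.modality not in ("fundus", "slo"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "slo" and np.any(px[:, :, 2] != 0):
            warnings.warn("SLO image has nonzero blue channel; zeroing it")
            px = px.copy()
            px[:, :, 2] = 0.0
        self.pixels = px

    @property
    def shape(self):
        return self.pixels.shape[:2]

    @property
    def red(self):
        return self.pixels[:, :, 0]

    @property
    def green(self):
        return self.pixels[:, :, 1]

    @property
    def blue(self):
        return self.pixels[:, :, 2]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, CHANNEL_NAMES.index(name)]


@dataclass
class AnnotationSet:
    """Clinical annotations attached to one image.

    ``disc`` and ``cup`` are ordered closed contours as (N, 2) ``(x, y)``
    arrays (first point implicitly joined to the last).
    """

    disc: np.ndarray | None = None
    cup: np.ndarray | None = None
    vertical_cdr: float | None = None
    horizontal_cdr: float | None = None
    label: str | None = None


def load_image(path, modality: str = "fundus") -> RetinalImage:
    """Read a PNG/TIFF/JPEG file into a :class:`RetinalImage`.

    Grayscale files are rejected (the pipeline needs at least red and green).
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raise ChannelError(f"{path} is single-channel; need colour channels")
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.shape[2] == 2:  # two-channel (red, green) file
        rgb = np.zeros(raw.shape[:2] + (3,), dtype=raw.dtype)
        rgb[:, :, :2] = raw
        raw = rgb
    if raw.shape[2] != 3:
        raise ChannelError(f"{path}: unsupported channel count {raw.shape[2]}")
    px = raw.astype(float)
    if raw.dtype == np.uint8:
        px /= 255.0
    elif raw.dtype == np.uint16:
        px /= 65535.0
    return RetinalImage(px, modality=modality)


def save_image(img: RetinalImage, path) -> None:
    """Write a :class:`RetinalImage` as an 8-bit PNG/TIFF."""
    arr = np.clip(img.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def to_luma(img: RetinalImage, rescale: bool = True) -> np.ndarray:
    """BT.601 luma Y = 0.299 R + 0.587 G + 0.114 B, optionally min-max
    rescaled to span [0, 1].  A constant luma map is returned unchanged
    (there is nothing to rescale)."""
    y = img.pixels @ _LUMA
    if rescale:
        try:
            y = minmax_normalize(y)
        except DegenerateInputError:
            pass
    return y


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affinely map ``values`` onto [0, 1] (min -> 0, max -> 1).

    Raises
    ------
    DegenerateInputError
        If the input is constant.
    """
    values = np.asarray(values, dtype=float)
    lo = values.min()
    hi = values.max()
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("non-finite values in map")
    if hi == lo:
        raise DegenerateInputError("constant map cannot be min-max normalised")
    return (values - lo) / (hi - lo)


def minmax_or_zeros(values: np.ndarray) -> np.ndarray:
    """Min-max normalise, falling back to an all-zero map on constant input."""
    try:
        return minmax_normalize(values)
    except DegenerateInputError:
        return np.zeros_like(np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# contours and masks
# ---------------------------------------------------------------------------

def read_contour_csv(path) -> np.ndarray:
    """Read an (x, y) contour CSV (header ``x,y``) into an (N, 2) array."""
    path = Path(path)
    pts = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().replace(" ", "").startswith("x,y"):
            raise AnnotationParseError(f"{path}:1: expected header 'x,y'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: cannot parse row {line!r}"
                ) from exc
            pts.append((x, y))
    contour = np.asarray(pts, dtype=float)
    if len(contour) >= 2 and np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]  # closure is implicit
    return contour


def write_contour_csv(contour: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(contour), columns=["x", "y"]).to_csv(
        path, index=False
    )


def read_annotation(path, label: str | None = None) -> AnnotationSet:
    """Load an annotation: a contour CSV or an 8-bit binary mask PNG."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return AnnotationSet(disc=read_contour_csv(path), label=label)
    mask = read_mask(path)
    return AnnotationSet(disc=mask_to_contour(mask), label=label)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def contour_to_mask(contour: np.ndarray, shape) -> np.ndarray:
    """Rasterise a closed (x, y) contour to a filled boolean mask."""
    pts_rc = np.asarray(contour, dtype=float)[:, ::-1]  # (row, col)
    return polygon2mask(shape, pts_rc)


def mask_to_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the boundary of the largest component of a mask as (x, y)."""
    found = find_contours(np.asarray(mask, float), 0.5)
    if not found:
        raise ValueError("mask is empty; no contour to trace")
    longest = max(found, key=len)
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


# ---------------------------------------------------------------------------
# dataset manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "modality", "label", "annotation_path"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
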