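"""Raster image loading, grayscale conversion and ROI extraction.

Dermoscopy photographs enter the pipeline as 8-bit rasters (PNG, TIFF, BMP
or JPEG).  RGB inputs are reduced to a single luminance channel with fixed,
documented weights; square regions of interest (ROIs) are then cropped at
explicit 0-based ``(row, col)`` offsets.  Every object carries provenance
(source identifier, lighting mode, lesion group) so each downstream feature
row is traceable to its source image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: ITU-R luminance weights for RGB -> gray reduction.
LUMINANCE_WEIGHTS = {
    "bt709": (0.2126, 0.7152, 0.0722),
    "bt601": (0.299, 0.587, 0.114),
}

METADATA_COLUMNS = [
    "source_path",
    "source_id",
    "lighting",
    "group_label",
    "roi_row",
    "roi_col",
    "roi_side",
]


class Lighting(str, Enum):
    """Illumination mode of the dermoscopy photograph."""

    POLARIZED = "polarized"
    NONPOLARIZED = "nonpolarized"


class GroupLabel(str, Enum):
    """Histopathological lesion group."""

    BN = "BN"  # benign nevus
    DN = "DN"  # dysplastic nevus
    MM = "MM"  # melanoma
    UNKNOWN = "unknown"


class ImageFormatError(ValueError):
    """Raised for rasters the pipeline cannot represent as 8-bit grayscale."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit grayscale raster with provenance.

    Attributes
    ----------
    pixels
        ``(height, width)`` array of ``uint8`` intensities.
    source_id
        Free-text identifier of the originating photograph.
    lighting
        Illumination mode under which the photograph was taken.
    """

    pixels: np.ndarray
    source_id: str = ""
    lighting: Lighting = Lighting.POLARIZED

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a nonempty 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROI:
    """A square region of interest cropped from a :class:`GrayImage`.

    The window is half-open: ``[row, row+side) x [col, col+side)`` in the
    0-based coordinates of the source image.
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    source_id: str = ""
    lighting: Lighting = Lighting.POLARIZED
    group_label: GroupLabel = GroupLabel.UNKNOWN

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1] or px.size == 0:
            raise ValueError(f"ROI pixels must be square and nonempty, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def rgb_to_gray(rgb: np.ndarray, weights: str = "bt709") -> np.ndarray:
    """Reduce an ``(h, w, 3)`` 8-bit RGB array to grayscale.

    Uses fixed luminance weights with round-half-up so the reduction is
    deterministic and documented (unlike GUI editors' "luminosity" modes).
    """
    w = LUMINANCE_WEIGHTS[weights]
    lum = rgb[..., 0] * w[0] + rgb[..., 1] * w[1] + rgb[..., 2] * w[2]
    return np.floor(lum + 0.5).astype(np.uint8)


def load_image(
    path: str | Path,
    lighting: Lighting | str = Lighting.POLARIZED,
    source_id: str | None = None,
    weights: str = "bt709",
) -> GrayImage:
    """Load a raster file as an 8-bit grayscale :class:`GrayImage`.

    Parameters
    ----------
    path
        PNG, TIFF, BMP or JPEG file.  JPEG is accepted with a warning:
        lossy compression artifacts perturb texture features, so lossless
        formats are recommended.
    lighting
        Illumination mode recorded in the provenance.
    source_id
        Defaults to the file stem.
    weights
        Luminance weight set for RGB reduction, ``"bt709"`` (default) or
        ``"bt601"``.

    Raises
    ------
    OSError
        If the file is missing, unreadable or corrupt.
    ImageFormatError
        For bit depths above 8 bits per channel.
    """
    path = Path(path)
    lighting = Lighting(lighting)
    try:
        with Image.open(path) as im:
            im.load()
            fmt = im.format
            mode = im.mode
            if mode in ("RGBA", "LA", "P"):
                im = im.convert("RGB" if mode in ("RGBA", "P") else "L")
                mode = im.mode
            if mode == "L":
                px = np.asarray(im, dtype=np.uint8)
            elif mode == "RGB":
                px = rgb_to_gray(np.asarray(im, dtype=np.uint8), weights=weights)
            elif mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise ImageFormatError(
                    f"{path}: bit depth above 8 bits per channel is not supported"
                )
            else:
                raise ImageFormatError(f"{path}: unsupported image mode {mode!r}")
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot read raster image {path}: {exc}") from exc
    if fmt == "JPEG":
        warnings.warn(
            f"{path}: JPEG is lossy; compression artifacts perturb texture "
            "features. Prefer PNG/TIFF/BMP.",
            stacklevel=2,
        )
    return GrayImage(px, source_id=source_id if source_id is not None else path.stem,
                     lighting=lighting)


def save_image(image: GrayImage | ROI, path: str | Path) -> None:
    """Write an 8-bit grayscale raster losslessly (format from the suffix)."""
    Image.fromarray(image.pixels, mode="L").save(Path(path))


def extract_roi(
    image: GrayImage,
    origin: tuple[int, int],
    side: int = 450,
    group_label: GroupLabel | str = GroupLabel.UNKNOWN,
) -> ROI:
    """Crop a ``side x side`` window at 0-based ``origin = (row, col)``.

    The returned pixels are an independent copy of the source window.

    Raises
    ------
    ValueError
        If the window does not fit inside the image.
    """
    row, col = int(origin[0]), int(origin[1])
    side = int(side)
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    if row < 0 or col < 0 or row + side > image.height or col + side > image.width:
        raise ValueError(
            f"ROI window origin=({row}, {col}), side={side} exceeds image "
            f"bounds {image.height}x{image.width}"
        )
    window = image.pixels[row : row + side, col : col + side].copy()
    return ROI(
        window,
        origin=(row, col),
        source_id=image.source_id,
        lighting=image.lighting,
        group_label=GroupLabel(group_label),
    )


def grid_rois(image: GrayImage, side: int = 450) -> list[tuple[int, int]]:
    """Origins of a uniform non-overlapping grid of ``side``-square windows.

    Convenience for tiling a lesion photograph when no hand-picked offsets
    are available; returns ``(row, col)`` pairs, row-major.
    """
    rows = range(0, image.height - side + 1, side)
    cols = range(0, image.width - side + 1, side)
    return [(r, c) for r in rows for c in cols]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read an ROI metadata table (CSV).

    Expected columns: ``source_path, source_id, lighting, group_label,
    roi_row, roi_col, roi_side``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV {path} is missing columns: {missing}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    """Write an ROI metadata table as CSV in the canonical column order."""
    df.loc[:, METADATA_COLUMNS].to_csv(path, index=False)


def iter_rois(metadata: pd.DataFrame, root: str | Path = ".") -> Iterator[ROI]:
    """Yield ROIs described by a metadata table, loading each source image.

    Relative ``source_path`` entries are resolved against ``root``.
    """
    root = Path(root)
    for rec in metadata.itertuples(index=False):
        src = Path(rec.source_path)
        if not src.is_absolute():
            src = root / src
        img = load_image(src, lighting=rec.lighting, source_id=rec.source_id)
        yield extract_roi(
            img,
            (int(rec.roi_row), int(rec.roi_col)),
            int(rec.roi_side),
            group_label=rec.group_label,
        )
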