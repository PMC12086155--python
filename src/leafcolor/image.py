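"""Image front end: decoding, palette reduction, vegetation segmentation.

Images are held as ``(height, width, 3)`` uint8 numpy arrays (row-major,
origin top-left).  Segmentation masks are boolean arrays of the same height
and width, True on vegetation.

The analysis emulates a workflow in which canopy JPEGs are reduced to a
256-color GIF palette before per-color pixel counting; palette reduction
uses median-cut with dithering disabled, because dithering would scatter
spurious colors through the histogram.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import ConfigError, InputError
from .histogram import ColorHistogram

SEGMENTATION_MODES = ("black-background", "excess-green")

#: Default luminance cutoff (on the 0-255 Rec.601 luma scale) separating a
#: dark studio background from leaf material.
DEFAULT_LUMINANCE_THRESHOLD = 20.0

#: Default excess-green (2G - R - B) cutoff for scenes with soil and pots.
DEFAULT_EXCESS_GREEN_THRESHOLD = 20.0


def read_image(path: str | Path) -> np.ndarray:
    """Decode a raster image to an 8-bit RGB pixel grid.

    Grayscale, palette and RGBA sources are converted to RGB; alpha is
    discarded.  Raises :class:`InputError` for unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            rgb = im.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc


def write_image(grid: np.ndarray, path: str | Path) -> None:
    """Write a pixel grid as PNG/JPEG/GIF according to the path suffix."""
    Image.fromarray(_check_grid(grid), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an externally produced vegetation mask (nonzero = vegetation)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode mask {path}: {exc}") from exc
    return arr > 0


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 3 or grid.shape[2] != 3:
        raise InputError(f"expected (h, w, 3) RGB grid, got shape {grid.shape}")
    if grid.shape[0] == 0 or grid.shape[1] == 0:
        raise InputError("empty image")
    return grid.astype(np.uint8, copy=False)


def count_distinct_colors(grid: np.ndarray) -> int:
    grid = _check_grid(grid)
    flat = grid.reshape(-1, 3).astype(np.int64)
    codes = flat[:, 0] * 65536 + flat[:, 1] * 256 + flat[:, 2]
    return int(np.unique(codes).size)


def quantize_palette(grid: np.ndarray, max_colors: int = 256) -> np.ndarray:
    """Reduce a grid to at most ``max_colors`` distinct colors (GIF-style).

    Median-cut without dithering.  If the input already fits the palette
    budget it is returned bit-identically, so lossless round-trips through
    GIF-style reduction leave the color histogram untouched.
    """
    grid = _check_grid(grid)
    if max_colors < 2:
        raise ConfigError(f"max_colors must be >= 2, got {max_colors}")
    if count_distinct_colors(grid) <= max_colors:
        return grid.copy()
    im = Image.fromarray(grid, mode="RGB")
    pal = im.quantize(
        colors=max_colors,
        method=Image.Quantize.MEDIANCUT,
        dither=Image.Dither.NONE,
    )
    out = np.asarray(pal.convert("RGB"), dtype=np.uint8)
    return out


def segment_vegetation(
    grid: np.ndarray,
    mode: str = "black-background",
    threshold: float | None = None,
) -> np.ndarray:
    """Boolean vegetation mask for a canopy photo.

    ``black-background``: vegetation iff Rec.601 luma exceeds ``threshold``
    (plants photographed on a black cloth).  ``excess-green``: vegetation iff
    2G - R - B exceeds ``threshold`` (plants among soil and pots).  Supplying
    a precomputed mask file through the pipeline bypasses this function.
    """
    grid = _check_grid(grid).astype(np.float64)
    if mode == "black-background":
        if threshold is None:
            threshold = DEFAULT_LUMINANCE_THRESHOLD
        luma = 0.299 * grid[..., 0] + 0.587 * grid[..., 1] + 0.114 * grid[..., 2]
        return luma > threshold
    if mode == "excess-green":
        if threshold is None:
            threshold = DEFAULT_EXCESS_GREEN_THRESHOLD
        exg = 2.0 * grid[..., 1] - grid[..., 0] - grid[..., 2]
        return exg > threshold
    raise ConfigError(
        f"unknown segmentation mode {mode!r}; expected one of {SEGMENTATION_MODES}"
    )


def build_histogram(grid: np.ndarray, mask: np.ndarray | None = None) -> ColorHistogram:
    """Tally the masked pixels of a grid into a :class:`ColorHistogram`."""
    grid = _check_grid(grid)
    if mask is None:
        mask = np.ones(grid.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape[:2]:
        raise InputError(
            f"mask shape {mask.shape} does not match image shape {grid.shape[:2]}"
        )
    return ColorHistogram.from_pixels(grid[mask])


def crop_tiles(
    grid: np.ndarray, boxes: list[tuple[int, int, int, int]]
) -> list[np.ndarray]:
    """Cut per-plant tiles out of a multi-plant photo.

    Boxes are (left, top, right, bottom) in pixel coordinates, right/bottom
    exclusive.  Used when several plants share one photo and per-plant color
    statistics are wanted.
    """
    grid = _check_grid(grid)
    h, w = grid.shape[:2]
    tiles = []
    for left, top, right, bottom in boxes:
        if not (0 <= left < right <= w and 0 <= top < bottom <= h):
            raise InputError(
                f"tile box {(left, top, right, bottom)} outside image {w}x{h}"
            )
        tiles.append(grid[top:bottom, left:right].copy())
    return tiles
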