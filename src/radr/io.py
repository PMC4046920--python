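"""Image input/output, tile-grid mosaics and tissue-mask derivation.

Whole organs are imaged as single 16-bit grayscale TIFF frames or as a grid
of tiles acquired in row-major order by an automated stage; tiles are abutted
(no overlap or registration) into one mosaic before counting. Tissue area —
the denominator of every foci frequency — comes from a binary tissue mask,
either supplied by the user or derived automatically from the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology, transform

__all__ = [
    "Raster",
    "TileGrid",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "compile_mosaic",
    "load_manifest",
    "derive_tissue_mask",
    "pixel_area_cm2",
]


def pixel_area_cm2(pixel_size_um: float) -> float:
    """Area of one pixel in cm². All px→cm² conversions go through here."""
    return (pixel_size_um * 1e-4) ** 2


@dataclass
class Raster:
    """A 2-D 16-bit intensity image with a physical pixel size.

    ``pixels`` is row-major, indexed 0-based as (row, col).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected single-channel 2-D image, got shape {px.shape}")
        if px.dtype != np.uint16:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 65535:
                px = px.astype(np.uint16)
            else:
                raise ValueError(
                    f"expected unsigned 16-bit pixels, got dtype {px.dtype}"
                )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_cm2(self, mask: Optional[np.ndarray] = None) -> float:
        n = int(mask.sum()) if mask is not None else self.pixels.size
        return n * pixel_area_cm2(self.pixel_size_um)


@dataclass
class TileGrid:
    """Tiles of one organ in row-major acquisition order."""

    tiles: list[Raster]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols != len(self.tiles):
            raise ValueError("n_rows * n_cols must equal the tile count")
        shapes = {t.shape for t in self.tiles}
        if len(shapes) > 1:
            raise ValueError(f"tiles have mismatched shapes: {sorted(shapes)}")
        sizes = {t.pixel_size_um for t in self.tiles}
        if len(sizes) > 1:
            raise ValueError("tiles have mismatched pixel sizes")


def write_image(raster: Raster, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF; pixel size stored in the description tag."""
    desc = json.dumps({"pixel_size_um": raster.pixel_size_um})
    tifffile.imwrite(str(path), raster.pixels, description=desc)


def read_image(path: str | Path, pixel_size_um: Optional[float] = None) -> Raster:
    """Read a grayscale TIFF into a :class:`Raster`.

    The pixel size is taken from the TIFF description written by
    :func:`write_image` unless overridden by ``pixel_size_um``. Raises on
    multi-channel or >16-bit input, naming the offending property.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim != 2:
        raise ValueError(
            f"expected single-channel grayscale image, got shape {arr.shape}"
        )
    if arr.dtype.itemsize > 2 or np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"expected <=16-bit integer pixels, got dtype {arr.dtype}")
    if pixel_size_um is None:
        try:
            pixel_size_um = float(json.loads(desc)["pixel_size_um"])
        except Exception:
            raise ValueError(
                f"{path}: no pixel size metadata; pass pixel_size_um explicitly"
            ) from None
    return Raster(arr.astype(np.uint16), pixel_size_um)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(str(path), (mask.astype(bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel mask, got shape {arr.shape}")
    return arr > 0


def compile_mosaic(grid: TileGrid) -> Raster:
    """Abut tiles on the grid (row-major, no overlap) into one Raster."""
    th, tw = grid.tiles[0].shape
    out = np.zeros((grid.n_rows * th, grid.n_cols * tw), dtype=np.uint16)
    for i, tile in enumerate(grid.tiles):
        r, c = divmod(i, grid.n_cols)
        out[r * th : (r + 1) * th, c * tw : (c + 1) * tw] = tile.pixels
    return Raster(out, grid.tiles[0].pixel_size_um)


def load_manifest(path: str | Path) -> TileGrid:
    """Load a tile grid from a JSON manifest.

    Schema: ``{"pixel_size_um": float, "n_rows": int, "n_cols": int,
    "tiles": [paths, row-major]}``; tile paths are relative to the manifest.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    tiles = [
        read_image(path.parent / p, pixel_size_um=spec.get("pixel_size_um"))
        for p in spec["tiles"]
    ]
    return TileGrid(tiles, int(spec["n_rows"]), int(spec["n_cols"]))


def derive_tissue_mask(
    raster: Raster,
    median_radius: int = 15,
    close_radius: int = 5,
    downsample: int = 4,
) -> np.ndarray:
    """Segment tissue from the dark slide background.

    Replaces manual outline tracing: heavy median smoothing, Otsu threshold,
    morphological closing, hole filling, and retention of the largest
    connected component. Smoothing and thresholding run on a
    ``downsample``-fold reduced image (the tissue outline is a very
    low-frequency structure) and the mask is upsampled back.

    Raises ``ValueError`` on an image with no foreground/background
    contrast, advising a user-supplied mask.
    """
    img = raster.pixels.astype(float)
    if downsample > 1:
        small = transform.downscale_local_mean(img, (downsample, downsample))
        mr = max(1, round(median_radius / downsample))
        cr = max(1, round(close_radius / downsample))
    else:
        small, mr, cr = img, median_radius, close_radius

    smooth = ndimage.median_filter(small, size=2 * mr + 1, mode="nearest")
    if np.ptp(smooth) == 0:
        raise ValueError(
            "image has no foreground/background contrast; supply a tissue mask"
        )
    thr = filters.threshold_otsu(smooth)
    mask_small = smooth > thr
    if not mask_small.any() or mask_small.all():
        raise ValueError(
            "automatic thresholding found no tissue outline; supply a tissue mask"
        )
    mask_small = morphology.closing(mask_small, morphology.disk(cr))
    mask_small = ndimage.binary_fill_holes(mask_small)

    if downsample > 1:
        mask = np.kron(mask_small, np.ones((downsample, downsample), dtype=bool))
        mask = mask[: img.shape[0], : img.shape[1]]
        if mask.shape != img.shape:  # image not a multiple of the factor
            pad = np.zeros(img.shape, dtype=bool)
            pad[: mask.shape[0], : mask.shape[1]] = mask
            mask = pad
    else:
        mask = mask_small

    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("derived tissue mask is empty; supply a tissue mask")
    return mask
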