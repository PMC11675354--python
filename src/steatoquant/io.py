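"""Reading, writing and assembling two-channel SHG/TPEF slide images.

The imaging convention throughout the package: channel 0 is the SHG
(collagen) channel, channel 1 is the TPEF (autofluorescence) channel.
Pixel coordinates are 0-based ``(row, col)``; physical coordinates refer to
pixel centers. Acquisition tiles are 512 x 512 px covering 200 x 200 um^2,
giving the default pixel pitch of 200/512 um.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage import morphology

#: Pixel edge length (um) implied by the acquisition geometry of a
#: 512 px tile spanning 200 um.
DEFAULT_PIXEL_SIZE_UM: float = 200.0 / 512.0


@dataclass
class SlideImage:
    """A registered pair of SHG and TPEF intensity rasters.

    Intensities are in arbitrary detector units, non-negative and finite.
    Integer input rasters are promoted to float32 so that all downstream
    arithmetic is bit-depth independent.
    """

    shg: np.ndarray
    tpef: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg, dtype=np.float32)
        self.tpef = np.asarray(self.tpef, dtype=np.float32)
        if self.shg.ndim != 2 or self.tpef.ndim != 2:
            raise ValueError("SHG and TPEF rasters must be 2-D")
        if self.shg.shape != self.tpef.shape:
            raise ValueError(
                f"channel shape mismatch: SHG {self.shg.shape} vs "
                f"TPEF {self.tpef.shape}"
            )
        if not (np.isfinite(self.shg).all() and np.isfinite(self.tpef).all()):
            raise ValueError("intensities must be finite")
        if (self.shg < 0).any() or (self.tpef < 0).any():
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    def with_pixel_size(self, pixel_size_um: float) -> "SlideImage":
        """Re-declare the same rasters at a different physical pixel size."""
        return SlideImage(self.shg, self.tpef, pixel_size_um, self.provenance)


@dataclass
class TissueMask:
    """Boolean tissue-foreground raster and its physical area.

    The tissue area is the denominator of every "% area" and "per mm^2"
    readout, so it is computed once here and carried around explicitly.
    """

    mask: np.ndarray
    pixel_size_um: float
    tissue_area_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.tissue_area_mm2 = float(
            self.mask.sum() * self.pixel_size_um**2 * 1e-6
        )


def _pixel_size_from_tags(page: "tifffile.TiffPage") -> float | None:
    """Recover pixel size (um) from TIFF resolution tags if present."""
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_value = getattr(unit, "value", None)
    unit_value = getattr(unit_value, "value", unit_value)  # enum -> int
    if unit_value == 3:  # centimeter
        return 1e4 / pixels_per_unit
    if unit_value == 2:  # inch
        return 25400.0 / pixels_per_unit
    return None


def read_slide(
    path: str | os.PathLike,
    tpef_path: str | os.PathLike | None = None,
    pixel_size_um: float | None = None,
) -> SlideImage:
    """Read a 2-channel TIFF (SHG, TPEF) or a pair of single-channel TIFFs.

    Pixel size resolution order: explicit argument, TIFF resolution
    metadata, then the acquisition-geometry default of 200/512 um.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if tpef_path is not None:
        tpef_path = Path(tpef_path)
        if not tpef_path.exists():
            raise FileNotFoundError(tpef_path)
        with tifffile.TiffFile(path) as tf:
            shg = tf.asarray()
            meta_px = _pixel_size_from_tags(tf.pages[0])
        tpef = tifffile.imread(tpef_path)
        if shg.ndim != 2 or tpef.ndim != 2:
            raise ValueError("paired-file mode expects single-channel TIFFs")
        provenance = f"{path}+{tpef_path}"
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_px = _pixel_size_from_tags(tf.pages[0])
        if data.ndim == 3 and data.shape[0] == 2:
            shg, tpef = data[0], data[1]
        elif data.ndim == 3 and data.shape[-1] == 2:
            shg, tpef = data[..., 0], data[..., 1]
        else:
            n = data.shape[0] if data.ndim == 3 else 1
            raise ValueError(f"expected 2 channels, got {n} in {path}")
        provenance = str(path)
    if pixel_size_um is None:
        pixel_size_um = meta_px if meta_px is not None else DEFAULT_PIXEL_SIZE_UM
    return SlideImage(shg, tpef, pixel_size_um, provenance)


def write_slide(path: str | os.PathLike, img: SlideImage) -> None:
    """Write a SlideImage as a 2-channel float32 TIFF with resolution tags."""
    pixels_per_cm = 1e4 / img.pixel_size_um
    data = np.stack([img.shg, img.tpef]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        resolution=(pixels_per_cm, pixels_per_cm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def assemble_tiles(
    tiles: Sequence[SlideImage], grid: tuple[int, int]
) -> SlideImage:
    """Abut tiles (row-major order) into a single mosaic; no blending."""
    rows, cols = grid
    if len(tiles) != rows * cols:
        raise ValueError(
            f"tile count {len(tiles)} does not match grid {rows}x{cols}"
        )
    shape = tiles[0].shape
    px = tiles[0].pixel_size_um
    for t in tiles:
        if t.shape != shape:
            raise ValueError("all tiles must share the same shape")
        if t.pixel_size_um != px:
            raise ValueError("all tiles must share the same pixel size")
    shg = np.block([[tiles[r * cols + c].shg for c in range(cols)] for r in range(rows)])
    tpef = np.block([[tiles[r * cols + c].tpef for c in range(cols)] for r in range(rows)])
    return SlideImage(shg, tpef, px, provenance=f"mosaic {rows}x{cols}")


def split_tiles(img: SlideImage, grid: tuple[int, int]) -> list[SlideImage]:
    """Inverse of :func:`assemble_tiles`: cut a mosaic back into its tiles."""
    rows, cols = grid
    h, w = img.shape
    if h % rows or w % cols:
        raise ValueError(f"image {img.shape} not divisible by grid {grid}")
    th, tw = h // rows, w // cols
    out = []
    for r in range(rows):
        for c in range(cols):
            sl = (slice(r * th, (r + 1) * th), slice(c * tw, (c + 1) * tw))
            out.append(SlideImage(img.shg[sl], img.tpef[sl], img.pixel_size_um))
    return out


def tissue_mask(img: SlideImage, min_object_um2: float = 50.0) -> TissueMask:
    """Segment the tissue foreground from the TPEF channel.

    Foreground = pixels above a global Otsu threshold of the TPEF
    histogram, then morphological closing and hole filling so that
    enclosed dark vacuoles count as tissue; connected components smaller
    than ``min_object_um2`` are dropped.
    """
    from .detect import channel_otsu  # local import to avoid a cycle

    try:
        _, bright = channel_otsu(img.tpef, above=True)
    except ValueError as exc:  # constant channel: nothing to segment
        raise ValueError("no tissue detected") from exc
    closed = morphology.closing(bright, morphology.disk(2))
    filled = ndimage.binary_fill_holes(closed)
    min_px = max(1, int(round(min_object_um2 / img.pixel_size_um**2)))
    cleaned = morphology.remove_small_objects(filled, max_size=min_px - 1)
    if not cleaned.any():
        raise ValueError("no tissue detected")
    return TissueMask(cleaned, img.pixel_size_um)
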