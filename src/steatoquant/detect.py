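"""Vacuole-candidate detection in the TPEF channel.

Lipid droplets leave autofluorescence-free holes in processed tissue, so
candidate detection is a dark-object segmentation: a global Otsu threshold
on the TPEF histogram marks below-threshold pixels, connected components
(8-connectivity, hole-filled) inside the tissue mask become candidates, and
each candidate carries the morphological and collagen features used by the
downstream decision tree.

Thresholds are always computed per image on a 256-bin histogram of the
min--max scaled channel, which makes detection independent of detector bit
depth and of any positive rescaling of the intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation

from .io import SlideImage, TissueMask

N_BINS = 256


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on an intensity histogram.

    Returns the level ``t`` maximizing the between-class variance of the
    split into levels ``<= t`` and ``> t``. Ties are broken by the lowest
    such level.

    Parameters
    ----------
    histogram:
        Counts per intensity level (any length >= 2).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with >= 2 levels")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 occupied levels")
    total = hist.sum()
    p = hist / total
    levels = np.arange(hist.size, dtype=np.float64)
    w0 = np.cumsum(p)
    mu0 = np.cumsum(p * levels)
    mu_t = mu0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    sigma_b[-1] = -np.inf  # a cut after the top level is no split
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) max


def quantize_channel(channel: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Min--max scale a channel onto integer levels 0..n_bins-1."""
    channel = np.asarray(channel, dtype=np.float64)
    lo = channel.min()
    hi = channel.max()
    if hi == lo:
        raise ValueError("degenerate histogram: constant channel")
    q = np.floor((channel - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(q, 0, n_bins - 1)


def channel_otsu(
    channel: np.ndarray, above: bool = False
) -> tuple[int, np.ndarray]:
    """Otsu-split a raw intensity channel.

    Returns ``(level, mask)`` where ``level`` is the Otsu level on the
    256-bin scaled histogram and ``mask`` selects the dark class
    (``<= level``), or the bright class when ``above`` is true.
    """
    q = quantize_channel(channel)
    level = otsu_threshold(np.bincount(q.ravel(), minlength=N_BINS))
    mask = q > level if above else q <= level
    return level, mask


@dataclass
class VacuoleCandidate:
    """One detected hole with the feature vector used for classification.

    ``mask`` is the boolean patch cropped to ``bbox`` (a pair of slices in
    image coordinates). ``solidity`` (area over convex-hull area) serves as
    the compactness/"density" feature; ragged vessel lumens score low,
    smooth droplets near 1.
    """

    id: int
    bbox: tuple[slice, slice]
    mask: np.ndarray
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    area_um2: float
    equivalent_diameter_um: float
    perimeter_um: float
    circularity: float
    length_width_ratio: float
    solidity: float
    mean_tpef_intensity: float
    collagen_annulus_um2: float = 0.0
    collagen_annulus_fraction: float = 0.0
    annulus_clipped: bool = False

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.bbox] = self.mask
        return out


def _annulus_stats(
    mask: np.ndarray,
    bbox: tuple[slice, slice],
    shg_positive: np.ndarray,
    width_px: int,
    pixel_size_um: float,
) -> tuple[float, float, bool]:
    """SHG-positive area and fraction in a fixed-width annulus outside a mask."""
    h, w = shg_positive.shape
    r0 = max(0, bbox[0].start - width_px)
    r1 = min(h, bbox[0].stop + width_px)
    c0 = max(0, bbox[1].start - width_px)
    c1 = min(w, bbox[1].stop + width_px)
    box = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    box[
        bbox[0].start - r0 : bbox[0].stop - r0,
        bbox[1].start - c0 : bbox[1].stop - c0,
    ] = mask
    dist = ndimage.distance_transform_edt(~box)
    annulus = (dist > 0) & (dist <= width_px)
    n_annulus = int(annulus.sum())
    clipped = (
        bbox[0].start - width_px < 0
        or bbox[0].stop + width_px > h
        or bbox[1].start - width_px < 0
        or bbox[1].stop + width_px > w
    )
    if n_annulus == 0:
        return 0.0, 0.0, clipped
    n_pos = int((annulus & shg_positive[r0:r1, c0:c1]).sum())
    area = n_pos * pixel_size_um**2
    return area, n_pos / n_annulus, clipped


def collagen_annulus(
    candidate: VacuoleCandidate,
    shg: np.ndarray,
    pixel_size_um: float,
    annulus_width_um: float = 5.0,
) -> tuple[float, float]:
    """SHG-positive area and fraction in an annulus around one candidate.

    SHG-positive pixels are those above a global Otsu threshold of the SHG
    channel; a constant (e.g. all-zero) SHG channel yields ``(0, 0)``.
    """
    if not annulus_width_um > 0:
        raise ValueError("annulus_width_um must be > 0")
    shg = np.asarray(shg)
    try:
        _, positive = channel_otsu(shg, above=True)
    except ValueError:
        positive = np.zeros(shg.shape, dtype=bool)
    width_px = max(1, int(round(annulus_width_um / pixel_size_um)))
    area, frac, _ = _annulus_stats(
        candidate.mask, candidate.bbox, positive, width_px, pixel_size_um
    )
    return area, frac


def detect_candidates(
    img: SlideImage,
    tissue: TissueMask,
    min_diameter_um: float = 3.0,
    max_diameter_um: float = 200.0,
    annulus_width_um: float = 5.0,
    max_hole_intensity_ratio: float = 0.5,
) -> list[VacuoleCandidate]:
    """Detect all empty-hole candidates and compute their features.

    Candidates are the 8-connected components of below-Otsu TPEF pixels
    inside the tissue mask, hole-filled, with equivalent diameter within
    ``[min_diameter_um, max_diameter_um]``. Components touching the image
    border are excluded because their truncated features would corrupt
    classification.

    True vacuoles contain no fluorophores at all, so the dark class must
    be much darker than the parenchyma: if the mean intensity of
    below-threshold pixels exceeds ``max_hole_intensity_ratio`` times the
    bright-class mean, the Otsu split is only carving texture out of a
    hole-free background and no candidates are returned.
    """
    if not tissue.mask.any():
        raise ValueError("tissue mask is empty")
    px = img.pixel_size_um
    try:
        _, dark = channel_otsu(img.tpef)
    except ValueError:
        return []
    dark_mean = float(img.tpef[dark].mean()) if dark.any() else 0.0
    bright_mean = float(img.tpef[~dark].mean()) if (~dark).any() else 0.0
    if bright_mean > 0 and dark_mean > max_hole_intensity_ratio * bright_mean:
        return []
    dark &= tissue.mask
    dark = ndimage.binary_fill_holes(dark)
    labels = measure.label(dark, connectivity=2)
    labels = segmentation.clear_border(labels)

    try:
        _, shg_positive = channel_otsu(img.shg, above=True)
    except ValueError:
        shg_positive = np.zeros(img.shape, dtype=bool)
    width_px = max(1, int(round(annulus_width_um / px)))

    out: list[VacuoleCandidate] = []
    next_id = 0
    for rp in measure.regionprops(labels, intensity_image=img.tpef):
        area_um2 = rp.area * px**2
        eq_diam = 2.0 * math.sqrt(area_um2 / math.pi)
        if eq_diam < min_diameter_um or eq_diam > max_diameter_um:
            continue
        perim_um = rp.perimeter * px
        circ = 1.0 if perim_um == 0 else min(1.0, 4 * math.pi * area_um2 / perim_um**2)
        minor = max(rp.axis_minor_length, 0.5)  # guard 1-px-thin shapes
        lw = max(1.0, rp.axis_major_length / minor)
        bbox = (slice(rp.bbox[0], rp.bbox[2]), slice(rp.bbox[1], rp.bbox[3]))
        ann_area, ann_frac, clipped = _annulus_stats(
            rp.image, bbox, shg_positive, width_px, px
        )
        cy, cx = rp.centroid
        out.append(
            VacuoleCandidate(
                id=next_id,
                bbox=bbox,
                mask=rp.image,
                centroid_px=(cy, cx),
                centroid_um=(cy * px, cx * px),
                area_um2=area_um2,
                equivalent_diameter_um=eq_diam,
                perimeter_um=perim_um,
                circularity=circ,
                length_width_ratio=lw,
                solidity=rp.solidity,
                mean_tpef_intensity=float(rp.intensity_mean),
                collagen_annulus_um2=ann_area,
                collagen_annulus_fraction=ann_frac,
                annulus_clipped=clipped,
            )
        )
        next_id += 1
    return out


def candidates_to_frame(candidates: list[VacuoleCandidate]):
    """Tabulate candidates (one row each) for CSV export."""
    import pandas as pd

    rows = [
        {
            "id": c.id,
            "centroid_row_um": c.centroid_um[0],
            "centroid_col_um": c.centroid_um[1],
            "area_um2": c.area_um2,
            "equivalent_diameter_um": c.equivalent_diameter_um,
            "perimeter_um": c.perimeter_um,
            "circularity": c.circularity,
            "length_width_ratio": c.length_width_ratio,
            "solidity": c.solidity,
            "mean_tpef_intensity": c.mean_tpef_intensity,
            "collagen_annulus_um2": c.collagen_annulus_um2,
            "collagen_annulus_fraction": c.collagen_annulus_fraction,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows)


def candidates_label_raster(
    candidates: list[VacuoleCandidate], shape: tuple[int, int]
) -> np.ndarray:
    """Label raster with candidate id + 1 at candidate pixels, 0 elsewhere."""
    out = np.zeros(shape, dtype=np.int32)
    for c in candidates:
        patch = out[c.bbox]
        patch[c.mask] = c.id + 1
    return out
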