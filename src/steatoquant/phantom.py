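"""Two-channel phantom slides with full ground truth.

The phantom emulates the image content an unstained SHG/TPEF liver slide
presents to the steatosis pipeline:

* a textured autofluorescent parenchyma background in the TPEF channel
  (low-frequency multiplicative field times additive Gaussian noise);
* fat vacuoles: near-circular dark holes with zero autofluorescence, the
  detection target, diameters drawn from a lognormal law;
* vessel lumens: larger, irregular dark holes; portal-type lumens carry a
  bright SHG collagen ring of configurable thickness, central-vein-type
  lumens do not — exactly the contrast that makes the surrounding-collagen
  feature discriminative;
* nuclei: small dark disks that retain a fraction of the parenchyma signal
  (chromatin is dim, not autofluorescence-free), the main small-object
  confounder;
* sparse thin SHG collagen strands in the background.

Ground truth records every object (class, mask, centroid, diameter,
histological region) plus the tissue mask and a region map built with the
same distance rules as :mod:`steatoquant.regions`, so region recovery is
testable. Identical (spec, seed) produces bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from skimage import draw

from .io import DEFAULT_PIXEL_SIZE_UM, SlideImage
from .regions import RegionMap, assign_region_labels


class PhantomPlacementError(ValueError):
    """Raised when objects cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom slide.

    Defaults describe a 400 x 400 um^2 field (a 2 x 2 mosaic of
    acquisition tiles) with a moderate steatosis burden and the two
    confounder classes at realistic relative abundance: a handful of
    vessels and nuclei an order of magnitude more numerous than droplets
    (roughly one nucleus per hepatocyte against dozens of droplets only in
    severe steatosis).
    """

    shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_fat: int = 50
    fat_diameter_lognormal: tuple[float, float] = (math.log(12.0), 0.4)
    fat_circularity_min: float = 0.97
    n_vessels: int = 5
    vessel_radius_um: tuple[float, float] = (20.0, 40.0)
    collagen_ring_um: float = 6.0
    portal_fraction: float = 0.5
    n_nuclei: int = 200
    nucleus_diameter_um: tuple[float, float] = (4.0, 8.0)
    nucleus_intensity_frac: float = 0.25
    background_mean: float = 150.0
    background_sd: float = 6.0
    noise_sd: float = 10.0
    strand_density_per_mm2: float = 60.0
    annulus_clearance_um: float = 5.0
    region_halo_um: float = 50.0
    perisinusoidal_halo_um: float = 10.0
    seed: int = 0
    max_place_attempts: int = 2000

    def __post_init__(self) -> None:
        if min(self.n_fat, self.n_vessels, self.n_nuclei) < 0:
            raise ValueError("object counts must be >= 0")
        if not self.fat_diameter_lognormal[1] > 0:
            raise ValueError("lognormal sigma must be > 0")
        if not 0.0 <= self.portal_fraction <= 1.0:
            raise ValueError("portal_fraction must be in [0, 1]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.background_mean <= 0 or self.noise_sd < 0:
            raise ValueError("invalid intensity model")


@dataclass
class PhantomObject:
    """One ground-truth object: a fat vacuole, vessel lumen or nucleus."""

    id: int
    cls: str  # "fat" | "vessel" | "nucleus"
    bbox: tuple[slice, slice]
    mask: np.ndarray
    centroid_px: tuple[float, float]
    centroid_um: tuple[float, float]
    diameter_um: float
    region: str = "lobular"
    vessel_type: str | None = None  # "portal_tract" | "central_vein"

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class PhantomTruth:
    """Full ground truth for one phantom slide."""

    objects: list[PhantomObject]
    tissue_mask: np.ndarray
    region_map: RegionMap
    label_raster: np.ndarray
    pixel_size_um: float
    spec: PhantomSpec = field(repr=False, default=None)

    @property
    def fat_objects(self) -> list[PhantomObject]:
        return [o for o in self.objects if o.cls == "fat"]

    @property
    def fat_diameters_um(self) -> np.ndarray:
        return np.array([o.diameter_um for o in self.fat_objects])

    @property
    def tissue_area_mm2(self) -> float:
        return float(self.tissue_mask.sum() * self.pixel_size_um**2 * 1e-6)

    @property
    def fat_area_um2(self) -> float:
        return float(
            sum(o.area_px for o in self.fat_objects) * self.pixel_size_um**2
        )

    @property
    def fat_pct_area(self) -> float:
        return 100.0 * self.fat_area_um2 * 1e-6 / self.tissue_area_mm2


def _axis_ratio_for_circularity(circ_min: float) -> float:
    """Largest ellipse axis ratio whose analytic circularity >= circ_min."""

    def circ(q: float) -> float:
        a, b = math.sqrt(q), 1.0 / math.sqrt(q)
        h = ((a - b) / (a + b)) ** 2
        perim = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        return 4 * math.pi**2 / perim**2  # area = pi * a * b = pi

    if circ(2.0) >= circ_min:
        return 2.0
    return brentq(lambda q: circ(q) - circ_min, 1.0, 2.0)


def _ellipse_mask(
    a_px: float, b_px: float, theta: float
) -> np.ndarray:
    """Boolean mask of a rotated ellipse centered in its own bbox."""
    half = int(math.ceil(max(a_px, b_px))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    u = np.cos(theta) * xx + np.sin(theta) * yy
    v = -np.sin(theta) * xx + np.cos(theta) * yy
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _blob_mask(r0_px: float, rng: np.random.Generator) -> np.ndarray:
    """Irregular vessel-lumen mask: radially perturbed disk."""
    amp2, amp3 = 0.18 * rng.random(), 0.12 * rng.random()
    ph2, ph3 = rng.uniform(0, 2 * math.pi, size=2)
    rmax = r0_px * (1 + amp2 + amp3)
    half = int(math.ceil(rmax)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    radius = r0_px * (
        1 + amp2 * np.sin(2 * theta + ph2) + amp3 * np.sin(3 * theta + ph3)
    )
    return r <= radius


def _pad_mask(mask: np.ndarray, margin_px: int) -> np.ndarray:
    """Grow a mask by margin_px (Euclidean) inside a padded bbox."""
    padded = np.pad(mask, margin_px)
    dist = ndimage.distance_transform_edt(~padded)
    return dist <= margin_px


def _blit_or(target: np.ndarray, patch: np.ndarray, r0: int, c0: int) -> None:
    """OR a patch into target at (r0, c0), clipping at the borders."""
    h, w = target.shape
    ph, pw = patch.shape
    tr0, tc0 = max(0, r0), max(0, c0)
    tr1, tc1 = min(h, r0 + ph), min(w, c0 + pw)
    if tr1 <= tr0 or tc1 <= tc0:
        return
    target[tr0:tr1, tc0:tc1] |= patch[tr0 - r0 : tr1 - r0, tc0 - c0 : tc1 - c0]


class _Placer:
    """Non-overlapping object placement by rejection sampling."""

    def __init__(self, shape: tuple[int, int], attempts: int):
        self.shape = shape
        self.attempts = attempts
        self.occupancy = np.zeros(shape, dtype=bool)
        self.strand_exclusion = np.zeros(shape, dtype=bool)

    def place(
        self,
        mask: np.ndarray,
        rng: np.random.Generator,
        border_px: int,
        margin_px: int,
        strand_margin_px: int,
    ) -> tuple[slice, slice]:
        h, w = self.shape
        mh, mw = mask.shape
        lo_r, hi_r = border_px, h - mh - border_px
        lo_c, hi_c = border_px, w - mw - border_px
        if hi_r < lo_r or hi_c < lo_c:
            raise PhantomPlacementError("object larger than placeable area")
        for _ in range(self.attempts):
            r = int(rng.integers(lo_r, hi_r + 1))
            c = int(rng.integers(lo_c, hi_c + 1))
            sl = (slice(r, r + mh), slice(c, c + mw))
            if not (self.occupancy[sl] & mask).any():
                big = max(margin_px, strand_margin_px)
                dist = ndimage.distance_transform_edt(~np.pad(mask, big))
                off = big - margin_px
                grown = (dist <= margin_px)[
                    off : off + mh + 2 * margin_px, off : off + mw + 2 * margin_px
                ]
                _blit_or(self.occupancy, grown, r - margin_px, c - margin_px)
                _blit_or(
                    self.strand_exclusion,
                    dist <= strand_margin_px,
                    r - big,
                    c - big,
                )
                return sl
        raise PhantomPlacementError(
            "could not place object without overlap; reduce counts or sizes"
        )


def generate_phantom(spec: PhantomSpec) -> tuple[SlideImage, PhantomTruth]:
    """Render one phantom slide and its ground truth.

    The RNG call sequence is fixed (background field, vessels, fat, nuclei,
    strands, channel noise), so identical ``(spec, seed)`` give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    px = spec.pixel_size_um

    # -- background autofluorescence: low-frequency field x mean, plus noise
    field_raw = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=32)
    sd = field_raw.std()
    rel = spec.background_sd / spec.background_mean
    mult = 1.0 + rel * (field_raw / sd if sd > 0 else field_raw)
    tpef = spec.background_mean * np.maximum(mult, 0.2)

    annulus_px = max(1, int(round(spec.annulus_clearance_um / px)))
    ring_px = max(1, int(round(spec.collagen_ring_um / px)))
    placer = _Placer((h, w), spec.max_place_attempts)
    objects: list[PhantomObject] = []
    next_id = 1

    def register(cls, mask, sl, diameter_um, vessel_type=None):
        nonlocal next_id
        ys, xs = np.nonzero(mask)
        cy = sl[0].start + ys.mean()
        cx = sl[1].start + xs.mean()
        obj = PhantomObject(
            id=next_id,
            cls=cls,
            bbox=sl,
            mask=mask,
            centroid_px=(cy, cx),
            centroid_um=(cy * px, cx * px),
            diameter_um=diameter_um,
            vessel_type=vessel_type,
        )
        objects.append(obj)
        next_id += 1
        return obj

    # -- vessels first (largest objects)
    portal_lumens = np.zeros((h, w), dtype=bool)
    central_lumens = np.zeros((h, w), dtype=bool)
    n_portal = int(round(spec.n_vessels * spec.portal_fraction))
    shg_ring = np.zeros((h, w), dtype=bool)
    for i in range(spec.n_vessels):
        r_um = rng.uniform(*spec.vessel_radius_um)
        mask = _blob_mask(r_um / px, rng)
        is_portal = i < n_portal
        margin = ring_px + annulus_px if is_portal else annulus_px
        sl = placer.place(
            mask, rng, border_px=ring_px + annulus_px + 2,
            margin_px=margin + 2, strand_margin_px=margin + annulus_px + 2,
        )
        eq_diam = 2 * math.sqrt(mask.sum() * px**2 / math.pi)
        vtype = "portal_tract" if is_portal else "central_vein"
        register("vessel", mask, sl, eq_diam, vessel_type=vtype)
        tpef[sl][mask] = 0.0
        (portal_lumens if is_portal else central_lumens)[sl] |= mask
        if is_portal:
            ring = _pad_mask(mask, ring_px)
            rsl = (
                slice(sl[0].start - ring_px, sl[0].stop + ring_px),
                slice(sl[1].start - ring_px, sl[1].stop + ring_px),
            )
            ring_crop = ring.copy()
            ring_crop[ring_px:-ring_px, ring_px:-ring_px] &= ~mask
            shg_ring[rsl] |= ring_crop

    # -- fat vacuoles: near-circular ellipses, lognormal diameters;
    # placed largest-first so dense (severe-steatosis) specs stay feasible
    mu_log, sigma_log = spec.fat_diameter_lognormal
    ratio_max = _axis_ratio_for_circularity(spec.fat_circularity_min)
    fat_draws = sorted(
        (
            (
                math.exp(rng.normal(mu_log, sigma_log)),
                rng.uniform(1.0, ratio_max),
                rng.uniform(0, math.pi),
            )
            for _ in range(spec.n_fat)
        ),
        key=lambda t: -t[0],
    )
    for d_um, q, theta in fat_draws:
        a = d_um / 2 / px * math.sqrt(q)
        b = d_um / 2 / px / math.sqrt(q)
        mask = _ellipse_mask(max(a, 1.0), max(b, 1.0), theta)
        sl = placer.place(
            mask, rng, border_px=annulus_px + 2, margin_px=2,
            strand_margin_px=annulus_px + 3,
        )
        register("fat", mask, sl, d_um)
        tpef[sl][mask] = 0.0

    # -- nuclei: small dark disks retaining some signal
    for _ in range(spec.n_nuclei):
        d_um = rng.uniform(*spec.nucleus_diameter_um)
        r_px = max(1.0, d_um / 2 / px)
        mask = _ellipse_mask(r_px, r_px, 0.0)
        sl = placer.place(
            mask, rng, border_px=annulus_px + 2, margin_px=2,
            strand_margin_px=annulus_px + 3,
        )
        register("nucleus", mask, sl, d_um)
        tpef[sl][mask] *= spec.nucleus_intensity_frac

    # -- SHG channel: faint background + strands + portal collagen rings
    shg = np.maximum(rng.normal(2.0, 1.5, size=(h, w)), 0.0)
    area_mm2 = h * w * px**2 * 1e-6
    n_strands = int(round(spec.strand_density_per_mm2 * area_mm2))
    strand_mask = np.zeros((h, w), dtype=bool)
    for _ in range(n_strands):
        for _attempt in range(spec.max_place_attempts):
            r0 = rng.integers(2, h - 2)
            c0 = rng.integers(2, w - 2)
            angle = rng.uniform(0, 2 * math.pi)
            length_px = rng.uniform(30.0, 100.0) / px
            r1 = int(round(r0 + length_px * math.sin(angle)))
            c1 = int(round(c0 + length_px * math.cos(angle)))
            if not (2 <= r1 < h - 2 and 2 <= c1 < w - 2):
                continue
            rr, cc = draw.line(int(r0), int(c0), r1, c1)
            if placer.strand_exclusion[rr, cc].any():
                continue
            for dr in (-1, 0, 1):  # ~1-um-thick strand
                for dc in (-1, 0, 1):
                    strand_mask[rr + dr, cc + dc] = True
            break
    strand_mask &= ~placer.strand_exclusion
    shg[strand_mask] = rng.normal(120.0, 10.0, size=int(strand_mask.sum()))
    shg[shg_ring] = rng.normal(150.0, 15.0, size=int(shg_ring.sum()))
    shg = np.maximum(shg, 0.0)

    # -- final TPEF noise
    tpef = np.maximum(tpef + rng.normal(0, spec.noise_sd, size=(h, w)), 0.0)

    # -- ground truth rasters
    tissue = np.ones((h, w), dtype=bool)
    label_raster = np.zeros((h, w), dtype=np.int32)
    for o in objects:
        patch = label_raster[o.bbox]
        patch[o.mask] = o.id
    region_labels = assign_region_labels(
        tissue, portal_lumens, central_lumens, strand_mask | shg_ring, px,
        halo_um=spec.region_halo_um,
        perisinusoidal_halo_um=spec.perisinusoidal_halo_um,
    )
    region_map = RegionMap.from_labels(region_labels, px)
    for o in objects:
        o.region = region_map.region_of(o.centroid_px)

    img = SlideImage(
        shg.astype(np.float32), tpef.astype(np.float32), px,
        provenance=f"phantom(seed={spec.seed})",
    )
    truth = PhantomTruth(
        objects=objects,
        tissue_mask=tissue,
        region_map=region_map,
        label_raster=label_raster,
        pixel_size_um=px,
        spec=spec,
    )
    return img, truth


def generate_cohort(
    template: PhantomSpec,
    groups: Sequence[Mapping],
    n_per_group: int,
    seed: int = 0,
) -> dict[str, list[tuple[SlideImage, PhantomTruth]]]:
    """Generate a multi-group phantom cohort from a template spec.

    Each group dict may set ``name``, ``n_fat_scale`` (multiplies the fat
    count; > 0) and ``diameter_shift`` (um added to the median droplet
    diameter). Per-sample seeds are spawned deterministically from ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for g in groups:
        if g.get("n_fat_scale", 1.0) <= 0:
            raise ValueError("n_fat_scale must be > 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(groups) * n_per_group)
    out: dict[str, list[tuple[SlideImage, PhantomTruth]]] = {}
    k = 0
    mu_log, sigma_log = template.fat_diameter_lognormal
    for g in groups:
        name = g["name"]
        scale = float(g.get("n_fat_scale", 1.0))
        shift = float(g.get("diameter_shift", 0.0))
        mu = math.log(math.exp(mu_log) + shift)
        samples = []
        for _ in range(n_per_group):
            child_seed = int(children[k].generate_state(1)[0] & 0x7FFFFFFF)
            k += 1
            spec = dataclasses.replace(
                template,
                seed=child_seed,
                n_fat=int(round(template.n_fat * scale)),
                fat_diameter_lognormal=(mu, sigma_log),
            )
            samples.append(generate_phantom(spec))
        out[name] = samples
    return out
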