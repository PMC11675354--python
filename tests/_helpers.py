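"""Small constructors shared between test modules."""

import math

import numpy as np

import steatoquant as sq
from steatoquant.detect import VacuoleCandidate
from steatoquant.regions import LOBULAR, RegionMap


def fake_vacuole(diameter_um, centroid_px=(10.0, 10.0), vid=0):
    """A minimal fat-vacuole candidate with exact analytic geometry."""
    area = math.pi * diameter_um**2 / 4
    return VacuoleCandidate(
        id=vid,
        bbox=(slice(0, 1), slice(0, 1)),
        mask=np.ones((1, 1), dtype=bool),
        centroid_px=centroid_px,
        centroid_um=centroid_px,
        area_um2=area,
        equivalent_diameter_um=diameter_um,
        perimeter_um=math.pi * diameter_um,
        circularity=1.0,
        length_width_ratio=1.0,
        solidity=1.0,
        mean_tpef_intensity=0.0,
    )


def lobular_setup(size=100, px=10.0):
    """size*px um square of tissue, all lobular (1 mm^2 at defaults)."""
    tissue = sq.TissueMask(np.ones((size, size), dtype=bool), px)
    labels = np.full((size, size), LOBULAR, dtype=np.int8)
    return tissue, RegionMap.from_labels(labels, px)
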