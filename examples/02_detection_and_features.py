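"""Detect vacuole candidates and look at their discriminating features.

Candidates are dark holes in the TPEF channel (global Otsu threshold,
8-connected components inside the tissue mask). Each carries the features
the classifier uses: interior intensity, area, circularity, solidity,
length-to-width ratio and the fraction of SHG-positive collagen in a 5 um
annulus around it.
"""

import numpy as np

import steatoquant as sq

img, truth = sq.generate_phantom(sq.PhantomSpec(seed=2))
tissue = sq.tissue_mask(img)
candidates = sq.detect_candidates(img, tissue)
labels = sq.make_training_set(candidates, truth).labels  # truth labels

print(f"tissue area: {tissue.tissue_area_mm2:.3f} mm^2")
print(f"candidates detected: {len(candidates)}")
for cls in ("fat", "non_fat"):
    sel = [c for c, l in zip(candidates, labels) if l == cls]
    diam = np.array([c.equivalent_diameter_um for c in sel])
    coll = np.array([c.collagen_annulus_fraction for c in sel])
    inten = np.array([c.mean_tpef_intensity for c in sel])
    print(
        f"  {cls:8s} n={len(sel):3d}  median diameter {np.median(diam):5.1f} um"
        f"  median collagen fraction {np.median(coll):.3f}"
        f"  median interior intensity {np.median(inten):6.1f}"
    )

# Fat vacuoles are near-zero inside (no fluorophores) with little
# surrounding collagen; nuclei retain some signal and vessels sit in
# collagen — exactly the contrasts the decision tree exploits.
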