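# steatoquant

Automated quantification of hepatic steatosis from **unstained** liver
sections imaged with combined second-harmonic generation (SHG, collagen)
and two-photon-excited autofluorescence (TPEF, parenchyma) microscopy.

Steatosis — lipid-droplet accumulation in hepatocytes — is the defining
feature of MASLD/NAFLD, but the conventional readout (Brunt / NASH-CRN
grade 0–3 assigned by a pathologist on stained slides) is semi-quantitative
and reader-dependent. In TPEF images, fat vacuoles contain no fluorophores
and appear as sharply bounded dark holes, which makes them directly
measurable. `steatoquant` implements the full analysis chain for
researchers running preclinical (e.g. mouse-model) steatosis studies:

1. **Detection** — a global Otsu threshold on the TPEF histogram marks all
   dark-hole candidates; 8-connected components inside the tissue mask are
   measured (area *A*, perimeter *P*, circularity 4π*A*/*P*²,
   solidity, length-to-width ratio, interior intensity, equivalent
   diameter 2√(*A*/π), and the SHG-positive collagen fraction in a 5 µm
   annulus).
2. **Classification** — a CART decision tree (Gini impurity, axis-aligned
   splits, no feature normalization required) separates fat vacuoles from
   the confounding holes: vessel lumens (large, irregular, collagen-walled)
   and nuclei (small, dim but not signal-free).
3. **Regions** — each tissue pixel is assigned to one of four histological
   regions (central vein, portal tract, perisinusoidal, lobular) by
   configurable distance rules around called vessels and collagen strands.
4. **Quantification** — a profile of **45 named parameters**
   (9 metrics × 5 contexts: % area, count, count/mm², mean and median
   diameter, macro/micro counts and % areas — overall and per region),
   a Brunt-style grade (cuts at 5 / 33 / 66 % steatotic area) and the
   droplet-diameter distribution per mm².
5. **Statistics** — per-parameter one-way ANOVA across groups, two-sample
   Kolmogorov–Smirnov tests on diameter distributions, and rank/linear
   correlation, at α = 0.05.

Because real SHG/TPEF slides are not freely redistributable, the package
ships a **phantom generator** that renders two-channel slides with full
ground truth (object masks, classes, diameters, regions), used for
validation and as the substrate of all tests.

## Worked example

```python
import numpy as np
import steatoquant as sq

# train a classifier on truth-labeled phantoms
feats, labels = [], []
for seed in (10, 11):
    img, truth = sq.generate_phantom(sq.PhantomSpec(seed=seed))
    cands = sq.detect_candidates(img, sq.tissue_mask(img))
    ts = sq.make_training_set(cands, truth)
    feats.append(ts.features); labels.append(ts.labels)
tree = sq.train_cart(sq.TrainingSet(np.vstack(feats), np.concatenate(labels)))

# quantify a held-out slide
img, truth = sq.generate_phantom(sq.PhantomSpec(seed=12))
result = sq.run_pipeline(img, tree)
print(result.profile["overall_pct_area"], result.profile.grade.grade)
```

Running `python examples/03_train_classify_quantify.py` (which does the
above) prints:

```
true burden    : 5.44 % area
measured       : 5.44 % area (50 fat vacuoles, 312 per mm^2)
steatosis grade: 1 (0 = <5 %, 3 = >66 % steatotic area)
macro / micro  : 15 / 35 (cut at 15 um)
```

i.e. the pipeline recovered the phantom's true 5.44 % steatotic area
exactly, counted all 50 droplets, and graded the slide 1 (the 5–33 % band).
The other examples cover phantom generation, feature inspection and cohort
statistics; each prints its numbers with a line on what they mean.

## Command line

A thin CLI wraps the library for batch use:

```bash
steatoquant simulate --out sim/ --seed 1        # phantom + ground truth
steatoquant detect sim/slide.tif --out cands.csv
steatoquant train --candidates cands.csv --labels labels.csv --out model.json
steatoquant quantify sim/slide.tif --model model.json --out run/
steatoquant compare --profiles profiles.csv --out results.csv
```

Two-channel TIFFs use channel order (SHG, TPEF); paired single-channel
files are accepted via `--shg/--tpef`. Pixel size is taken from an explicit
option, TIFF resolution metadata, or the 200/512 µm tile-geometry default.

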