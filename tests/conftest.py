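"""Shared fixtures: phantoms and trained models reused across test modules."""

import numpy as np
import pytest

import steatoquant as sq
from steatoquant.cart import feature_matrix


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom slide (50 fat, 5 vessels, 200 nuclei)."""
    return sq.generate_phantom(sq.PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def default_tissue(default_phantom):
    img, _ = default_phantom
    return sq.tissue_mask(img)


@pytest.fixture(scope="session")
def default_candidates(default_phantom, default_tissue):
    img, _ = default_phantom
    return sq.detect_candidates(img, default_tissue)


@pytest.fixture(scope="session")
def trained_tree():
    """CART trained on two truth-labeled phantoms (for pipeline tests)."""
    feats, labels = [], []
    for seed in (300, 301):
        img, truth = sq.generate_phantom(sq.PhantomSpec(seed=seed))
        tissue = sq.tissue_mask(img)
        cands = sq.detect_candidates(img, tissue)
        ts = sq.make_training_set(cands, truth)
        feats.append(ts.features)
        labels.append(ts.labels)
    ts = sq.TrainingSet(np.vstack(feats), np.concatenate(labels))
    return sq.train_cart(ts)


def fat_predictions(tree, candidates):
    if not candidates:
        return np.array([])
    return tree.predict(feature_matrix(candidates))
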