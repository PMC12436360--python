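"""Shared fixtures: a small phantom study and one fully trained desk model.

The trained model is expensive (minutes), so it is built once per session
and reused by the end-to-end, localization, and saliency tests.
"""

from __future__ import annotations

import time

import numpy as np
import pytest

from crossrad.model import DESK_ENCODER
from crossrad.phantom import (
    PhantomConfig,
    generate_phantom_dataset,
    split_dataset,
    subsample_negatives,
)
from crossrad.train import DESK_TRAIN, TrainConfig, manifest_samples, predict_scores, train_model

#: Conditions of the desk-scale phantom study: 200 cases at the emulated
#: 18% prevalence, with a strong, clearly visible rim discontinuity.
STUDY_PHANTOMS = PhantomConfig(
    n_samples=200, prevalence=0.18, image_size=64,
    fracture_contrast=0.6, noise_sd=0.02, exact_counts=True, seed=11,
)


def build_study(config: PhantomConfig = STUDY_PHANTOMS, seed: int = 11):
    """Generate -> 7:1:2 stratified split -> 1:1 negative balancing."""
    manifest, samples = generate_phantom_dataset(config)
    manifest = split_dataset(manifest, (7, 1, 2), seed=seed)
    manifest = subsample_negatives(manifest, neg_pos_ratio=1.0, seed=seed)
    return manifest, samples


@pytest.fixture(scope="session")
def phantom_study():
    return build_study()


@pytest.fixture(scope="session")
def desk_pipeline(phantom_study):
    """Full pipeline in all three modes; returns models, scores and timing."""
    manifest, samples = phantom_study
    splits = {
        name: manifest_samples(manifest, samples, name)
        for name in ("train", "tune", "test")
    }
    out = {"splits": splits, "manifest": manifest, "samples": samples}
    t0 = time.time()
    for mode in ("single", "multi", "multi_csl"):
        cfg = TrainConfig(mode=mode, seed=5)
        model, log = train_model(splits["train"], splits["tune"], cfg, DESK_ENCODER)
        scores = predict_scores(model, splits["test"])
        out[mode] = {"model": model, "log": log, "scores": scores}
    out["elapsed"] = time.time() - t0
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
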