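"""Shared fixtures: a synthetic dataset on disk and models trained on it.

The dataset/model fixtures are session-scoped because training the two
networks is the expensive part of the suite; every test that needs a trained
model shares the same run (default configs, fixed seed, easy rendering
regime: no blur, noise or jitter).
"""

from __future__ import annotations

import numpy as np
import pytest

from perioscan import pipeline as pl
from perioscan import segmenter as sg
from perioscan import detector as dt
from perioscan.panorasim import DatasetConfig, SceneConfig, generate_dataset

RECOVERY_SEED = 7


@pytest.fixture(scope="session")
def easy_manifest(tmp_path_factory) -> pl.DatasetManifest:
    """40 clean scenes at the default 512x256 canvas, split 80/20."""
    out = tmp_path_factory.mktemp("easy_dataset")
    cfg = DatasetConfig(out_dir=out, n_images=40, scene=SceneConfig().easy())
    manifest = pl.load_manifest(generate_dataset(cfg, seed=RECOVERY_SEED))
    return pl.split_dataset(manifest, 0.8, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def trained_segmenter(easy_manifest) -> sg.UNetSegmenter:
    cfg = sg.SegmenterConfig(seed=RECOVERY_SEED)
    model = sg.build_segmenter(cfg)
    pairs = pl.segmentation_pairs(easy_manifest, downscale=cfg.downscale)
    model, history = sg.train_segmenter(model, pairs, cfg)
    assert np.isfinite(history).all()
    return model


@pytest.fixture(scope="session")
def trained_detector(easy_manifest) -> dt.YoloDetector:
    cfg = dt.DetectorConfig(seed=RECOVERY_SEED)
    model = dt.build_detector(cfg)
    samples = pl.detection_samples(easy_manifest, keypoint_box_side=cfg.keypoint_box_side)
    model, history = dt.train_detector(model, samples, cfg)
    assert np.isfinite(history).all()
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
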