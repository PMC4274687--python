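"""Shared fixtures: phantoms and their segmentations are expensive, so they
are generated once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from annulustrack import pipeline as pl
from annulustrack.phantom import PhantomConfig, generate_phantom


def init_from_truth(gt, init_diameter: float = 25.0) -> pl.InitConfig:
    """Initialization a user would derive from the recording metadata:
    frame-0 axis and approximate annulus center."""
    return pl.InitConfig(
        lvot_axis=gt.normals[0],
        annulus_center=gt.centers[0],
        init_diameter=init_diameter,
    )


@pytest.fixture(scope="session")
def phantom_default():
    """Default moving, pulsating, speckle phantom."""
    cfg = PhantomConfig()
    seq, gt = generate_phantom(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def phantom_noiseless():
    cfg = PhantomConfig(noise_level=0.0)
    seq, gt = generate_phantom(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def phantom_static():
    """Small static noiseless phantom for stiff-phase tests."""
    cfg = PhantomConfig(
        noise_level=0.0,
        translation_amp=0.0,
        rotation_amp_deg=0.0,
        pulse_amp=0.0,
        n_frames=4,
    )
    seq, gt = generate_phantom(cfg)
    return cfg, seq, gt


@pytest.fixture(scope="session")
def segmented_default(phantom_default):
    cfg, seq, gt = phantom_default
    res = pl.segment(seq, init_from_truth(gt))
    assert res.status == "ok"
    return cfg, gt, res


@pytest.fixture(scope="session")
def segmented_noiseless(phantom_noiseless):
    cfg, seq, gt = phantom_noiseless
    res = pl.segment(seq, init_from_truth(gt))
    assert res.status == "ok"
    return cfg, gt, res
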