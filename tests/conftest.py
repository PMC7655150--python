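"""Shared fixtures.

The expensive artifacts (trained tiny networks, window datasets) are
session-scoped so training happens once per run; all data are generated by
the simulator at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from neovitals.interventionnet import (
    InterventionNet,
    StreamSchedule,
    build_window_dataset,
    from_scratch_fusion_schedule,
    train_interventionnet,
)
from neovitals.skinnet import (
    SkinNet,
    SkinNetConfig,
    from_scratch_schedules,
    train_skinnet,
)
from neovitals.synthetic import SceneConfig, SceneEvent, generate_recording


@pytest.fixture(scope="session")
def skin_train_recording():
    """200 frames (20 s at 10 fps) with an absence stretch for negatives."""
    cfg = SceneConfig(duration=20.0, fps=10.0, rng_seed=5,
                      events=[SceneEvent("absence", 14.0, 19.0)])
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def skin_holdout_recording():
    cfg = SceneConfig(duration=4.0, fps=10.0, rng_seed=11,
                      events=[SceneEvent("absence", 3.0, 4.0)])
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def trained_skinnet(skin_train_recording):
    seq, truth = skin_train_recording
    net = SkinNet(SkinNetConfig(backbone="tiny", input_size=128, seed=0))
    s1, s2 = from_scratch_schedules()
    net.history = train_skinnet(net, seq.frames, truth.masks, truth.presence,
                                s1, s2, rng_seed=0)
    return net


def _window_set(seeds, event=(5.0, 30.0)):
    ctxs, mots, labs = [], [], []
    for s in seeds:
        cfg = SceneConfig(duration=60.0, fps=2.0, rng_seed=s,
                          events=[SceneEvent("occluder", *event)])
        seq, truth = generate_recording(cfg)
        ctx, mot, lab, _ = build_window_dataset(
            seq, truth.masks.astype(np.float32), truth.timeline)
        ctxs.append(ctx); mots.append(mot); labs.append(lab)
    return np.concatenate(ctxs), np.concatenate(mots), np.concatenate(labs)


@pytest.fixture(scope="session")
def window_train_set():
    """~448 labeled windows, roughly balanced, from 8 synthetic recordings."""
    return _window_set(range(100, 108))


@pytest.fixture(scope="session")
def window_holdout_set():
    return _window_set([999], event=(20.0, 45.0))


@pytest.fixture(scope="session")
def trained_interventionnet(window_train_set):
    context, motion, labels = window_train_set
    model = InterventionNet(backbone="tiny", fusion_channels=64, seed=0)
    train_interventionnet(model, context, motion, labels,
                          StreamSchedule(iterations=300),
                          from_scratch_fusion_schedule(300), rng_seed=0)
    return model


@pytest.fixture()
def two_tone_image():
    """Flat disk on a contrasting background with mild sensor noise."""
    rng = np.random.default_rng(0)
    h = w = 40
    yy, xx = np.mgrid[:h, :w]
    disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12 ** 2
    img = np.where(disk[..., None], (200, 150, 130), (40, 50, 60)).astype(float)
    img = np.clip(img + rng.normal(0, 2.0, img.shape), 0, 255).astype(np.uint8)
    return img, disk
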