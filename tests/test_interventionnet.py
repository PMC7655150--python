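"""Window bookkeeping, two-stream architecture contracts and the timeline."""

import numpy as np
import pytest

from neovitals.interventionnet import (
    ActivityTimeline,
    InterventionNet,
    StreamConfig,
    StreamSchedule,
    FusionSchedule,
    WindowConfig,
    _balanced_batches,
    build_context_stream,
    build_flow_stream,
    label_window,
    make_windows,
)
from neovitals.nn.optim import step_decay_lr
from neovitals.videoio import FrameSequence


def _seq(duration_s, fps=20):
    n = int(duration_s * fps)
    return FrameSequence(np.zeros((n, 8, 8, 3), np.uint8), fps=fps)


class TestWindows:
    def test_sixty_second_recording_yields_56_windows(self):
        assert len(make_windows(_seq(60), WindowConfig())) == 56

    def test_each_window_has_six_frames(self):
        for w in make_windows(_seq(20), WindowConfig()):
            assert len(w.frame_indices) == 6

    def test_one_second_frame_spacing(self):
        w = make_windows(_seq(20), WindowConfig())[3]
        assert np.array_equal(np.diff(w.frame_indices), [20] * 5)

    def test_boundary_five_second_recording(self):
        assert len(make_windows(_seq(5), WindowConfig())) == 1

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            make_windows(_seq(4), WindowConfig())

    def test_coverage_bookkeeping(self):
        # every non-edge second is covered by exactly T/tau windows
        cfg = WindowConfig()
        windows = make_windows(_seq(60), cfg)
        cover = np.zeros(60)
        for w in windows:
            cover[int(w.start_time): int(w.start_time + cfg.T)] += 1
        assert cover.sum() == len(windows) * cfg.T
        assert np.all(cover[int(cfg.T) - 1: -int(cfg.T)] == cfg.T / cfg.tau)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            WindowConfig(T=1.0, tau=2.0)
        with pytest.raises(ValueError):
            WindowConfig(frames_per_window=5)


class TestLabelWindow:
    def test_strict_majority(self):
        s = np.array(["intervention"] * 3 + ["valid"] * 2, dtype=object)
        assert label_window(s, WindowConfig()) == "intervention"

    def test_exact_half_is_non_intervention(self):
        s = np.array(["intervention"] * 2 + ["valid"] * 2, dtype=object)
        assert label_window(s, WindowConfig()) == "non-intervention"

    def test_all_quiet(self):
        s = np.array(["valid"] * 5, dtype=object)
        assert label_window(s, WindowConfig()) == "non-intervention"

    def test_absence_excluded(self):
        s = np.array(["absent"] + ["valid"] * 4, dtype=object)
        with pytest.raises(ValueError):
            label_window(s, WindowConfig())


class TestStreams:
    def test_context_stream_takes_six_channels(self):
        net = build_context_stream()
        y = net.forward(np.zeros((1, 6, 64, 64), np.float32))
        assert y.ndim == 4 and y.shape[1] == net.out_channels  # features, no scores

    def test_flow_stream_channel_counts(self):
        net = build_flow_stream()
        y = net.forward(np.zeros((2, 10, 64, 64), np.float32))
        assert y.shape[:2] == (2, net.out_channels)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 9, 64, 64), np.float32))
        with pytest.raises(ValueError):
            build_flow_stream(StreamConfig(in_channels=9))

    def test_replicate_average_initialization(self):
        # 6 copies of the mean over 3 channels: new kernel channel-sums are
        # 2x the original sums
        rng_cfg = StreamConfig(backbone="tiny", in_channels=6, seed=3)
        from neovitals import nn
        from neovitals.interventionnet import _extend_first_conv
        ref = nn.Conv2d(3, 8, 3, stride=2, rng=np.random.default_rng(3))
        conv = nn.Conv2d(3, 8, 3, stride=2, rng=np.random.default_rng(3))
        _extend_first_conv(conv, 6)
        assert conv.W.shape[1] == 6
        assert np.allclose(conv.W.sum(axis=1), 2 * ref.W.sum(axis=1), atol=1e-5)

    def test_all_zero_motion_finite(self):
        net = build_flow_stream()
        y = net.forward(np.zeros((1, 10, 32, 32), np.float32))
        assert np.all(np.isfinite(y))

    def test_resnet50_stream_builds_and_forwards(self):
        net = build_context_stream(StreamConfig(backbone="resnet50", in_channels=6))
        y = net.forward(np.zeros((1, 6, 64, 64), np.float32))
        assert y.shape[1] == 2048  # headless feature map
        assert y.shape[2] > 1     # global pooling removed


class TestFusion:
    def test_fusion_conv_has_512_outputs_by_default(self):
        model = InterventionNet(backbone="tiny")
        assert model.fuse.W.shape[0] == 512
        # concatenation doubles the channel count ahead of fusion
        assert model.fuse.W.shape[1] == model.ctx.out_channels + model.mot.out_channels

    def test_probabilities_sum_to_one(self):
        model = InterventionNet(backbone="tiny", fusion_channels=16)
        rng = np.random.default_rng(0)
        p = model.forward(rng.random((3, 6, 32, 32)), rng.random((3, 10, 32, 32)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_constant_features_reduce_to_linear_map(self):
        # with spatially constant inputs, pooling commutes with the 1x1
        # fusion conv: the logits equal the classifier applied to the
        # fused constant vector
        model = InterventionNet(backbone="tiny", fusion_channels=16)
        ctx = np.full((1, 6, 32, 32), 0.25, np.float32)
        mot = np.full((1, 10, 32, 32), -3.0, np.float32)
        p = model.forward(ctx, mot)
        cctx, cmot = model._center(ctx, mot)
        fc_feat = model.ctx.forward(cctx)
        fm_feat = model.mot.forward(cmot)
        feats = np.concatenate([fc_feat, fm_feat], axis=1).mean(axis=(2, 3))
        # interior of the feature maps is constant; pool+conv == conv+pool
        fused = model.fuse.W[:, :, 0, 0] @ feats[0] + model.fuse.b
        logits = model.fc.W @ fused + model.fc.b
        from neovitals.nn import softmax
        assert np.allclose(p[0], softmax(logits[None], axis=1)[0], atol=1e-3)


class TestTrainingSchedules:
    def test_stream_lr_drops_tenfold_at_12000(self):
        s = StreamSchedule()
        assert step_decay_lr(s.lr_start, 11_999, s.decay_every) == pytest.approx(1e-3)
        assert step_decay_lr(s.lr_start, 12_000, s.decay_every) == pytest.approx(1e-4)

    def test_published_stage_hyperparameters(self):
        s1, s2 = StreamSchedule(), FusionSchedule()
        assert (s1.batch_size, s1.momentum) == (24, 0.90)
        assert (s2.batch_size, s2.lr_start, s2.decay_every) == (12, 1e-5, 6000)

    def test_balanced_batches(self):
        labels = np.array([0] * 90 + [1] * 10)
        rng = np.random.default_rng(0)
        for batch in _balanced_batches(labels, 24, 5, rng):
            assert (labels[batch] == 1).sum() == 12
        with pytest.raises(ValueError):
            list(_balanced_batches(np.zeros(5, int), 4, 1, rng))

    def test_fusion_stage_freezes_streams(self, window_train_set):
        from neovitals.interventionnet import train_interventionnet, from_scratch_fusion_schedule
        context, motion, labels = window_train_set
        model = InterventionNet(backbone="tiny", fusion_channels=8, seed=9)
        before = [w.copy() for w, _ in model.ctx.parameters() + model.mot.parameters()]
        train_interventionnet(model, context[:40], motion[:40], labels[:40],
                              StreamSchedule(iterations=0),
                              from_scratch_fusion_schedule(5), rng_seed=0)
        after = [w for w, _ in model.ctx.parameters() + model.mot.parameters()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)


def test_channel_order_matters_downstream(trained_interventionnet, window_holdout_set):
    """The (u1,v1,...,u5,v5) stack order is part of the contract: permuting
    the motion channels of a trained model changes its predictions.

    (An untrained model is channel-permutation symmetric by construction:
    replicate-average initialization gives every input channel the same
    kernel; training breaks that symmetry.)
    """
    context, motion, _ = window_holdout_set
    model = trained_interventionnet
    p = model.forward(context[:8], motion[:8])
    p2 = model.forward(context[:8], motion[:8, ::-1].copy())
    assert not np.allclose(p, p2, atol=1e-4)


class TestPredictTimeline:
    def test_states_partition_and_follow_events(self, trained_skinnet,
                                                trained_interventionnet):
        from neovitals.interventionnet import predict_timeline
        from neovitals.synthetic import SceneConfig, SceneEvent, generate_recording
        cfg = SceneConfig(duration=60.0, fps=2.0, rng_seed=77,
                          events=[SceneEvent("occluder", 20.0, 30.0),
                                  SceneEvent("absence", 40.0, 50.0)])
        seq, truth = generate_recording(cfg)
        tl = predict_timeline(seq, trained_skinnet, trained_interventionnet)
        assert len(tl.states) == 60  # one state per second, no gaps
        # absence is recovered exactly and never labeled intervention
        absent_true = truth.timeline.states == "absent"
        assert np.array_equal(tl.states == "absent", absent_true)
        # a contiguous intervention block overlapping the occluder within
        # one window length at each boundary
        pred_int = np.flatnonzero(tl.states == "intervention")
        assert len(pred_int) > 0
        assert np.all(np.diff(pred_int) == 1)
        assert 20 - 5 <= pred_int[0] <= 20 + 5
        assert 30 - 5 <= pred_int[-1] + 1 <= 30 + 5
        # quiet seconds are valid
        assert np.all(tl.states[:15] == "valid")


class TestTimeline:
    def test_states_validated(self):
        with pytest.raises(ValueError):
            ActivityTimeline(np.array(["valid", "bogus"], dtype=object))

    def test_state_lookup_and_span(self):
        tl = ActivityTimeline(np.array(["valid", "absent", "intervention"], dtype=object))
        assert tl.duration == 3.0
        assert list(tl.state_at(np.array([0.2, 1.9, 2.0]))) == [
            "valid", "absent", "intervention"]
        with pytest.raises(ValueError):
            tl.state_at(3.5)

    def test_csv_roundtrip(self, tmp_path):
        tl = ActivityTimeline(np.array(["valid"] * 3 + ["absent"] * 2, dtype=object))
        tl.to_csv(tmp_path / "t.csv")
        back = ActivityTimeline.from_csv(tmp_path / "t.csv")
        assert np.array_equal(back.states, tl.states)
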