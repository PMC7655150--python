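"""Sliding-window two-stream clinical-intervention detector.

A 5 s window stepped by 1 s yields 6 frames (one per second). Two
convolutional streams process the window: a context stream over the 6
stacked skin-confidence maps, and a motion stream over the 10 stacked
encoded optical-flow components (5 pairs x u,v). Their final feature maps
are concatenated, fused by a 1x1 convolution (512 outputs by default),
globally average-pooled and classified into intervention /
non-intervention. Per-second states come from averaging the scores of all
windows covering each second, with patient absence (from the detection
network) taking precedence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import resize as _sk_resize

from . import nn
from .nn.functional import softmax
from .nn.optim import SGD, step_decay_lr
from .flow import window_flow_stack

STATES = ("absent", "intervention", "valid")


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

@dataclass
class ActivityTimeline:
    """Per-second state in {absent, intervention, valid}; states partition
    the covered time span."""

    states: np.ndarray  # array of strings, one per second
    start_time: float = 0.0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=object)
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown states {bad}")

    @property
    def duration(self) -> float:
        return float(len(self.states))

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """State of the second containing each time t."""
        idx = np.floor(np.asarray(t, dtype=float) - self.start_time).astype(int)
        if np.any(idx < 0) or np.any(idx >= len(self.states)):
            raise ValueError("time outside the timeline span")
        return self.states[idx]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["second", "state"])
            for i, s in enumerate(self.states):
                w.writerow([int(self.start_time) + i, s])

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityTimeline":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        rows.sort(key=lambda r: int(r["second"]))
        return cls(np.array([r["state"] for r in rows], dtype=object),
                   start_time=float(rows[0]["second"]))


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

@dataclass
class WindowConfig:
    T: float = 5.0       # window length, s
    tau: float = 1.0     # step, s
    frames_per_window: int = 6
    input_size: int = 64  # spatial size fed to the streams

    def __post_init__(self):
        if not self.T >= self.tau > 0:
            raise ValueError("need T >= tau > 0")
        if self.frames_per_window != int(self.T) + 1:
            raise ValueError("frames_per_window must be T + 1 at 1 fps sampling")


@dataclass
class WindowSample:
    """One sliding-window sample; stacks may be filled lazily."""

    start_time: float
    frame_indices: np.ndarray
    context: np.ndarray | None = None  # (6, H, W) confidence stack
    motion: np.ndarray | None = None   # (10, H, W) decoded-flow stack
    label: str | None = None           # intervention | non-intervention


def make_windows(seq, cfg: WindowConfig) -> list[WindowSample]:
    """Unscored windows at starts 0, tau, 2*tau, ... sampling 6 frames at
    1 s spacing; count = floor((duration - T)/tau) + 1."""
    duration = seq.duration
    if duration < cfg.T:
        raise ValueError(f"recording ({duration:.1f} s) shorter than the window ({cfg.T} s)")
    n = int(np.floor((duration - cfg.T) / cfg.tau)) + 1
    windows = []
    n_frames = len(seq.frames)
    for k in range(n):
        start = k * cfg.tau
        idx = np.minimum(
            np.round((start + np.arange(cfg.frames_per_window)) * seq.fps).astype(int),
            n_frames - 1,
        )
        windows.append(WindowSample(start_time=start, frame_indices=idx))
    return windows


def label_window(per_second_states: np.ndarray, cfg: WindowConfig) -> str:
    """Strict-majority rule: intervention iff more than half the window's
    labeled time is intervention. Windows touching absence are excluded."""
    states = np.asarray(per_second_states, dtype=object)
    if np.any(states == "absent"):
        raise ValueError("window overlapping absence is excluded, not labeled")
    frac = (states == "intervention").sum() / len(states)
    return "intervention" if frac > 0.5 else "non-intervention"


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

@dataclass
class StreamConfig:
    backbone: str = "tiny"  # tiny | resnet50
    in_channels: int = 6
    seed: int = 0


def _extend_first_conv(conv: nn.Conv2d, in_channels: int) -> None:
    """Cross-modality input: replace the 3-channel kernels by their spatial
    average over the input-channel axis replicated across ``in_channels``."""
    mean_k = conv.W.mean(axis=1, keepdims=True)  # (C_out, 1, k, k)
    conv.W = np.repeat(mean_k, in_channels, axis=1).astype(np.float32)
    conv.dW = np.zeros_like(conv.W)
    conv.c_in = in_channels


class _Bottleneck:
    """ResNet bottleneck: 1x1 -> 3x3 -> 1x1 with a (possibly projected)
    shortcut and post-addition ReLU."""

    def __init__(self, c_in, c_mid, c_out, stride, rng):
        self.body = nn.Sequential(
            nn.Conv2d(c_in, c_mid, 1, stride=stride, pad=0, rng=rng),
            nn.BatchNorm2d(c_mid), nn.ReLU(),
            nn.Conv2d(c_mid, c_mid, 3, rng=rng),
            nn.BatchNorm2d(c_mid), nn.ReLU(),
            nn.Conv2d(c_mid, c_out, 1, pad=0, rng=rng),
            nn.BatchNorm2d(c_out),
        )
        if stride != 1 or c_in != c_out:
            self.shortcut = nn.Sequential(
                nn.Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng),
                nn.BatchNorm2d(c_out),
            )
        else:
            self.shortcut = None
        self.relu = nn.ReLU()

    def parameters(self):
        ps = self.body.parameters()
        if self.shortcut is not None:
            ps = ps + self.shortcut.parameters()
        return ps

    def forward(self, x, train=False):
        y = self.body.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return self.relu.forward(y + s, train=train)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        dx = self.body.backward(dy)
        if self.shortcut is None:
            return dx + dy
        return dx + self.shortcut.backward(dy)


def build_stream(cfg: StreamConfig) -> nn.Sequential:
    """Headless feature extractor accepting ``cfg.in_channels`` input planes.

    The first convolution is built for 3 channels and then extended by
    replicate-averaging, mirroring how a pretrained RGB backbone is adapted
    to confidence/flow stacks; the classification head (global pooling +
    fully connected) is deliberately absent.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.backbone == "tiny":
        first = nn.Conv2d(3, 8, 3, stride=2, rng=rng)
        _extend_first_conv(first, cfg.in_channels)
        net = nn.Sequential(
            first, nn.BatchNorm2d(8), nn.ReLU(),
            nn.Conv2d(8, 16, 3, stride=2, rng=rng), nn.BatchNorm2d(16), nn.ReLU(),
            nn.Conv2d(16, 32, 3, stride=2, rng=rng), nn.BatchNorm2d(32), nn.ReLU(),
        )
        net.out_channels = 32
        return net
    if cfg.backbone == "resnet50":
        first = nn.Conv2d(3, 64, 7, stride=2, pad=3, rng=rng)
        _extend_first_conv(first, cfg.in_channels)
        layers = [first, nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d()]
        c_in = 64
        for c_mid, c_out, blocks, stride in (
            (64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)
        ):
            for b in range(blocks):
                layers.append(_Bottleneck(c_in, c_mid, c_out, stride if b == 0 else 1, rng))
                c_in = c_out
        net = nn.Sequential(*layers)
        net.out_channels = 2048
        return net
    raise ValueError(f"unknown backbone {cfg.backbone!r}")


def build_context_stream(cfg: StreamConfig | None = None) -> nn.Sequential:
    cfg = cfg or StreamConfig(in_channels=6)
    if cfg.in_channels != 6:
        raise ValueError("the context stream takes 6 stacked confidence maps")
    return build_stream(cfg)


def build_flow_stream(cfg: StreamConfig | None = None) -> nn.Sequential:
    cfg = cfg or StreamConfig(in_channels=10)
    if cfg.in_channels != 10:
        raise ValueError("the flow stream takes 10 stacked flow components")
    return build_stream(cfg)


# ---------------------------------------------------------------------------
# Fusion model
# ---------------------------------------------------------------------------

@dataclass
class InterventionScore:
    p_intervention: float
    p_non_intervention: float


class InterventionNet:
    """Two streams, 1x1 fusion convolution, global pooling, 2-way classifier."""

    def __init__(self, backbone: str = "tiny", fusion_channels: int = 512, seed: int = 0):
        self.backbone = backbone
        self.ctx = build_context_stream(StreamConfig(backbone, 6, seed))
        self.mot = build_flow_stream(StreamConfig(backbone, 10, seed + 1))
        rng = np.random.default_rng(seed + 2)
        c = self.ctx.out_channels + self.mot.out_channels
        self.fuse = nn.Conv2d(c, fusion_channels, 1, pad=0, rng=rng)
        self.pool = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(fusion_channels, 2, rng=rng)
        self.input_means: np.ndarray | None = None  # (16,) per-channel means
        self.streams_trained = False

    def fusion_parameters(self):
        return self.fuse.parameters() + self.fc.parameters()

    def _center(self, ctx, mot):
        x = np.concatenate([ctx, mot], axis=1).astype(np.float32)
        if self.input_means is not None:
            x = x - self.input_means[None, :, None, None]
        return x[:, :6], x[:, 6:]

    def forward(self, ctx, mot, train=False):
        """Class probabilities (N, 2) as (p_non_intervention, p_intervention)."""
        ctx, mot = self._center(np.asarray(ctx), np.asarray(mot))
        fc_feat = self.ctx.forward(ctx, train=train)
        fm_feat = self.mot.forward(mot, train=train)
        if fc_feat.shape[2:] != fm_feat.shape[2:]:
            raise ValueError("stream feature maps must share a spatial grid")
        fused = self.fuse.forward(np.concatenate([fc_feat, fm_feat], axis=1), train=train)
        logits = self.fc.forward(self.pool.forward(fused), train=train)
        self._n_stream_channels = (fc_feat.shape[1], fm_feat.shape[1])
        return softmax(logits, axis=1)

    def backward_fusion(self, d_logits):
        """Backward through the fusion layers only (stage-2 training)."""
        d = self.fuse.backward(self.pool.backward(self.fc.backward(d_logits)))
        return d

    def score_window(self, sample: WindowSample) -> InterventionScore:
        p = self.forward(sample.context[None], sample.motion[None])[0]
        return InterventionScore(p_intervention=float(p[1]), p_non_intervention=float(p[0]))

    # -- persistence --------------------------------------------------------
    def _state_arrays(self) -> list[np.ndarray]:
        def walk(layer):
            if isinstance(layer, nn.Sequential):
                for sub in layer.layers:
                    yield from walk(sub)
            elif isinstance(layer, _Bottleneck):
                yield from walk(layer.body)
                if layer.shortcut is not None:
                    yield from walk(layer.shortcut)
            else:
                for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    if hasattr(layer, attr):
                        yield getattr(layer, attr)

        arrays = []
        for part in (self.ctx, self.mot, self.fuse, self.fc):
            arrays.extend(walk(part))
        return arrays

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {f"arr_{i}": a for i, a in enumerate(self._state_arrays())}
        if self.input_means is not None:
            state["input_means"] = self.input_means
        np.savez(path, **state)
        meta = {"backbone": self.backbone,
                "fusion_channels": int(self.fc.W.shape[1]),
                "streams_trained": bool(self.streams_trained)}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "InterventionNet":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        model = cls(backbone=meta["backbone"], fusion_channels=meta["fusion_channels"])
        data = np.load(path if path.suffix else path.with_suffix(".npz"))
        for i, arr in enumerate(model._state_arrays()):
            arr[...] = data[f"arr_{i}"]
        if "input_means" in data:
            model.input_means = data["input_means"]
        model.streams_trained = meta.get("streams_trained", False)
        return model


def _balanced_batches(labels: np.ndarray, batch_size: int, iterations: int,
                      rng: np.random.Generator):
    """Yield index batches sampled uniformly across the two classes."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("balanced sampling needs both classes")
    half = batch_size // 2
    for _ in range(iterations):
        yield np.concatenate([
            rng.choice(pos, size=half, replace=True),
            rng.choice(neg, size=batch_size - half, replace=True),
        ])


def _class_grad(probs: np.ndarray, labels: np.ndarray):
    n = len(probs)
    p_true = probs[np.arange(n), labels]
    loss = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    return loss, ((probs - onehot) / n).astype(np.float32)


@dataclass
class StreamSchedule:
    lr_start: float = 1e-3
    decay_every: int = 12_000  # iterations per tenfold drop
    momentum: float = 0.90
    batch_size: int = 24
    iterations: int = 12_000


@dataclass
class FusionSchedule:
    lr_start: float = 1e-5
    decay_every: int = 6_000
    momentum: float = 0.90
    batch_size: int = 12
    iterations: int = 6_000


def from_scratch_fusion_schedule(iterations: int = 300) -> FusionSchedule:
    """Fusion schedule for randomly initialized fusion layers.

    The published 1e-5 rate fine-tunes layers sitting on pretrained
    streams; a fresh 1x1 fusion convolution and classifier need a rate
    comparable to stage 1 to converge in a short desk-scale run.
    """
    return FusionSchedule(lr_start=1e-3, iterations=iterations)


def train_interventionnet(
    model: InterventionNet,
    context: np.ndarray,   # (N, 6, H, W)
    motion: np.ndarray,    # (N, 10, H, W)
    labels: np.ndarray,    # 1 = intervention, 0 = non-intervention
    stream_schedule: StreamSchedule | None = None,
    fusion_schedule: FusionSchedule | None = None,
    rng_seed: int = 0,
) -> dict:
    """Two-stage training with balanced class sampling.

    Stage 1 trains each stream individually under a temporary global-pool +
    fully-connected head (all stream weights updated); stage 2 trains only
    the fusion layers added after concatenation.
    """
    s1 = stream_schedule or StreamSchedule()
    s2 = fusion_schedule or FusionSchedule()
    context = np.asarray(context, dtype=np.float32)
    motion = np.asarray(motion, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    model.input_means = np.concatenate([
        context.mean(axis=(0, 2, 3)), motion.mean(axis=(0, 2, 3))
    ]).astype(np.float32)
    cen = np.concatenate([context, motion], axis=1) - model.input_means[None, :, None, None]
    ctx_c, mot_c = cen[:, :6], cen[:, 6:]
    rng = np.random.default_rng(rng_seed)
    history: dict = {}

    for name, stream, data in (("context", model.ctx, ctx_c), ("flow", model.mot, mot_c)):
        head_pool = nn.GlobalAvgPool2d()
        head_fc = nn.Linear(stream.out_channels, 2, rng=np.random.default_rng(rng_seed + 7))
        params = stream.parameters() + head_fc.parameters()
        opt = SGD(params, lr=s1.lr_start, momentum=s1.momentum)
        losses = []
        for it, sel in enumerate(_balanced_batches(labels, s1.batch_size, s1.iterations, rng)):
            opt.lr = step_decay_lr(s1.lr_start, it, s1.decay_every)
            feats = stream.forward(data[sel], train=True)
            probs = softmax(head_fc.forward(head_pool.forward(feats)), axis=1)
            loss, dlog = _class_grad(probs, labels[sel])
            stream.backward(head_pool.backward(head_fc.backward(dlog)))
            opt.step()
            opt.zero_grad()
            losses.append(loss)
        history[f"stage1_{name}"] = losses
    model.streams_trained = True

    opt = SGD(model.fusion_parameters(), lr=s2.lr_start, momentum=s2.momentum)
    losses = []
    for it, sel in enumerate(_balanced_batches(labels, s2.batch_size, s2.iterations, rng)):
        opt.lr = step_decay_lr(s2.lr_start, it, s2.decay_every)
        probs = model.forward(context[sel], motion[sel], train=True)
        loss, dlog = _class_grad(probs, labels[sel])
        model.backward_fusion(dlog)
        opt.step()
        opt.zero_grad()
        losses.append(loss)
    history["stage2_fusion"] = losses
    return history


def build_window_dataset(seq, confidence_maps, timeline: ActivityTimeline,
                         cfg: WindowConfig | None = None,
                         flow_backend: str = "ilk"):
    """Labeled window samples for training/evaluation.

    ``confidence_maps`` holds one per-frame skin-confidence map (float
    [0,1]) on the frame grid; ground-truth masks cast to float serve the
    same role when no trained segmenter is in the loop. Windows touching
    absence are excluded. Returns (context (N,6,s,s), motion (N,10,s,s),
    labels (N,) with 1 = intervention, windows).
    """
    cfg = cfg or WindowConfig()
    confidence_maps = np.asarray(confidence_maps, dtype=np.float32)
    ctx_list, mot_list, labels, kept = [], [], [], []
    for sample in make_windows(seq, cfg):
        secs = timeline.state_at(sample.start_time + np.arange(int(cfg.T)) + 0.5)
        if np.any(secs == "absent"):
            continue
        sample.label = label_window(secs, cfg)
        sample.context = _resize_stack(confidence_maps[sample.frame_indices], cfg.input_size)
        frames = seq.frames[sample.frame_indices]
        small = np.stack([
            _resize_stack(f.transpose(2, 0, 1), cfg.input_size).transpose(1, 2, 0)
            for f in frames
        ])
        sample.motion = window_flow_stack(small, backend=flow_backend, encode=True)
        ctx_list.append(sample.context)
        mot_list.append(sample.motion)
        labels.append(1 if sample.label == "intervention" else 0)
        kept.append(sample)
    if not ctx_list:
        raise ValueError("no labelable windows (recording fully absent?)")
    return (np.stack(ctx_list), np.stack(mot_list),
            np.array(labels, dtype=int), kept)


# ---------------------------------------------------------------------------
# Timeline prediction
# ---------------------------------------------------------------------------

def _resize_stack(stack: np.ndarray, size: int) -> np.ndarray:
    if stack.shape[-1] == size and stack.shape[-2] == size:
        return stack.astype(np.float32)
    return np.stack([
        _sk_resize(ch.astype(np.float64), (size, size), order=1,
                   preserve_range=True, anti_aliasing=False)
        for ch in stack
    ]).astype(np.float32)


def predict_timeline(seq, skin_net, model: InterventionNet,
                     cfg: WindowConfig | None = None,
                     flow_backend: str = "ilk") -> ActivityTimeline:
    """Per-second activity states for a recording.

    One frame per second is passed through the detection/segmentation
    network; seconds classified absent are ``absent`` and override
    everything else. Remaining seconds are ``intervention`` when the mean
    intervention probability of the windows covering them reaches 0.5,
    ``valid`` otherwise.
    """
    cfg = cfg or WindowConfig()
    n_seconds = int(np.floor(seq.duration))
    n_frames = len(seq.frames)
    sec_idx = np.minimum(np.round(np.arange(n_seconds + 1) * seq.fps).astype(int), n_frames - 1)
    sec_idx = sec_idx[: n_seconds + 1]
    frames = seq.frames[sec_idx]
    # detection + skin confidence per sampled second
    from .videoio import letterbox_resize
    size = skin_net.cfg.input_size
    boxed = np.stack([letterbox_resize(f, size)[0] for f in frames])
    probs, maps = skin_net.predict_batch(boxed)
    present = probs[:, 1] >= skin_net.cfg.detection_threshold
    maps = np.where(np.isnan(maps), 0.0, maps)

    small_frames = _resize_stack(boxed.transpose(0, 3, 1, 2).reshape(-1, size, size),
                                 cfg.input_size).reshape(len(boxed), 3, cfg.input_size, cfg.input_size)
    small_maps = _resize_stack(maps, cfg.input_size)

    score_sum = np.zeros(n_seconds)
    score_cnt = np.zeros(n_seconds)
    step = int(cfg.tau)
    for start in range(0, n_seconds - int(cfg.T) + 1, step):
        sec = slice(start, start + int(cfg.T) + 1)
        if not present[sec].all():
            continue
        ctx = small_maps[sec]
        win_frames = small_frames[sec].transpose(0, 2, 3, 1)
        mot = window_flow_stack(win_frames, backend=flow_backend, encode=True)
        p = model.forward(ctx[None], mot[None])[0]
        cover = slice(start, start + int(cfg.T))
        score_sum[cover] += p[1]
        score_cnt[cover] += 1

    states = np.empty(n_seconds, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_score = np.where(score_cnt > 0, score_sum / np.maximum(score_cnt, 1), 0.0)
    states[:] = "valid"
    states[mean_score >= 0.5] = "intervention"
    # absence precedence: a second whose sampled frame lacks the patient
    states[~present[:n_seconds]] = "absent"
    return ActivityTimeline(states)
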