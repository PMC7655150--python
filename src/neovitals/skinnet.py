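"""Joint patient detection + skin segmentation network.

A shared convolutional core (VGG-16-style, or a slim ``tiny`` variant for
desk-scale experiments) feeds two output streams:

* a detection stream: 1x1 convolution (2 outputs) on the last pooling
  stage, global average pooling, softmax over {absent, present};
* a segmentation stream in the FCN-8s pattern: 1x1 score convolutions on
  pooling stages 3, 4 and the coarsest stage, learnable x2/x2/x8 transpose-
  convolution upsampling with skip additions, and a per-pixel softmax
  yielding the skin confidence map.

Segmentation runs only when the detection stream finds the patient.
Training follows the two-stage recipe: the core and segmentation stream
first (positives only, lr 1e-2), then everything jointly with an equally
weighted sum of the two losses (positives + negatives, lr 1e-4); both
stages drop the rate tenfold every two epochs, batch 20, momentum 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn.functional import EPS_LOG, softmax
from .nn.optim import SGD, step_decay_lr
from .videoio import ChannelMeans

TINY_CHANNELS = [8, 16, 16, 24, 32]
VGG16_CHANNELS = [[64, 64], [128, 128], [256, 256, 256], [512, 512, 512], [512, 512, 512]]


@dataclass
class SkinNetConfig:
    backbone: str = "tiny"  # tiny | vgg16
    input_size: int = 64
    n_classes: int = 2
    batch_norm: bool = True
    skip_stages: tuple[int, int, int] = (3, 4, 5)
    detection_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.n_classes != 2:
            raise ValueError("the model is a 2-class (non-skin/skin) segmenter")

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone,
            "input_size": self.input_size,
            "n_classes": self.n_classes,
            "batch_norm": self.batch_norm,
            "skip_stages": list(self.skip_stages),
            "detection_threshold": self.detection_threshold,
            "seed": self.seed,
        }


@dataclass
class PatientScore:
    p_absent: float
    p_present: float


@dataclass
class TrainingSchedule:
    """Hyper-parameters for one training stage."""

    stage: int
    lr_start: float
    epochs: int
    decay_every: int = 2  # epochs between tenfold lr drops
    lr_decay_factor: float = 10.0
    momentum: float = 0.90
    batch_size: int = 20
    loss_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.lr_start <= 0:
            raise ValueError("lr_start must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")

    def lr_at_epoch(self, epoch: int) -> float:
        return step_decay_lr(self.lr_start, epoch, self.decay_every, self.lr_decay_factor)


def default_schedules() -> tuple[TrainingSchedule, TrainingSchedule]:
    """The published two-stage recipe (assumes a pretrained backbone):
    segmentation stage at lr 1e-2, joint stage at 1e-4, both dropping
    tenfold every two epochs, batch 20, momentum 0.90."""
    return (
        TrainingSchedule(stage=1, lr_start=1e-2, epochs=6),
        TrainingSchedule(stage=2, lr_start=1e-4, epochs=4),
    )


def from_scratch_schedules() -> tuple[TrainingSchedule, TrainingSchedule]:
    """Schedules for training the tiny backbone from random weights.

    The joint stage keeps the stage-1 rate: without pretrained features the
    freshly initialized detection head sees gradients far too small at
    1e-4 to converge within the decay horizon. Decay law, batch size and
    momentum are unchanged.
    """
    return (
        TrainingSchedule(stage=1, lr_start=1e-2, epochs=6),
        TrainingSchedule(stage=2, lr_start=1e-2, epochs=6),
    )


def _conv_stage(c_in, channels, rng, batch_norm, k=3):
    layers = []
    for c_out in channels:
        layers.append(nn.Conv2d(c_in, c_out, k, rng=rng))
        if batch_norm:
            layers.append(nn.BatchNorm2d(c_out))
        layers.append(nn.ReLU())
        c_in = c_out
    layers.append(nn.MaxPool2d())
    return nn.Sequential(*layers)


class SkinNet:
    """Multi-task patient-detection / skin-segmentation network."""

    def __init__(self, cfg: SkinNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        if cfg.backbone == "tiny":
            stage_channels = [[c] for c in TINY_CHANNELS]
        elif cfg.backbone == "vgg16":
            stage_channels = VGG16_CHANNELS
        else:
            raise ValueError(f"unknown backbone {cfg.backbone!r}")
        self.stages: list[nn.Sequential] = []
        c_in = 3
        for chans in stage_channels:
            self.stages.append(_conv_stage(c_in, chans, rng, cfg.batch_norm))
            c_in = chans[-1]
        self.stage_out_channels = [chans[-1] for chans in stage_channels]
        if cfg.backbone == "vgg16":
            # fully-connected layers converted to convolutions
            self.fc_block = nn.Sequential(
                nn.Conv2d(512, 4096, 7, rng=rng), nn.ReLU(),
                nn.Conv2d(4096, 4096, 1, rng=rng), nn.ReLU(),
            )
            coarse_ch = 4096
        else:
            self.fc_block = None
            coarse_ch = self.stage_out_channels[-1]
        s3, s4, _ = cfg.skip_stages
        # detection head on the last pooling stage
        self.det_score = nn.Conv2d(self.stage_out_channels[-1], 2, 1, rng=rng)
        self.det_pool = nn.GlobalAvgPool2d()
        # segmentation scores and learnable upsampling (bilinear init, no bias)
        self.score_coarse = nn.Conv2d(coarse_ch, 2, 1, rng=rng)
        self.score_s4 = nn.Conv2d(self.stage_out_channels[s4 - 1], 2, 1, rng=rng)
        self.score_s3 = nn.Conv2d(self.stage_out_channels[s3 - 1], 2, 1, rng=rng)
        self.up2a = nn.ConvTranspose2d(2, 2, 4, 2, init="bilinear")
        self.up2b = nn.ConvTranspose2d(2, 2, 4, 2, init="bilinear")
        self.up8 = nn.ConvTranspose2d(2, 2, 16, 8, init="bilinear")
        self.channel_means: ChannelMeans | None = None
        self.seg_eval_count = 0

    # -- parameter groups ---------------------------------------------------
    def core_parameters(self):
        ps = []
        for st in self.stages:
            ps.extend(st.parameters())
        if self.fc_block is not None:
            ps.extend(self.fc_block.parameters())
        return ps

    def seg_parameters(self):
        ps = []
        for layer in (self.score_coarse, self.score_s4, self.score_s3,
                      self.up2a, self.up2b, self.up8):
            ps.extend(layer.parameters())
        return ps

    def det_parameters(self):
        return self.det_score.parameters()

    def all_parameters(self):
        return self.core_parameters() + self.seg_parameters() + self.det_parameters()

    # -- forward / backward -------------------------------------------------
    def _core_forward(self, x, train=False):
        outs = []
        for st in self.stages:
            x = st.forward(x, train=train)
            outs.append(x)
        coarse = outs[-1] if self.fc_block is None else self.fc_block.forward(outs[-1], train=train)
        return outs, coarse

    def forward_train(self, x):
        """Full forward pass with caches; returns (det_logits, seg_logits)."""
        outs, coarse = self._core_forward(x, train=True)
        s3, s4, _ = self.cfg.skip_stages
        det_logits = self.det_pool.forward(self.det_score.forward(outs[-1], train=True))
        f5 = self.score_coarse.forward(coarse, train=True)
        f4 = self.up2a.forward(f5, train=True) + self.score_s4.forward(outs[s4 - 1], train=True)
        f3 = self.up2b.forward(f4, train=True) + self.score_s3.forward(outs[s3 - 1], train=True)
        seg_logits = self.up8.forward(f3, train=True)
        return det_logits, seg_logits

    def backward_full(self, d_det_logits, d_seg_logits):
        """Backward for a forward_train pass; fills parameter gradients.

        Skip-connection gradients are injected when the backward sweep
        reaches the stage whose pooled output fed the corresponding score
        convolution.
        """
        s3, s4, _ = self.cfg.skip_stages
        d3 = self.up8.backward(d_seg_logits)
        d_skip3 = self.score_s3.backward(d3)
        d4 = self.up2b.backward(d3)
        d_skip4 = self.score_s4.backward(d4)
        d5 = self.up2a.backward(d4)
        d_coarse = self.score_coarse.backward(d5)
        if self.fc_block is not None:
            d_coarse = self.fc_block.backward(d_coarse)
        d_det = self.det_score.backward(self.det_pool.backward(d_det_logits))
        grad = d_coarse + d_det
        for i in reversed(range(len(self.stages))):
            grad = self.stages[i].backward(grad)
            if i == s4:  # grad now w.r.t. output of stage s4 (index s4-1)
                grad = grad + d_skip4
            elif i == s3:
                grad = grad + d_skip3
        return grad

    def _preprocess(self, frames: np.ndarray) -> np.ndarray:
        x = np.asarray(frames)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] == 3:  # HWC -> CHW
            x = x.transpose(0, 3, 1, 2)
        x = x.astype(np.float32)
        if self.channel_means is not None:
            x = x - np.asarray(self.channel_means.means, dtype=np.float32)[None, :, None, None]
        return x

    def detect(self, frames: np.ndarray) -> np.ndarray:
        """Patient presence probabilities, (N, 2) as (p_absent, p_present)."""
        x = self._preprocess(frames)
        if x.shape[-1] != self.cfg.input_size or x.shape[-2] != self.cfg.input_size:
            raise ValueError("frame not preprocessed to cfg.input_size")
        outs, _ = self._core_forward(x, train=False)
        self._eval_cache = (x, outs)
        logits = self.det_pool.forward(self.det_score.forward(outs[-1]))
        return softmax(logits, axis=1)

    def segment(self, cached=True, frames=None) -> np.ndarray:
        """Skin confidence maps (N, H, W) for the last ``detect`` batch."""
        if cached and hasattr(self, "_eval_cache"):
            x, outs = self._eval_cache
        else:
            x = self._preprocess(frames)
            outs, _ = self._core_forward(x, train=False)
        coarse = outs[-1] if self.fc_block is None else self.fc_block.forward(outs[-1])
        s3, s4, _ = self.cfg.skip_stages
        f5 = self.score_coarse.forward(coarse)
        f4 = self.up2a.forward(f5) + self.score_s4.forward(outs[s4 - 1])
        f3 = self.up2b.forward(f4) + self.score_s3.forward(outs[s3 - 1])
        seg_logits = self.up8.forward(f3)
        self.seg_eval_count += len(x)
        return softmax(seg_logits, axis=1)[:, 1]

    def forward(self, frame: np.ndarray):
        """(PatientScore, SkinConfidenceMap | None) for a single frame.

        The segmentation stream is evaluated only when
        p_present >= cfg.detection_threshold.
        """
        probs = self.detect(frame)
        score = PatientScore(p_absent=float(probs[0, 0]), p_present=float(probs[0, 1]))
        if score.p_present >= self.cfg.detection_threshold:
            return score, self.segment(cached=True)[0]
        return score, None

    def predict_batch(self, frames: np.ndarray, chunk: int = 16):
        """Vectorized inference over many frames.

        Returns (presence probabilities (N,2), confidence maps (N,H,W) with
        NaN rows for frames classified absent).
        """
        frames = np.asarray(frames)
        n = len(frames)
        probs = np.zeros((n, 2), dtype=np.float32)
        maps = np.full((n, self.cfg.input_size, self.cfg.input_size), np.nan, dtype=np.float32)
        for i0 in range(0, n, chunk):
            batch = frames[i0 : i0 + chunk]
            p = self.detect(batch)
            probs[i0 : i0 + len(batch)] = p
            present = p[:, 1] >= self.cfg.detection_threshold
            if present.any():
                x, outs = self._eval_cache
                sel = np.flatnonzero(present)
                self._eval_cache = (x[sel], [o[sel] for o in outs])
                maps[i0 + sel] = self.segment(cached=True)
        return probs, maps

    # -- persistence ---------------------------------------------------------
    def _named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        layers = {"det_score": self.det_score, "score_coarse": self.score_coarse,
                  "score_s4": self.score_s4, "score_s3": self.score_s3,
                  "up2a": self.up2a, "up2b": self.up2b, "up8": self.up8}
        for i, st in enumerate(self.stages):
            for j, layer in enumerate(st.layers):
                layers[f"stage{i}_{j}"] = layer
        if self.fc_block is not None:
            for j, layer in enumerate(self.fc_block.layers):
                layers[f"fc_{j}"] = layer
        for name, layer in layers.items():
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    arrays[f"{name}.{attr}"] = getattr(layer, attr)
        return arrays

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self._named_arrays())
        sidecar = path.with_suffix(".yaml")
        meta = {"config": self.cfg.to_dict()}
        if self.channel_means is not None:
            meta["channel_means"] = list(self.channel_means.means)
        sidecar.write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SkinNet":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        cfgd = meta["config"]
        cfgd["skip_stages"] = tuple(cfgd["skip_stages"])
        net = cls(SkinNetConfig(**cfgd))
        data = np.load(path if path.suffix else path.with_suffix(".npz"))
        for name, arr in net._named_arrays().items():
            arr[...] = data[name]
        if "channel_means" in meta:
            net.channel_means = ChannelMeans(tuple(meta["channel_means"]))
        return net


def build_skinnet(cfg: SkinNetConfig) -> SkinNet:
    return SkinNet(cfg)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def threshold_map(p_skin: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """Skin label: pixel is skin iff p_skin >= theta, theta in (0, 1)."""
    if not 0 < theta < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(p_skin) >= theta


def detection_loss(p_absent: float, p_present: float, truth: str) -> float:
    """Multinomial logistic loss: -ln(prob of the true class), clamped."""
    if truth not in ("absent", "present"):
        raise ValueError("truth must be 'absent' or 'present'")
    p_true = p_present if truth == "present" else p_absent
    return float(-np.log(max(p_true, EPS_LOG)))


def segmentation_pixel_weights(truth: np.ndarray) -> np.ndarray:
    """Class-balanced per-pixel weights summing to 1.

    Each pixel weighs 1/(2 * frequency of its true class); a single-class
    truth falls back to uniform weights (plain mean).
    """
    truth = np.asarray(truth, dtype=bool)
    n = truth.size
    n_skin = int(truth.sum())
    if n_skin == 0 or n_skin == n:
        return np.full(truth.shape, 1.0 / n)
    w = np.where(truth, 1.0 / (2.0 * n_skin / n), 1.0 / (2.0 * (n - n_skin) / n))
    return w / n


def segmentation_loss(p_skin: np.ndarray, truth: np.ndarray) -> float:
    """Class-balanced multinomial logistic loss over all pixels.

    A predictor emitting 0.5 everywhere scores ln 2 on any two-class truth
    regardless of class imbalance.
    """
    p_skin = np.asarray(p_skin, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if p_skin.shape != truth.shape:
        raise ValueError("map and truth must share a size")
    p_true = np.where(truth, p_skin, 1.0 - p_skin)
    nll = -np.log(np.clip(p_true, EPS_LOG, None))
    return float((segmentation_pixel_weights(truth) * nll).sum())


def joint_loss(l_det: float, l_seg: float, weights: tuple[float, float] = (1.0, 1.0)) -> float:
    if weights[0] < 0 or weights[1] < 0:
        raise ValueError("loss weights must be non-negative")
    return weights[0] * l_det + weights[1] * l_seg


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _seg_grad(seg_logits: np.ndarray, truths: np.ndarray) -> tuple[float, np.ndarray]:
    """Balanced segmentation loss and gradient w.r.t. logits for a batch."""
    probs = softmax(seg_logits, axis=1)
    n = len(seg_logits)
    grad = np.zeros_like(seg_logits)
    total = 0.0
    for i in range(n):
        t = truths[i].astype(bool)
        w = segmentation_pixel_weights(t)
        p_true = np.where(t, probs[i, 1], probs[i, 0])
        total += (w * -np.log(np.clip(p_true, EPS_LOG, None))).sum()
        onehot = np.stack([~t, t]).astype(np.float64)
        grad[i] = (probs[i] - onehot) * w[None]
    return total / n, (grad / n).astype(np.float32)


def _det_grad(det_logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Detection loss (mean -ln p_true) and gradient w.r.t. logits."""
    probs = softmax(det_logits, axis=1)
    n = len(det_logits)
    p_true = probs[np.arange(n), labels]
    loss = float(-np.log(np.clip(p_true, EPS_LOG, None)).mean())
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    return loss, ((probs - onehot) / n).astype(np.float32)


def iou_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks (empty union -> 1)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    union = (pred | truth).sum()
    if union == 0:
        return 1.0
    return float((pred & truth).sum() / union)


def train_skinnet(
    net: SkinNet,
    images: np.ndarray,
    masks: np.ndarray,
    presence: np.ndarray,
    schedule1: TrainingSchedule | None = None,
    schedule2: TrainingSchedule | None = None,
    rng_seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Two-stage training.

    Stage 1 updates the core and segmentation stream on positive images
    only; stage 2 updates all layers jointly on positives and negatives
    with equally weighted losses. ``images`` are uint8 HWC frames at the
    network input size; ``masks`` boolean, ``presence`` boolean per image.
    Corpus channel means are computed here once and stored with the model.
    """
    d1, d2 = default_schedules()
    schedule1 = schedule1 or d1
    schedule2 = schedule2 or d2
    images = np.asarray(images)
    masks = np.asarray(masks, dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    net.channel_means = ChannelMeans(tuple(
        float(images[presence][..., c].mean()) for c in range(3)
    ))
    rng = np.random.default_rng(rng_seed)
    history: dict = {"stage1": [], "stage2": []}

    def run_stage(sched, idx, params, joint):
        opt = SGD(params, lr=sched.lr_at_epoch(0), momentum=sched.momentum)
        for epoch in range(sched.epochs):
            opt.lr = sched.lr_at_epoch(epoch)
            order = rng.permutation(idx)
            losses = []
            for i0 in range(0, len(order), sched.batch_size):
                sel = order[i0 : i0 + sched.batch_size]
                x = net._preprocess(images[sel])
                det_logits, seg_logits = net.forward_train(x)
                labels = presence[sel].astype(int)
                l_det, g_det = _det_grad(det_logits, labels)
                # segmentation loss only over frames with the patient present
                pos = np.flatnonzero(presence[sel])
                g_seg = np.zeros_like(seg_logits)
                l_seg = 0.0
                if len(pos):
                    l_seg, g_pos = _seg_grad(seg_logits[pos], masks[sel][pos])
                    g_seg[pos] = g_pos * (len(pos) / len(sel))
                if joint:
                    w1, w2 = sched.loss_weights
                    net.backward_full(w1 * g_det, w2 * g_seg)
                    losses.append(joint_loss(l_det, l_seg, sched.loss_weights))
                else:
                    net.backward_full(np.zeros_like(g_det), g_seg)
                    losses.append(l_seg)
                opt.step()
                opt.zero_grad()
            history[f"stage{sched.stage}"].append(float(np.mean(losses)))
            if verbose:
                print(f"stage {sched.stage} epoch {epoch}: loss {np.mean(losses):.4f} lr {opt.lr:g}")

    pos_idx = np.flatnonzero(presence)
    if len(pos_idx) == 0:
        raise ValueError("stage 1 requires positive images with masks")
    run_stage(schedule1, pos_idx, net.core_parameters() + net.seg_parameters(), joint=False)
    run_stage(schedule2, np.arange(len(images)), net.all_parameters(), joint=True)
    return history
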