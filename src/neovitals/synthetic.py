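"""Deterministic incubator-scene simulator.

Each recording shows one skin-colored elliptical region on a dark
background. The green channel inside the ellipse is modulated by ~1% at
the cardiac frequency (the PPGi signal); the ellipse axes breathe at the
respiratory frequency so the skin area oscillates; a slow multiplicative
lightness drift emulates changing ambient light. Two event types exercise
the pipeline: ``occluder`` draws a fast-moving block of distinct chroma
over the scene (a clinical intervention; its speed exceeds the 40 px/s
flow clip), and ``absence`` removes the patient entirely (e.g. kangaroo
care). Ground truth (per-frame mask and presence, per-second activity
state, true rates) is emitted alongside the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.morphology import dilation, disk, erosion

from .interventionnet import ActivityTimeline


@dataclass
class SceneEvent:
    kind: str   # occluder | absence
    start: float
    end: float

    def __post_init__(self):
        if self.kind not in ("occluder", "absence"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.end > self.start >= 0:
            raise ValueError("event must have end > start >= 0")


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (128, 128)  # (H, W)
    fps: float = 20.0
    duration: float = 10.0  # seconds
    skin_chroma: tuple[int, int, int] = (205, 160, 140)
    background_chroma: tuple[int, int, int] = (42, 48, 58)
    occluder_chroma: tuple[int, int, int] = (90, 115, 205)
    hr: float = 150.0             # beats/min
    ppg_amplitude: float = 0.01   # fractional green modulation
    rr: float = 50.0              # breaths/min
    resp_area_amplitude: float = 0.05  # fractional area modulation
    lighting_drift: tuple[float, float] = (0.05, 20.0)  # (amplitude, period s)
    occluder_speed: float = 60.0  # px/s, > 40 to exercise flow clipping
    occluder_size: float = 0.25   # fraction of min(image size)
    noise_sigma: float = 1.0      # additive Gaussian, intensity units
    events: list = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.ppg_amplitude < 0.2:
            raise ValueError("ppg_amplitude must lie in (0, 0.2)")
        self.events = [e if isinstance(e, SceneEvent) else SceneEvent(**e)
                       for e in self.events]
        for kind in ("occluder", "absence"):
            spans = sorted((e.start, e.end) for e in self.events if e.kind == kind)
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {kind} events")
            if any(e > self.duration for _, e in spans):
                raise ValueError("events must lie within the recording duration")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "fps", "duration", "hr", "ppg_amplitude", "rr", "resp_area_amplitude",
            "occluder_speed", "occluder_size", "noise_sigma", "rng_seed")}
        d["image_size"] = list(self.image_size)
        for k in ("skin_chroma", "background_chroma", "occluder_chroma"):
            d[k] = list(getattr(self, k))
        d["lighting_drift"] = list(self.lighting_drift)
        d["events"] = [{"kind": e.kind, "start": e.start, "end": e.end}
                       for e in self.events]
        return d


@dataclass
class GroundTruth:
    masks: np.ndarray      # (T, H, W) bool skin masks
    presence: np.ndarray   # (T,) bool
    timeline: ActivityTimeline
    hr: float
    rr: float


def _in_event(t: float, events, kind: str) -> SceneEvent | None:
    for e in events:
        if e.kind == kind and e.start <= t < e.end:
            return e
    return None


def generate_recording(cfg: SceneConfig):
    """Render the scene; returns (FrameSequence, GroundTruth).

    Identical configs (including seed) produce bit-identical frames.
    """
    from .videoio import FrameSequence  # local import to avoid a cycle

    h, w = cfg.image_size
    n = int(round(cfg.duration * cfg.fps))
    rng = np.random.default_rng(cfg.rng_seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = h / 2.0, w / 2.0
    a0, b0 = 0.35 * w, 0.27 * h  # base semi-axes (col, row)
    base_area = np.pi * a0 * b0
    occ_half = int(round(cfg.occluder_size * min(h, w) / 2))

    frames = np.zeros((n, h, w, 3), dtype=np.uint8)
    masks = np.zeros((n, h, w), dtype=bool)
    presence = np.zeros(n, dtype=bool)
    bg = np.asarray(cfg.background_chroma, dtype=np.float64)
    skin = np.asarray(cfg.skin_chroma, dtype=np.float64)
    occ = np.asarray(cfg.occluder_chroma, dtype=np.float64)
    drift_amp, drift_period = cfg.lighting_drift

    for i in range(n):
        t = i / cfg.fps
        img = np.broadcast_to(bg, (h, w, 3)).copy()
        absent = _in_event(t, cfg.events, "absence") is not None
        if not absent:
            # respiratory modulation of the area; both axes scale by sqrt
            s = np.sqrt(1.0 + cfg.resp_area_amplitude * np.sin(2 * np.pi * cfg.rr / 60.0 * t))
            ell = ((xx - cx) / (a0 * s)) ** 2 + ((yy - cy) / (b0 * s)) ** 2 <= 1.0
            color = skin.copy()
            img[ell] = color
            # cardiac modulation of the green channel over the skin
            img[ell, 1] = color[1] * (1.0 + cfg.ppg_amplitude
                                      * np.sin(2 * np.pi * cfg.hr / 60.0 * t))
            masks[i] = ell
            presence[i] = True
        occ_event = None if absent else _in_event(t, cfg.events, "occluder")
        if occ_event is not None:
            # block sweeps horizontally, bouncing off the frame edges
            span = max(1, w - 2 * occ_half)
            x = (occ_event.start * 0 + cfg.occluder_speed * (t - occ_event.start)) % (2 * span)
            x = span - abs(x - span)
            ocx = int(occ_half + x)
            ocy = int(cy)
            sl = (slice(max(0, ocy - occ_half), min(h, ocy + occ_half)),
                  slice(max(0, ocx - occ_half), min(w, ocx + occ_half)))
            img[sl] = occ
            masks[i][sl] = False  # the occluder covers the skin
        # global lightness drift then sensor noise
        img *= 1.0 + drift_amp * np.sin(2 * np.pi * t / drift_period)
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    states = np.empty(int(np.floor(cfg.duration)), dtype=object)
    states[:] = "valid"
    for e in cfg.events:
        s0, s1 = int(np.floor(e.start)), int(np.ceil(e.end))
        states[s0:s1] = "intervention" if e.kind == "occluder" else "absent"
    # absence wins where events of both kinds touch the same second
    for e in cfg.events:
        if e.kind == "absence":
            states[int(np.floor(e.start)) : int(np.ceil(e.end))] = "absent"

    seq = FrameSequence(frames, fps=cfg.fps)
    truth = GroundTruth(masks=masks, presence=presence,
                        timeline=ActivityTimeline(states), hr=cfg.hr, rr=cfg.rr)
    return seq, truth


def simulate_annotators(truth_masks: np.ndarray, n_annotators: int = 3,
                        disagreement: float = 1.0, rng_seed: int = 0
                        ) -> list[list[np.ndarray]]:
    """Per-annotator masks: the truth morphologically perturbed at the
    boundary by independent dilations/erosions of radius up to
    ``disagreement`` pixels. Returns one mask list per annotator."""
    if disagreement < 0:
        raise ValueError("disagreement must be >= 0")
    truth_masks = np.asarray(truth_masks, dtype=bool)
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_annotators):
        ann = []
        for mask in truth_masks:
            r = int(rng.integers(0, int(np.ceil(disagreement)) + 1)) if disagreement > 0 else 0
            if r == 0:
                ann.append(mask.copy())
                continue
            op = dilation if rng.random() < 0.5 else erosion
            ann.append(op(mask, disk(r)).astype(bool))
        out.append(ann)
    return out


def write_recording(path: str | Path, seq, truth: GroundTruth, cfg: SceneConfig) -> Path:
    """Write frames/*.png, truth/masks/*.png, truth/timeline.csv, scene.yaml."""
    path = Path(path)
    (path / "frames").mkdir(parents=True, exist_ok=True)
    (path / "truth" / "masks").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(path / "frames" / f"frame_{i:06d}.png", frame)
        iio.imwrite(path / "truth" / "masks" / f"mask_{i:06d}.png",
                    truth.masks[i].astype(np.uint8) * 255)
    truth.timeline.to_csv(path / "truth" / "timeline.csv")
    (path / "scene.yaml").write_text(yaml.safe_dump({"fps": seq.fps, **cfg.to_dict()}))
    return path
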