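"""Frame and mask I/O plus the geometric/photometric normalization applied
before both networks: aspect-preserving letterbox resize to a square canvas
and training-corpus mean subtraction.

Conventions: 0-based pixel grid, row-major, origin at the top-left,
half-open boxes. Landscape sources pad top/bottom, portrait sources pad
left/right; an odd padding remainder goes to the bottom/right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize as _sk_resize

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass
class FrameSequence:
    """Ordered RGB frames (8-bit per channel) with timing metadata."""

    frames: np.ndarray  # (T, H, W, 3) uint8
    fps: float
    origin_time: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (T, H, W, 3)")
        if len(self.frames) < 1:
            raise ValueError("frame count must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return len(self.frames) / self.fps

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times(self) -> np.ndarray:
        """Timestamp of each frame in seconds."""
        return self.origin_time + np.arange(len(self.frames)) / self.fps


@dataclass
class LetterboxTransform:
    """Mapping from a source frame onto a square target canvas."""

    target_size: int
    content_box: tuple[int, int, int, int]  # (top, left, bottom, right), half-open
    scale: float
    source_size: tuple[int, int]  # (H, W)

    def to_source(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map target-canvas pixel coordinates back onto the source grid."""
        top, left, _, _ = self.content_box
        return (np.asarray(rows) - top) / self.scale, (np.asarray(cols) - left) / self.scale

    def to_dict(self) -> dict:
        return {
            "target_size": self.target_size,
            "content_box": list(self.content_box),
            "scale": float(self.scale),
            "source_size": list(self.source_size),
        }


@dataclass
class ChannelMeans:
    """Per-channel (R, G, B) mean intensity of the training corpus."""

    means: tuple[float, float, float]

    def __post_init__(self):
        if any(m < 0 or m > 255 for m in self.means):
            raise ValueError("channel means must lie in the pixel value range [0, 255]")


def load_frames(source: str | Path, sampling: int = 1, fps: float | None = None) -> FrameSequence:
    """Read an ordered image-sequence directory (or a multi-frame file).

    ``sampling`` keeps every N-th frame and divides the fps metadata
    accordingly. For directories, fps comes from ``fps`` or a
    ``scene.yaml``/``meta.yaml`` sibling; defaults to 20 fps otherwise.
    """
    source = Path(source)
    if sampling < 1:
        raise ValueError("sampling must be >= 1")
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise FileNotFoundError(f"no image files in {source}")
        if fps is None:
            for meta_name in ("scene.yaml", "meta.yaml"):
                meta = source.parent / meta_name
                if meta.exists():
                    fps = float(yaml.safe_load(meta.read_text()).get("fps", 20.0))
                    break
            else:
                fps = 20.0
        frames = [np.atleast_3d(iio.imread(f)) for f in files[::sampling]]
    elif source.exists():
        arr = iio.imread(source)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            arr = arr[None]
        frames = list(arr[::sampling])
        fps = fps or 20.0
    else:
        raise FileNotFoundError(source)
    frames = [f[..., :3] if f.shape[-1] >= 3 else np.repeat(f, 3, axis=-1) for f in frames]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame sizes: {sorted(shapes)}")
    return FrameSequence(np.stack(frames).astype(np.uint8), fps=fps / sampling)


def letterbox_resize(
    frame: np.ndarray, target: int
) -> tuple[np.ndarray, LetterboxTransform]:
    """Resize to a ``target`` x ``target`` canvas, preserving aspect ratio.

    The content is scaled with bilinear interpolation; the remaining canvas
    is padded black (top/bottom for landscape sources, left/right for
    portrait ones).
    """
    frame = np.asarray(frame)
    if target <= 0:
        raise ValueError("target must be positive")
    h, w = frame.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("degenerate (zero-area) frame")
    scale = target / max(h, w)
    if w >= h:  # landscape: full width, bars top/bottom
        new_w, new_h = target, max(1, round(h * scale))
    else:  # portrait: full height, bars left/right
        new_h, new_w = target, max(1, round(w * scale))
    content = _sk_resize(
        frame, (new_h, new_w), order=1, preserve_range=True, anti_aliasing=False
    )
    top = (target - new_h) // 2
    left = (target - new_w) // 2
    canvas_shape = (target, target) + frame.shape[2:]
    canvas = np.zeros(canvas_shape, dtype=frame.dtype)
    canvas[top : top + new_h, left : left + new_w] = np.round(content).astype(frame.dtype) if np.issubdtype(frame.dtype, np.integer) else content
    tfm = LetterboxTransform(
        target_size=target,
        content_box=(top, left, top + new_h, left + new_w),
        scale=scale,
        source_size=(h, w),
    )
    return canvas, tfm


def letterbox_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Letterbox a binary mask with nearest-neighbour scaling (labels stay binary)."""
    mask = np.asarray(mask)
    h, w = mask.shape[:2]
    scale = target / max(h, w)
    if w >= h:
        new_w, new_h = target, max(1, round(h * scale))
    else:
        new_h, new_w = target, max(1, round(w * scale))
    content = _sk_resize(
        mask.astype(float), (new_h, new_w), order=0, preserve_range=True, anti_aliasing=False
    )
    canvas = np.zeros((target, target), dtype=bool)
    top = (target - new_h) // 2
    left = (target - new_w) // 2
    canvas[top : top + new_h, left : left + new_w] = content > 0.5
    return canvas


def compute_channel_means(frames: Sequence[np.ndarray] | np.ndarray) -> ChannelMeans:
    """Mean of each color channel across a training corpus."""
    frames = np.asarray(frames, dtype=np.float64)
    m = frames.reshape(-1, frames.shape[-1]).mean(axis=0)
    return ChannelMeans(tuple(float(v) for v in m[:3]))


def mean_subtract(seq: FrameSequence | np.ndarray, means: ChannelMeans) -> np.ndarray:
    """Center frames by subtracting per-channel corpus means (float output)."""
    frames = seq.frames if isinstance(seq, FrameSequence) else np.asarray(seq)
    return frames.astype(np.float32) - np.asarray(means.means, dtype=np.float32)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel PNG mask (0 = non-skin, 255 = skin) as boolean."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr >= 128


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_confidence_map(path: str | Path, p_skin: np.ndarray) -> None:
    """Store a skin-confidence map as 8-bit PNG (value = round(255*p))."""
    iio.imwrite(path, np.round(np.clip(p_skin, 0, 1) * 255).astype(np.uint8))


def read_confidence_map(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float32) / 255.0
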