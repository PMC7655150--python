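"""Dense optical flow between consecutive sampled frames and the lossy
8-bit codec used to store flow and feed it to the intervention network.

Each displacement component is clipped to +/-40 px (displacements above
40 px over one second are rare in the incubator scene) and mapped linearly
onto [0, 255] (-40 -> 0, 0 -> 128 after round-half-up, +40 -> 255), so a
5 s window of flow fits in a handful of 8-bit images.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

CLIP_LIMIT = 40.0  # pixels


@dataclass
class FlowField:
    """Per-pixel displacement from the first frame to the second, in pixels."""

    u: np.ndarray  # horizontal (+right)
    v: np.ndarray  # vertical (+down)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float32)
        self.v = np.asarray(self.v, dtype=np.float32)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share the frame grid")


@dataclass
class EncodedFlow:
    """8-bit encoded flow components plus the clip limit they were coded with."""

    u8: np.ndarray
    v8: np.ndarray
    clip_limit: float = CLIP_LIMIT


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return rgb2gray(frame)
    return frame.astype(np.float64) / (255.0 if frame.dtype == np.uint8 else 1.0)


def compute_flow(frame_a: np.ndarray, frame_b: np.ndarray, backend: str = "tvl1") -> FlowField:
    """Dense displacement of points from ``frame_a`` to ``frame_b``.

    ``backend``: ``tvl1`` (variational, default) or ``ilk`` (iterative
    Lucas-Kanade; faster, used for bulk window extraction).
    """
    a, b = _to_gray(frame_a), _to_gray(frame_b)
    if a.shape != b.shape:
        raise ValueError("frames must share a size")
    # registration returns the field that warps frame_b back onto frame_a,
    # which equals the displacement of scene points from frame_a to frame_b
    if backend == "tvl1":
        dv, du = optical_flow_tvl1(a, b)
    elif backend == "ilk":
        dv, du = optical_flow_ilk(a, b, radius=5)
    else:
        raise ValueError(f"unknown flow backend {backend!r}")
    return FlowField(u=du, v=dv)


def _encode_component(x: np.ndarray, clip: float) -> np.ndarray:
    c = np.clip(x, -clip, clip)
    # round-half-up so displacement 0 codes to 128
    return np.floor((c + clip) * (255.0 / (2 * clip)) + 0.5).astype(np.uint8)


def encode_flow(field: FlowField, clip_limit: float = CLIP_LIMIT) -> EncodedFlow:
    """Clip each component to [-clip, +clip] and map linearly to [0, 255]."""
    return EncodedFlow(
        u8=_encode_component(field.u, clip_limit),
        v8=_encode_component(field.v, clip_limit),
        clip_limit=clip_limit,
    )


def decode_flow(enc: EncodedFlow) -> FlowField:
    """Linear inverse of the encode mapping (clipping is irreversible)."""
    scale = 2 * enc.clip_limit / 255.0
    return FlowField(
        u=enc.u8.astype(np.float32) * scale - enc.clip_limit,
        v=enc.v8.astype(np.float32) * scale - enc.clip_limit,
    )


def window_flow_stack(
    frames: np.ndarray, backend: str = "tvl1", encode: bool = True,
    padding_mask: np.ndarray | None = None,
) -> np.ndarray:
    """10-channel stack (u1,v1,...,u5,v5) for one window of exactly 6 frames.

    With ``encode`` the stack round-trips the 8-bit codec, reproducing what
    the classifier sees at training time. ``padding_mask`` (True where the
    letterbox padding is) forces zero flow in non-content regions.
    """
    frames = np.asarray(frames)
    if len(frames) != 6:
        raise ValueError(f"a 5 s window needs exactly 6 frames, got {len(frames)}")
    channels = []
    for a, b in zip(frames[:-1], frames[1:]):
        field = compute_flow(a, b, backend=backend)
        if padding_mask is not None:
            field.u[padding_mask] = 0.0
            field.v[padding_mask] = 0.0
        if encode:
            field = decode_flow(encode_flow(field))
        channels.extend([field.u, field.v])
    return np.stack(channels, axis=0)


def save_encoded_flow(enc: EncodedFlow, stem: str | Path, container: str = "jpg",
                      jpeg_quality: int = 90) -> tuple[Path, Path]:
    """Write ``<stem>_u.<ext>`` / ``<stem>_v.<ext>`` plus a YAML sidecar with
    the codec endpoints (bit-exact decode requires the sidecar)."""
    stem = Path(stem)
    pu = stem.with_name(stem.name + f"_u.{container}")
    pv = stem.with_name(stem.name + f"_v.{container}")
    kwargs = {"quality": jpeg_quality} if container in ("jpg", "jpeg") else {}
    iio.imwrite(pu, enc.u8, **kwargs)
    iio.imwrite(pv, enc.v8, **kwargs)
    sidecar = stem.with_name(stem.name + "_flow.yaml")
    sidecar.write_text(
        yaml.safe_dump({"clip_limit": float(enc.clip_limit), "code_range": [0, 255]})
    )
    return pu, pv


def load_encoded_flow(stem: str | Path, container: str = "jpg") -> EncodedFlow:
    stem = Path(stem)
    sidecar = stem.with_name(stem.name + "_flow.yaml")
    clip = CLIP_LIMIT
    if sidecar.exists():
        clip = float(yaml.safe_load(sidecar.read_text())["clip_limit"])
    u8 = iio.imread(stem.with_name(stem.name + f"_u.{container}"))
    v8 = iio.imread(stem.with_name(stem.name + f"_v.{container}"))
    return EncodedFlow(u8=u8, v8=v8, clip_limit=clip)
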