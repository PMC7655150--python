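"""Training-time augmentation for both networks.

Deterministic variants per original image: 3 lighting variants (HSL
lightness rescaled to the means of intervals 2-4 of the corpus lightness
histogram), 7 rotations at 45-degree increments on a fixed canvas, and 2
mirrors (horizontal and vertical) - 12 in total. Random jitter (translate /
scale / rotate / mirror) is drawn per sample from a named preset and applied
identically to the image and its mask so pairs stay pixel-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, rotate as _sk_rotate, warp as _sk_warp


# ---------------------------------------------------------------------------
# HSL color space (hue [0,360), saturation and lightness in [0,1])
# ---------------------------------------------------------------------------

def rgb_to_hsl(rgb: np.ndarray) -> np.ndarray:
    """Vectorized RGB (float [0,1]) -> HSL."""
    rgb = np.asarray(rgb, dtype=np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cmax = rgb.max(axis=-1)
    cmin = rgb.min(axis=-1)
    delta = cmax - cmin
    lightness = (cmax + cmin) / 2.0
    sat = np.zeros_like(lightness)
    nz = delta > 0
    sat[nz] = delta[nz] / (1.0 - np.abs(2.0 * lightness[nz] - 1.0))
    hue = np.zeros_like(lightness)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.where(nz, ((g - b) / np.where(nz, delta, 1)) % 6.0, 0.0)
        hg = np.where(nz, (b - r) / np.where(nz, delta, 1) + 2.0, 0.0)
        hb = np.where(nz, (r - g) / np.where(nz, delta, 1) + 4.0, 0.0)
    hue = np.where(cmax == r, hr, np.where(cmax == g, hg, hb)) * 60.0
    hue = np.where(nz, hue % 360.0, 0.0)
    return np.stack([hue, np.clip(sat, 0, 1), lightness], axis=-1)


def hsl_to_rgb(hsl: np.ndarray) -> np.ndarray:
    """Vectorized HSL -> RGB (float [0,1])."""
    hsl = np.asarray(hsl, dtype=np.float64)
    h, s, lightness = hsl[..., 0] % 360.0, hsl[..., 1], hsl[..., 2]
    c = (1.0 - np.abs(2.0 * lightness - 1.0)) * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    zeros = np.zeros_like(c)
    conds = [(hp < 1), (hp < 2), (hp < 3), (hp < 4), (hp < 5), (hp < 6)]
    rgbs = [(c, x, zeros), (x, c, zeros), (zeros, c, x), (zeros, x, c), (x, zeros, c), (c, zeros, x)]
    r = np.select(conds, [t[0] for t in rgbs], zeros)
    g = np.select(conds, [t[1] for t in rgbs], zeros)
    b = np.select(conds, [t[2] for t in rgbs], zeros)
    m = lightness - c / 2.0
    return np.clip(np.stack([r + m, g + m, b + m], axis=-1), 0.0, 1.0)


def _as_float(image: np.ndarray) -> tuple[np.ndarray, bool]:
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.asarray(image, dtype=np.float64) / 255.0, True
    return np.asarray(image, dtype=np.float64), False


def _restore(image: np.ndarray, was_int: bool) -> np.ndarray:
    if was_int:
        return np.round(np.clip(image, 0, 1) * 255.0).astype(np.uint8)
    return image


# ---------------------------------------------------------------------------
# Lighting model
# ---------------------------------------------------------------------------

@dataclass
class LightingModel:
    """Means of the 4 uniform intervals of the corpus average-lightness histogram."""

    interval_means: tuple[float, float, float, float]

    def __post_init__(self):
        m = self.interval_means
        if not all(m[i] < m[i + 1] for i in range(3)):
            raise ValueError("interval means must be strictly increasing")
        if not all(0.0 <= v <= 1.0 for v in m):
            raise ValueError("interval means must lie in the lightness range [0,1]")


def average_lightness(image: np.ndarray) -> float:
    """Mean HSL lightness of one image."""
    f, _ = _as_float(image)
    return float(rgb_to_hsl(f)[..., 2].mean())


def fit_lighting_model(corpus: Sequence[np.ndarray]) -> LightingModel:
    """Split the histogram of per-image average lightness into 4 uniform
    intervals and take each interval's mean (centers fill empty intervals)."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    values = np.array([average_lightness(img) for img in corpus])
    lo, hi = values.min(), values.max()
    if hi - lo <= 1e-9:
        raise ValueError("degenerate lightness histogram: corpus has no lightness variance")
    edges = np.linspace(lo, hi, 5)
    means = []
    for k in range(4):
        sel = (values >= edges[k]) & (
            values <= edges[k + 1] if k == 3 else values < edges[k + 1]
        )
        means.append(values[sel].mean() if sel.any() else (edges[k] + edges[k + 1]) / 2)
    return LightingModel(tuple(float(v) for v in means))


def lighting_variants(image: np.ndarray, model: LightingModel) -> list[np.ndarray]:
    """Three images whose average lightness is rescaled to the means of
    intervals 2, 3 and 4 (multiplicative on L, clipped to [0,1])."""
    f, was_int = _as_float(image)
    hsl = rgb_to_hsl(f)
    avg = hsl[..., 2].mean()
    if avg <= 1e-9:
        raise ValueError("zero-lightness image: lightness scale undefined")
    out = []
    for target in model.interval_means[1:]:
        scaled = hsl.copy()
        scaled[..., 2] = np.clip(hsl[..., 2] * (target / avg), 0.0, 1.0)
        out.append(_restore(hsl_to_rgb(scaled), was_int))
    return out


# ---------------------------------------------------------------------------
# Geometric variants and random jitter
# ---------------------------------------------------------------------------

def _rotate(image: np.ndarray, angle: float, is_mask: bool) -> np.ndarray:
    order = 0 if is_mask else 1
    arr = np.asarray(image)
    out = _sk_rotate(
        arr.astype(np.float64), angle, resize=False, order=order, cval=0.0,
        preserve_range=True,
    )
    if arr.dtype == bool:
        return out > 0.5
    if np.issubdtype(arr.dtype, np.integer):
        return np.round(out).astype(arr.dtype)
    return out


def geometric_variants(image: np.ndarray, is_mask: bool = False) -> list[np.ndarray]:
    """7 rotations (45..315 deg, canvas unchanged, exposed corners black)
    plus horizontal and vertical mirrors; masks use nearest-neighbour."""
    arr = np.asarray(image)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("geometric variants require a square (letterboxed) image")
    variants = [_rotate(arr, angle, is_mask) for angle in range(45, 360, 45)]
    variants.append(arr[:, ::-1].copy())  # mirror across the vertical axis
    variants.append(arr[::-1, :].copy())  # mirror across the horizontal axis
    return variants


@dataclass
class JitterConfig:
    """Random-jitter ranges; fractions for translation, ratio pair for scale,
    degree pair for rotation."""

    translate_range: float = 0.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    rotate_range: tuple[float, float] = (0.0, 0.0)
    mirror: bool = False

    def __post_init__(self):
        if self.translate_range < 0:
            raise ValueError("translate_range must be non-negative")
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be well-ordered")
        if self.rotate_range[0] > self.rotate_range[1]:
            raise ValueError("rotate_range must be well-ordered")


#: jitter presets named in the YAML config
PRESETS = {
    "skin_net": JitterConfig(translate_range=0.10, scale_range=(0.90, 1.10)),
    "intervention_net": JitterConfig(
        translate_range=0.10, scale_range=(1.00, 1.25), rotate_range=(-45.0, 45.0), mirror=True
    ),
}


def draw_jitter_params(cfg: JitterConfig, rng: np.random.Generator) -> dict:
    return {
        "tx": rng.uniform(-cfg.translate_range, cfg.translate_range),
        "ty": rng.uniform(-cfg.translate_range, cfg.translate_range),
        "scale": rng.uniform(*cfg.scale_range),
        "angle": rng.uniform(*cfg.rotate_range),
        "flip_h": bool(cfg.mirror and rng.random() < 0.5),
        "flip_v": bool(cfg.mirror and rng.random() < 0.5),
    }


def apply_jitter(image: np.ndarray, params: dict, is_mask: bool = False) -> np.ndarray:
    """Apply one drawn jitter parameter set (center-anchored similarity)."""
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tfm = (
        AffineTransform(translation=-center)
        + AffineTransform(scale=params["scale"], rotation=np.deg2rad(params["angle"]))
        + AffineTransform(translation=center + [params["tx"] * w, params["ty"] * h])
    )
    order = 0 if is_mask else 1
    out = _sk_warp(
        arr.astype(np.float64), tfm.inverse, order=order, cval=0.0, preserve_range=True
    )
    if params["flip_h"]:
        out = out[:, ::-1]
    if params["flip_v"]:
        out = out[::-1, :]
    if arr.dtype == bool:
        return out > 0.5
    if np.issubdtype(arr.dtype, np.integer):
        return np.round(out).astype(arr.dtype)
    return out


def random_jitter(
    image: np.ndarray,
    cfg: JitterConfig,
    rng_seed: int,
    mask: np.ndarray | None = None,
):
    """One jittered sample, reproducible by seed; the mask (if given) is
    transformed with the same parameters."""
    rng = np.random.default_rng(rng_seed)
    params = draw_jitter_params(cfg, rng)
    out = apply_jitter(image, params, is_mask=False)
    if mask is None:
        return out
    return out, apply_jitter(mask, params, is_mask=True)
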