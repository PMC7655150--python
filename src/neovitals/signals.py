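"""PPGi and respiratory waveform extraction from segmented skin, validity
masking against the activity timeline, and rate estimation by peak counting.

The cardiac (PPGi) waveform is the spatial mean of the green channel over
the skin mask per frame; respiratory waveforms come from geometric
properties of the mask (area by default; centroid and perimeter are also
available). A rate over a window is simply ``peaks * 60 / duration``,
matching how rates are read off a strip chart.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks
from skimage.measure import perimeter as _sk_perimeter


@dataclass
class PhysiologicBand:
    """Plausible rate limits, events per minute, used to set the minimum
    peak separation. Defaults are neonatal."""

    min_rate: float
    max_rate: float

    def __post_init__(self):
        if not (0 < self.min_rate < self.max_rate):
            raise ValueError("band must satisfy 0 < min_rate < max_rate")


CARDIAC_BAND = PhysiologicBand(90.0, 240.0)
RESPIRATORY_BAND = PhysiologicBand(20.0, 120.0)


@dataclass
class VitalTimeSeries:
    """Waveform with sampling rate, kind and a per-sample validity mask."""

    samples: np.ndarray
    fs: float
    kind: str = "ppgi"  # ppgi | resp_area | resp_centroid | resp_perimeter
    valid: np.ndarray | None = None
    origin_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.valid is None:
            self.valid = np.ones(len(self.samples), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.samples):
            raise ValueError("validity mask length must equal sample length")

    def times(self) -> np.ndarray:
        return self.origin_time + np.arange(len(self.samples)) / self.fs

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class RateEstimate:
    """Rate in events/min derived from a peak count over a window."""

    rate: float
    peak_count: int
    window_duration: float


def extract_ppgi(seq, masks: Sequence[np.ndarray], channel: int = 1) -> VitalTimeSeries:
    """Spatial mean of one color channel over the skin mask, per frame.

    ``channel`` defaults to green. Frames with an empty mask yield an
    invalid sample (value 0).
    """
    frames = seq.frames
    if len(masks) != len(frames):
        raise ValueError("need one mask per frame")
    samples = np.zeros(len(frames))
    valid = np.zeros(len(frames), dtype=bool)
    for i, (frame, mask) in enumerate(zip(frames, masks)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != frame.shape[:2]:
            raise ValueError("mask/frame size mismatch")
        if mask.any():
            samples[i] = frame[..., channel][mask].mean()
            valid[i] = True
    return VitalTimeSeries(samples, fs=seq.fps, kind="ppgi", valid=valid,
                           origin_time=seq.origin_time)


def extract_resp(masks: Sequence[np.ndarray], fps: float,
                 origin_time: float = 0.0) -> dict[str, VitalTimeSeries]:
    """Respiratory candidate signals from mask geometry.

    Returns area (default respiratory signal), centroid row/column and
    perimeter series; empty-mask frames are invalid.
    """
    n = len(masks)
    area = np.zeros(n)
    cy = np.zeros(n)
    cx = np.zeros(n)
    perim = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        a = mask.sum()
        if a > 0:
            area[i] = a
            rows, cols = np.nonzero(mask)
            cy[i], cx[i] = rows.mean(), cols.mean()
            perim[i] = _sk_perimeter(mask)
            valid[i] = True
    mk = lambda s, kind: VitalTimeSeries(s, fs=fps, kind=kind, valid=valid.copy(),
                                         origin_time=origin_time)
    return {
        "area": mk(area, "resp_area"),
        "centroid_row": mk(cy, "resp_centroid"),
        "centroid_col": mk(cx, "resp_centroid"),
        "perimeter": mk(perim, "resp_perimeter"),
    }


def detrend(series: VitalTimeSeries, band: PhysiologicBand) -> VitalTimeSeries:
    """Subtract a moving-average baseline (window = 2x the slowest expected
    period) so slow illumination drift does not bias peak detection."""
    win = max(3, int(round(2 * 60.0 / band.min_rate * series.fs)))
    if win % 2 == 0:
        win += 1
    x = series.samples.copy()
    # invalid stretches (masked periods) carry arbitrary values; bridge
    # them by interpolation so they cannot drag the baseline near run edges
    if (~series.valid).any() and series.valid.any():
        idx = np.arange(len(x))
        x[~series.valid] = np.interp(idx[~series.valid], idx[series.valid],
                                     x[series.valid])
    if len(x) < 3:
        return VitalTimeSeries(x - x.mean(), series.fs, series.kind,
                               series.valid.copy(), series.origin_time)
    pad = win // 2
    xp = np.pad(x, pad, mode="reflect")
    baseline = np.convolve(xp, np.ones(win) / win, mode="valid")
    return VitalTimeSeries(x - baseline, series.fs, series.kind,
                           series.valid.copy(), series.origin_time)


def detect_peaks(series: VitalTimeSeries, band: PhysiologicBand,
                 min_prominence_frac: float = 0.2) -> np.ndarray:
    """Local maxima respecting the band's minimum separation, on valid
    samples only.

    The minimum peak distance is one period at ``band.max_rate``; the
    prominence floor is ``min_prominence_frac`` times the valid-sample
    standard deviation (0 disables it). Invalid runs are searched
    independently so peaks never straddle masked-out periods.
    """
    distance = max(1, int(np.floor(60.0 / band.max_rate * series.fs)))
    x = series.samples
    valid = series.valid
    if not valid.any():
        return np.array([], dtype=int)
    prominence = None
    if min_prominence_frac > 0:
        sd = x[valid].std()
        if sd > 0:
            prominence = min_prominence_frac * sd
    peaks: list[int] = []
    # split into contiguous valid runs
    idx = np.flatnonzero(valid)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if len(run) < 3:
            continue
        p, _ = find_peaks(x[run[0] : run[-1] + 1], distance=distance,
                          prominence=prominence)
        peaks.extend((p + run[0]).tolist())
    return np.array(sorted(peaks), dtype=int)


def rate_from_peaks(peak_count: int, window_duration: float) -> RateEstimate:
    """rate [events/min] = peak_count * 60 / window_duration."""
    if window_duration <= 0:
        raise ValueError("window duration must be positive")
    return RateEstimate(rate=peak_count * 60.0 / window_duration,
                        peak_count=int(peak_count),
                        window_duration=float(window_duration))


def estimate_rate(series: VitalTimeSeries, band: PhysiologicBand) -> RateEstimate:
    """Detrend, count peaks, convert to a rate.

    The denominator is the *valid* observation time: peaks are only
    counted during valid samples, so a partially masked segment must not
    dilute the rate. For a fully valid series this equals the series
    duration.
    """
    det = detrend(series, band)
    peaks = detect_peaks(det, band)
    valid_duration = series.valid.sum() / series.fs
    if valid_duration <= 0:
        return RateEstimate(rate=0.0, peak_count=0, window_duration=0.0)
    return rate_from_peaks(len(peaks), valid_duration)


def sliding_rates(series: VitalTimeSeries, band: PhysiologicBand,
                  segment: float = 30.0, step: float | None = None
                  ) -> list[tuple[float, float, RateEstimate]]:
    """Rates over sliding analysis segments (default 30 s, non-overlapping)."""
    step = segment if step is None else step
    out = []
    t0 = 0.0
    n = len(series.samples)
    while t0 + segment <= series.duration + 1e-9:
        i0 = int(round(t0 * series.fs))
        i1 = min(n, int(round((t0 + segment) * series.fs)))
        sub = VitalTimeSeries(series.samples[i0:i1], series.fs, series.kind,
                              series.valid[i0:i1], series.origin_time + t0)
        out.append((t0, t0 + segment, estimate_rate(sub, band)))
        t0 += step
    return out


def mask_invalid(series: VitalTimeSeries, timeline) -> VitalTimeSeries:
    """Invalidate samples falling in absent or intervention seconds.

    ``timeline`` is an ActivityTimeline covering the series' span; sample
    values are preserved, only the validity mask changes.
    """
    t = series.times()
    if t[0] < timeline.start_time - 1e-9 or t[-1] >= timeline.end_time + 1e-9:
        raise ValueError("timeline does not cover the series' time span")
    states = timeline.state_at(t)
    valid = series.valid & (states == "valid")
    return VitalTimeSeries(series.samples.copy(), series.fs, series.kind,
                           valid, series.origin_time)


def write_series_csv(path: str | Path, series: VitalTimeSeries) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "value", "valid"])
        for t, x, v in zip(series.times(), series.samples, series.valid):
            w.writerow([f"{t:.6f}", f"{x:.6f}", int(v)])


def write_rates_csv(path: str | Path,
                    rates: Iterable[tuple[float, float, RateEstimate]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_start", "t_end", "rate", "peaks"])
        for t0, t1, est in rates:
            w.writerow([f"{t0:.3f}", f"{t1:.3f}", f"{est.rate:.3f}", est.peak_count])
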