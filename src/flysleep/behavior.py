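"""Movement quantification and sleep-bout segmentation from video.

A fly is "moved" on a frame when the absolute difference to the previous
frame, binarized and dilated, contains a contour larger than an area
threshold.  Brief movement runs are pruned as noise; maximal immobile runs
of at least 5 min are sleep bouts.  The crepuscular profile z-scores
per-minute movement and bins it into the six printed twilight windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import dilation, footprint_rectangle

from .intervals import Bout, BoutSet, SLEEP_MIN_S, StageLabels, clock_at
from .intervals import segment_sleep_epochs as _segment

segment_sleep_epochs = _segment   # re-exported: stages are derived from bouts

CREPUSCULAR_WINDOWS = {           # clock hours, half-open
    "predawn": (5, 7), "dawn": (7, 9), "postdawn": (9, 11),
    "predusk": (17, 19), "dusk": (19, 21), "postdusk": (21, 23),
}


@dataclass
class MovementTrace:
    moved: np.ndarray              # binary per frame
    fps: float

    @property
    def per_minute_fraction(self) -> np.ndarray:
        f = int(round(60 * self.fps))
        n_min = self.moved.size // f
        if n_min == 0:
            return np.array([self.moved.mean()]) if self.moved.size else np.array([])
        return self.moved[:n_min * f].reshape(n_min, f).mean(axis=1)


@dataclass
class CrepuscularProfile:
    z_per_minute: np.ndarray
    period: np.ndarray             # window name or '' per minute
    clock_minute: np.ndarray       # clock time (s since midnight) per minute


def quantify_movement(frames: np.ndarray, pixel_threshold: float = 25.0,
                      area_threshold: float = 40.0,
                      fps: float = 30.0) -> MovementTrace:
    """Per-frame movement from a grayscale stack via frame differencing.

    |current - previous| -> binarize at ``pixel_threshold`` -> 3x3 dilation
    -> connected components; moved iff any component area exceeds
    ``area_threshold``.  Frame 0 is defined still.
    """
    frames = np.asarray(frames)
    if frames.ndim == 4:
        warnings.warn("color input converted to grayscale")
        frames = frames.mean(axis=-1)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 grayscale frames")
    if pixel_threshold <= 0 or area_threshold <= 0:
        raise ValueError("thresholds must be positive")
    f = frames.astype(np.int16)
    moved = np.zeros(frames.shape[0], dtype=np.int8)
    foot = footprint_rectangle((3, 3))
    for i in range(1, frames.shape[0]):
        delta = np.abs(f[i] - f[i - 1])
        mask = dilation(delta > pixel_threshold, foot)
        if not mask.any():
            continue
        lab, n = cc_label(mask, return_num=True)
        areas = np.bincount(lab.ravel())[1:]
        if areas.size and areas.max() > area_threshold:
            moved[i] = 1
    return MovementTrace(moved, fps)


def movement_from_magnitude(magnitude: np.ndarray, area_threshold: float = 40.0,
                            fps: float = 30.0) -> MovementTrace:
    """Movement trace from a precomputed per-frame contour-area series."""
    mag = np.asarray(magnitude, dtype=float)
    moved = (mag > area_threshold).astype(np.int8)
    if moved.size:
        moved[0] = 0
    return MovementTrace(moved, fps)


def prune_movement(trace: MovementTrace, min_run_frames: int = 15) -> MovementTrace:
    """Zero out movement runs shorter than ``min_run_frames`` (noise)."""
    if min_run_frames < 1:
        raise ValueError("min_run_frames must be >= 1")
    m = trace.moved.astype(np.int8).copy()
    n = m.size
    i = 0
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            if j - i < min_run_frames:
                m[i:j] = 0
            i = j
        else:
            i += 1
    return MovementTrace(m, trace.fps)


def label_states(trace: MovementTrace, clock_start: float = 0.0) -> BoutSet:
    """Sleep bouts = maximal immobile runs >= 5 min; the rest is awake.

    Day/night flags use the bout onset clock time (lights on 8 a.m.-8 p.m.).
    """
    fps = trace.fps
    m = trace.moved.astype(bool)
    n = m.size
    duration = n / fps
    min_frames = int(round(SLEEP_MIN_S * fps))
    bouts: list[Bout] = []
    i = 0
    cursor = 0.0
    while i < n:
        if not m[i]:
            j = i
            while j < n and not m[j]:
                j += 1
            if j - i >= min_frames:
                s, e = i / fps, j / fps
                if s > cursor:
                    bouts.append(Bout(cursor, s, "awake",
                                      _day(clock_start, cursor)))
                bouts.append(Bout(s, e, "sleep", _day(clock_start, s)))
                cursor = e
            i = j
        else:
            i += 1
    if cursor < duration:
        bouts.append(Bout(cursor, duration, "awake", _day(clock_start, cursor)))
    return BoutSet(bouts, duration, clock_start)


def _day(clock_start: float, t: float) -> bool:
    c = clock_at(clock_start, t)
    return 8 * 3600 <= c < 20 * 3600


def crepuscular_profile(trace: MovementTrace,
                        clock_start: float) -> CrepuscularProfile:
    """Per-minute movement fraction, z-scored per fly, binned into the six
    twilight windows (predawn 5-7 a.m. ... postdusk 9-11 p.m.)."""
    frac = trace.per_minute_fraction
    if frac.size == 0:
        raise ValueError("recording too short for a single minute")
    sd = frac.std()
    if sd == 0:
        warnings.warn("zero variance in movement: z-scores undefined, "
                      "emitting zeros")
        z = np.zeros_like(frac)
    else:
        z = (frac - frac.mean()) / sd
    clock = np.array([clock_at(clock_start, 60.0 * i + 30.0)
                      for i in range(frac.size)])
    period = np.full(frac.size, "", dtype=object)
    for name, (h0, h1) in CREPUSCULAR_WINDOWS.items():
        period[(clock >= h0 * 3600) & (clock < h1 * 3600)] = name
    if not (period != "").any():
        raise ValueError("recording overlaps no crepuscular window")
    return CrepuscularProfile(z, period, clock)


def bout_duration_stats(bouts: BoutSet) -> dict[str, float]:
    """Median sleep-bout duration (minutes) by day/night of bout onset."""
    day = [b.duration_s / 60 for b in bouts.sleep_bouts() if b.day_flag]
    night = [b.duration_s / 60 for b in bouts.sleep_bouts() if not b.day_flag]
    return {"day_median_min": float(np.median(day)) if day else float("nan"),
            "night_median_min": float(np.median(night)) if night else float("nan"),
            "n_day": len(day), "n_night": len(night)}
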