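"""Multichannel LFP preprocessing, referencing, epoching, localization.

The preprocessing chain mirrors standard EEG practice: resample to 250 Hz,
zero-phase Hamming windowed-sinc FIR bandpass 0.5-40 Hz, 50-Hz notch, and
linear interpolation across hourly file boundaries.  Re-referencing
subtracts the polarity-reversal channel (a brain-based reference, like a
Cz reference in human EEG) from every other channel, leaving 15 channels;
an alternative differential (bipolar) referencing subtracts neighbouring
channels pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .intervals import StageInterval, StageLabels, minute_label
from .synth import CalibrationRecording

CHANNEL_GROUPS = {
    "central": (1, 2, 3, 4, 5),
    "middle": (6, 7, 8, 9, 10),
    "peripheral": (12, 13, 14, 15, 16),
}

MIN_TRIALS = {60.0: 10, 1.0: 50}   # per-fly per-condition inclusion minima


@dataclass
class LFPRecording:
    data: np.ndarray               # (n_channels, n_samples)
    fs: float
    channel_ids: tuple[int, ...] = tuple(range(1, 17))
    clock_start: float = 0.0


@dataclass
class ReferencedLFP:
    data: np.ndarray               # (15, n_samples)
    fs: float
    reference_channel: int
    channel_ids: tuple[int, ...]   # original 1-based ids of retained rows
    clock_start: float = 0.0
    scheme: str = "common"         # 'common' | 'differential'

    def group_rows(self, group: str) -> np.ndarray:
        ids = CHANNEL_GROUPS[group]
        return np.array([self.channel_ids.index(c) for c in ids
                         if c in self.channel_ids])


@dataclass
class EpochSet:
    epochs: np.ndarray             # (n_epochs, n_channels, n_samples)
    fs: float
    epoch_s: float
    labels: np.ndarray             # per-epoch condition label
    minute_labels: np.ndarray      # per-epoch minute-relative tag
    bout_ids: np.ndarray
    channel_ids: tuple[int, ...]
    fly_id: int = 0


@dataclass
class ElectrodeTrack:
    site_coords: np.ndarray        # (n_sites, 3) in um, site 1 innermost
    eigenvector: np.ndarray        # unit 3-vector pointing outward
    spacing: float


def _bandpass_fir(fs: float, lo: float = 0.5, hi: float = 40.0,
                  trans_lo: float = 0.5, trans_hi: float = 10.0) -> np.ndarray:
    """Hamming windowed-sinc bandpass; odd length so 'same' convolution is
    exactly zero-phase."""
    width = min(trans_lo, trans_hi)
    numtaps = int(3.3 * fs / width)
    numtaps += (numtaps + 1) % 2
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                         window="hamming")


def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return signal.fftconvolve(x, taps[None, :], mode="same", axes=1)


def join_hourly_segments(segments: list[np.ndarray], fs: float,
                         blend_s: float = 1.0) -> np.ndarray:
    """Concatenate hourly chunks, linearly interpolating across boundaries
    to avoid step discontinuities."""
    if not segments:
        raise ValueError("no segments to join")
    out = [np.asarray(segments[0], dtype=float)]
    for seg in segments[1:]:
        seg = np.asarray(seg, dtype=float)
        prev = out[-1]
        nb = max(int(blend_s * fs), 1)
        jump = seg[:, :1] - prev[:, -1:]
        ramp = np.linspace(1.0, 0.0, min(nb, seg.shape[1]))[None, :]
        seg = seg.copy()
        seg[:, :ramp.shape[1]] -= jump * ramp
        out.append(seg)
    return np.concatenate(out, axis=1)


def preprocess(data: np.ndarray, fs: float, clock_start: float = 0.0,
               fs_target: float = 250.0) -> LFPRecording:
    """Resample to 250 Hz, zero-phase FIR bandpass 0.5-40 Hz, 50-Hz notch."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected (channels, samples)")
    if fs < 80.0:
        raise ValueError("sampling rate too low: need fs >= 80 Hz")
    if fs != fs_target:
        frac = Fraction(fs_target / fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=1)
    taps = _bandpass_fir(fs_target)
    data = _zero_phase(data, taps)
    b, a = signal.iirnotch(50.0, Q=25.0, fs=fs_target)
    data = signal.filtfilt(b, a, data, axis=1)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite samples after preprocessing")
    return LFPRecording(data, fs_target, tuple(range(1, data.shape[0] + 1)),
                        clock_start)


def detect_polarity_reversal(cal: CalibrationRecording,
                             window_s: float = 0.2,
                             baseline_s: float = 0.1) -> int:
    """Channel at which the stimulus-locked deflection flips sign.

    The evoked amplitude per channel is the mean signal in the 0-200 ms
    post-onset window minus the mean in the 100 ms before onset, averaged
    over onsets.  The reversal is the first zero-crossing of this profile
    scanning from channel 1 (central, negative) outward; between the two
    bracketing channels the one with the smaller magnitude is returned.
    """
    onsets = np.asarray(cal.stimulus_onsets, dtype=float)
    if onsets.size < 5:
        raise ValueError("need at least 5 stimulus onsets")
    fs = cal.fs
    nw, nb = int(window_s * fs), int(baseline_s * fs)
    profile = np.zeros(cal.lfp.shape[0])
    for on in onsets:
        i0 = int(round(on * fs))
        if i0 - nb < 0 or i0 + nw > cal.lfp.shape[1]:
            continue
        profile += (cal.lfp[:, i0:i0 + nw].mean(axis=1)
                    - cal.lfp[:, i0 - nb:i0].mean(axis=1))
    profile /= onsets.size
    # first crossing from negative (central) to positive (peripheral);
    # the reversal channel is the smallest-magnitude channel in between
    # (it may sit at an exact null)
    for j in range(1, len(profile)):
        if profile[j] > 0 and (profile[:j] < 0).any():
            i = int(np.flatnonzero(profile[:j] < 0)[-1])
            k = i + int(np.argmin(np.abs(profile[i:j + 1])))
            return k + 1
    raise ValueError("no polarity reversal found across channels")


def calibration_passes(reversal_channel: int) -> bool:
    """Insertion-depth criterion: the polarity reversal must sit on
    channels 11-13 for the recording to be spatially comparable."""
    return 11 <= reversal_channel <= 13


def rereference(lfp: LFPRecording, reference_channel: int) -> ReferencedLFP:
    """Common re-reference: subtract the reference channel from all others."""
    if not (1 <= reference_channel <= len(lfp.channel_ids)):
        raise ValueError("reference channel out of range")
    if len(lfp.channel_ids) != 16:
        raise ValueError(
            "re-referencing expects the full 16-channel recording; "
            "it cannot be applied twice")
    ref_row = lfp.channel_ids.index(reference_channel)
    keep = [i for i in range(lfp.data.shape[0]) if i != ref_row]
    data = lfp.data[keep] - lfp.data[ref_row][None, :]
    ids = tuple(lfp.channel_ids[i] for i in keep)
    return ReferencedLFP(data, lfp.fs, reference_channel, ids,
                         lfp.clock_start, "common")


def differential_rereference(lfp: LFPRecording) -> ReferencedLFP:
    """Bipolar referencing: channel k+1 minus channel k, 15 outputs."""
    if lfp.data.shape[0] != 16:
        raise ValueError("expected 16 channels")
    data = lfp.data[1:] - lfp.data[:-1]
    ids = tuple(lfp.channel_ids[:-1])
    return ReferencedLFP(data, lfp.fs, 0, ids, lfp.clock_start, "differential")


def epoch_by_labels(lfp: ReferencedLFP,
                    intervals: list[StageInterval] | StageLabels,
                    epoch_s: float, fly_id: int = 0,
                    label_map=None) -> EpochSet:
    """Tile each labeled interval into non-overlapping epochs of ``epoch_s``.

    Tiling starts at each interval's onset; a tail shorter than ``epoch_s``
    is dropped.  ``label_map`` optionally renames interval stages to
    condition labels (e.g. midsleep -> sleep).
    """
    if isinstance(intervals, StageLabels):
        intervals = intervals.intervals
    fs = lfp.fs
    ns = int(round(epoch_s * fs))
    n_total = lfp.data.shape[1]
    chunks, labels, minutes, bids = [], [], [], []
    for iv in intervals:
        lab = label_map(iv) if label_map is not None else iv.stage
        if lab is None:
            continue
        i0 = int(round(iv.start_s * fs))
        i1 = min(int(round(iv.end_s * fs)), n_total)
        k = 0
        while i0 + (k + 1) * ns <= i1:
            chunks.append(lfp.data[:, i0 + k * ns: i0 + (k + 1) * ns])
            labels.append(lab)
            minutes.append(minute_label(iv, k * epoch_s))
            bids.append(iv.bout_id)
            k += 1
    if not chunks:
        import warnings
        warnings.warn("no interval long enough for a single epoch")
        epochs = np.empty((0, lfp.data.shape[0], ns), dtype=np.float32)
    else:
        epochs = np.stack(chunks).astype(np.float32)
    return EpochSet(epochs, fs, epoch_s, np.asarray(labels, dtype=object),
                    np.asarray(minutes, dtype=object),
                    np.asarray(bids), lfp.channel_ids, fly_id)


def meets_trial_minimum(epochs: EpochSet, conditions: list[str],
                        minimum: int | None = None) -> bool:
    """Per-fly inclusion rule: every condition needs its minimum trial count
    (10 for 60-s sleep/wake epochs, 50 for 1-s PE epochs)."""
    if minimum is None:
        minimum = MIN_TRIALS.get(epochs.epoch_s, 1)
    return all(int(np.sum(epochs.labels == c)) >= minimum for c in conditions)


def localize_electrodes(dye_points: np.ndarray, spacing: float = 25.0,
                        n_sites: int = 16,
                        midline: np.ndarray | None = None) -> ElectrodeTrack:
    """Electrode sites from dye fragments: PCA line fit + 25-um sampling.

    The probe axis is the first principal component of the dye points.  The
    innermost site (channel 1) is the projection of the innermost dye point
    onto this line, where "innermost" means nearest the brain midline
    (``midline``, default the template-space origin); the eigenvector is
    oriented so that larger channel indices lie toward the periphery.
    """
    pts = np.asarray(dye_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("need at least two 3-D dye points")
    if midline is None:
        midline = np.zeros(3)
    center = pts.mean(axis=0)
    X = pts - center
    if np.allclose(X, 0):
        raise ValueError("dye points are coincident")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    v = vt[0]
    proj = X @ v
    if proj.max() - proj.min() <= 0:
        raise ValueError("dye points are coincident")
    lo = center + proj.min() * v
    hi = center + proj.max() * v
    # innermost end = nearer the midline; orient v outward from it
    if np.linalg.norm(hi - midline) < np.linalg.norm(lo - midline):
        lo, v = hi, -v
    sites = lo[None, :] + spacing * np.arange(n_sites)[:, None] * v[None, :]
    return ElectrodeTrack(sites, v, spacing)
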