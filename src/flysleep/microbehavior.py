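"""Proboscis-extension (PE) detection and antennal periodicity from pose.

PEs are found by an rbf-kernel SVM over filtered pose features (plus a
likelihood-threshold augmentation rule for occluded frames), grouped into
events and 10-s bursts.  A PE is "periodic" when it follows its
predecessor by less than 6 s.  Antennal motion is converted to a
head-axis-corrected angle and classified as periodic per segment by the
dominance of its FFT peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .intervals import BoutSet, StageLabels

PE_FEATURE_PARTS = ("proboscis", "leg1_tip", "leg1_joint", "eye", "abdomen")
BURST_GAP_S = 10.0        # events within 10 s share a burst
PERIODIC_GAP_S = 6.0      # a PE <6 s after its predecessor is periodic
EVENT_MERGE_GAP_S = 0.2   # candidate frames closer than this merge


# ------------------------------------------------------------ pose filtering

def filter_pose(pose: pd.DataFrame, fps: float,
                lowpass_hz: float = 0.1, ma_window: int = 5) -> pd.DataFrame:
    """Per body part: 0.1-Hz Butterworth low-pass baseline and a 5-sample
    moving average, kept as derived columns alongside the raw trace."""
    n = len(pose)
    if n < 30:
        raise ValueError("trace shorter than the filter warm-up")
    b, a = signal.butter(2, lowpass_hz, fs=fps)
    out = pose.copy()
    kernel = np.ones(ma_window) / ma_window
    pad = ma_window // 2
    for col in pose.columns:
        if col.endswith(("_x", "_y", "_likelihood")):
            x = pose[col].to_numpy(float)
            lp = signal.filtfilt(b, a, x)
            ma = np.convolve(np.pad(lp, pad, mode="edge"), kernel,
                             mode="same")[pad:pad + n]
            out[col + "_lp"] = lp
            out[col + "_ma"] = ma
    return out


def dist_eyeprob(pose: pd.DataFrame) -> np.ndarray:
    """Eye-proboscis Euclidean distance weighted by proboscis likelihood."""
    for part in ("eye", "proboscis"):
        if f"{part}_x" not in pose.columns:
            raise ValueError(f"missing body part {part!r}")
    d = np.hypot(pose.proboscis_x - pose.eye_x,
                 pose.proboscis_y - pose.eye_y)
    return (d * pose.proboscis_likelihood).to_numpy(float)


def proboscis_displacement(pose: pd.DataFrame) -> np.ndarray:
    """Raw distance of the proboscis from its median (resting) position."""
    rx = np.median(pose.proboscis_x)
    ry = np.median(pose.proboscis_y)
    return np.hypot(pose.proboscis_x - rx, pose.proboscis_y - ry).to_numpy(float)


# -------------------------------------------------------------- PE detection

def _pe_features(pose: pd.DataFrame, fps: float) -> np.ndarray:
    f = filter_pose(pose, fps)
    cols = []
    for part in PE_FEATURE_PARTS:
        for ax in ("x", "y"):
            for suff in ("", "_lp", "_ma"):
                cols.append(f.get(f"{part}_{ax}{suff}",
                                  pd.Series(np.zeros(len(f)))).to_numpy(float))
            cols.append(np.gradient(f[f"{part}_{ax}_ma"].to_numpy(float)))
    cols.append(dist_eyeprob(pose))
    return np.column_stack(cols)


def truth_pe_frame_mask(n_frames: int, fps: float,
                        pe_times: np.ndarray, half_width_s: float = 0.2
                        ) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for t in np.asarray(pe_times, float):
        a = int(round((t - half_width_s) * fps))
        b = int(round((t + half_width_s) * fps)) + 1
        mask[max(a, 0):min(b, n_frames)] = True
    return mask


@dataclass
class PEFrameDetection:
    candidate_frames: np.ndarray   # boolean per frame
    frame_accuracy: float          # on the held-out 30%
    report_frames: np.ndarray      # held-out frame indices


def detect_pe_frames(pose: pd.DataFrame, truth_mask: np.ndarray, fps: float,
                     seed: int = 0, likelihood_threshold: float = 0.9,
                     max_train: int = 4000) -> PEFrameDetection:
    """rbf-kernel SVM over pose features; candidates on all frames.

    The classifier trains on a 70/30 split of labeled example frames
    (negatives downsampled to keep the problem desk-scale).  Candidate
    frames are its positive predictions on the whole trace, augmented by a
    likelihood rule: frames where the smoothed proboscis likelihood drops
    below ``likelihood_threshold`` while the raw displacement from rest is
    large are kept even if the classifier (whose distance feature is
    likelihood-weighted) missed them.
    """
    truth_mask = np.asarray(truth_mask, bool)
    if truth_mask.all() or not truth_mask.any():
        raise ValueError("need both PE and non-PE example frames")
    X = _pe_features(pose, fps)
    y = truth_mask.astype(int)
    idx = np.arange(len(y))
    itr, ite = train_test_split(idx, test_size=0.3, stratify=y,
                                random_state=seed)
    # downsample training negatives
    rng = np.random.default_rng(seed)
    pos = itr[y[itr] == 1]
    neg = itr[y[itr] == 0]
    n_neg = min(len(neg), max(3 * len(pos), 500), max_train)
    neg = rng.choice(neg, size=n_neg, replace=False)
    itr_b = np.concatenate([pos, neg])
    scaler = StandardScaler().fit(X[itr_b])
    clf = SVC(kernel="rbf", random_state=seed)
    clf.fit(scaler.transform(X[itr_b]), y[itr_b])
    pred_all = clf.predict(scaler.transform(X)).astype(bool)
    acc = accuracy_score(y[ite], pred_all[ite])
    # likelihood augmentation for occluded extensions
    lik = pose["proboscis_likelihood"].to_numpy(float)
    kernel = np.ones(5) / 5
    lik_s = np.convolve(lik, kernel, mode="same")
    disp = proboscis_displacement(pose)
    thr = np.median(disp) + 4 * (np.median(np.abs(disp - np.median(disp)))
                                 + 1e-9)
    augmented = (lik_s < likelihood_threshold) & (disp > max(thr, 2.0))
    return PEFrameDetection(pred_all | augmented, float(acc), ite)


# ----------------------------------------------------------- event building

@dataclass
class PEEvent:
    peak_frame: int
    time_s: float
    state: str
    burst_id: int
    periodic: bool = False


@dataclass
class PEBurst:
    events: list[PEEvent]
    inter_pe_intervals: np.ndarray

    @property
    def is_single(self) -> bool:
        return len(self.events) == 1


def _state_at(t: float, stages: StageLabels | None) -> str:
    if stages is None:
        return "unknown"
    for iv in stages.intervals:
        if iv.start_s <= t < iv.end_s:
            if iv.stage in ("earlysleep", "midsleep", "latesleep"):
                return "sleep"
            if iv.stage == "presleep":
                return "presleep"
            return "awake"
    return "awake"


def construct_pe_events(candidates: np.ndarray, pose: pd.DataFrame,
                        fps: float, stages: StageLabels | None = None
                        ) -> tuple[list[PEEvent], list[PEBurst]]:
    """Candidate frames -> events (peak = max displacement) -> 10-s bursts,
    with periodic flags from the <6-s predecessor/successor rule."""
    cand = np.asarray(candidates, bool)
    disp = proboscis_displacement(pose)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return [], []
    gap = int(round(EVENT_MERGE_GAP_S * fps))
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    events: list[PEEvent] = []
    min_sep = max(int(round(0.5 * fps)), 1)
    for (a, b) in runs:
        seg = disp[a:b + 1]
        # a candidate run is a proboscis period and may hold several
        # extensions: one event per local displacement peak
        peaks, _ = signal.find_peaks(seg, distance=min_sep,
                                     prominence=0.5 * max(seg.max(), 1e-9))
        if peaks.size == 0:
            peaks = np.array([int(np.argmax(seg))])
        for p in peaks:
            peak = a + int(p)
            t = peak / fps
            events.append(PEEvent(peak, t, _state_at(t, stages), -1))
    # bursts: successive events within 10 s
    bursts: list[PEBurst] = []
    cur: list[PEEvent] = []
    for ev in events:
        if cur and ev.time_s - cur[-1].time_s > BURST_GAP_S:
            bursts.append(_close_burst(cur, len(bursts)))
            cur = []
        cur.append(ev)
    if cur:
        bursts.append(_close_burst(cur, len(bursts)))
    # periodic flags: <6 s after a predecessor; the first event of a run is
    # periodic iff its successor is <6 s away
    times = np.array([e.time_s for e in events])
    for i, ev in enumerate(events):
        prev_ok = i > 0 and times[i] - times[i - 1] < PERIODIC_GAP_S
        succ_ok = (i + 1 < len(events)
                   and times[i + 1] - times[i] < PERIODIC_GAP_S)
        ev.periodic = prev_ok or succ_ok
    return events, bursts


def _close_burst(evts: list[PEEvent], bid: int) -> PEBurst:
    for e in evts:
        e.burst_id = bid
    ivals = np.diff([e.time_s for e in evts])
    return PEBurst(list(evts), ivals)


def match_events(detected_s: np.ndarray, truth_s: np.ndarray,
                 tol_s: float = 0.5) -> dict:
    """Greedy one-to-one matching of detected to truth event times.

    Accuracy = TP / (TP + FN + FP): the fraction of all real-plus-reported
    events that are correctly detected.
    """
    det = np.sort(np.asarray(detected_s, float))
    tru = np.sort(np.asarray(truth_s, float))
    used = np.zeros(det.size, bool)
    tp = 0
    for t in tru:
        if det.size == 0:
            break
        i = int(np.argmin(np.abs(det - t) + used * 1e9))
        if not used[i] and abs(det[i] - t) <= tol_s:
            used[i] = True
            tp += 1
    fn = tru.size - tp
    fp = det.size - tp
    denom = tp + fn + fp
    return {"tp": tp, "fn": fn, "fp": fp,
            "accuracy": tp / denom if denom else float("nan")}


# ------------------------------------------------------------- statistics

SEGMENT_ORDER = ("-2:-1", "-1:0", "+0:+1", "+1:+2", "mid", "x-2:x-1", "x-1:x")


def pe_statistics(events: list[PEEvent], bursts: list[PEBurst],
                  stages: StageLabels | None = None) -> dict:
    """Interval distribution, single/multiple counts, periodic flags, and
    normalized event counts per sleep segment, plus before/after-minute-5
    counts for sleep and awake bouts."""
    ivals = np.concatenate([b.inter_pe_intervals for b in bursts]) \
        if bursts else np.array([])
    out: dict = {
        "n_events": len(events),
        "n_bursts": len(bursts),
        "n_single": sum(b.is_single for b in bursts),
        "n_multiple": sum(not b.is_single for b in bursts),
        "inter_pe_intervals": ivals,
        "interval_p95": float(np.percentile(ivals, 95)) if ivals.size else
        float("nan"),
        "fraction_single": (sum(b.is_single for b in bursts) / len(bursts))
        if bursts else float("nan"),
        "periodic_fraction": (np.mean([e.periodic for e in events])
                              if events else float("nan")),
    }
    if stages is not None:
        seg_counts = {s: 0 for s in SEGMENT_ORDER}
        seg_time = {s: 0.0 for s in SEGMENT_ORDER}
        for iv in stages.intervals:
            segs: list[tuple[str, float, float]] = []
            if iv.stage == "presleep":
                mid = (iv.start_s + iv.end_s) / 2
                segs = [("-2:-1", iv.start_s, mid), ("-1:0", mid, iv.end_s)]
            elif iv.stage == "earlysleep":
                mid = (iv.start_s + iv.end_s) / 2
                segs = [("+0:+1", iv.start_s, mid), ("+1:+2", mid, iv.end_s)]
            elif iv.stage == "latesleep":
                mid = (iv.start_s + iv.end_s) / 2
                segs = [("x-2:x-1", iv.start_s, mid), ("x-1:x", mid, iv.end_s)]
            elif iv.stage == "midsleep":
                segs = [("mid", iv.start_s, iv.end_s)]
            for name, a, b in segs:
                seg_time[name] += b - a
                seg_counts[name] += sum(a <= e.time_s < b for e in events)
        total = sum(seg_counts.values())
        out["segment_counts"] = seg_counts
        out["segment_normalized"] = {
            s: (seg_counts[s] / total if total else 0.0)
            for s in SEGMENT_ORDER}
        # events before vs after minute 5 of each sleep bout (and awake
        # bouts as control)
        def split5(kind):
            before = after = 0
            for b in stages_bouts(stages, kind):
                for e in events:
                    if b[0] <= e.time_s < b[1]:
                        if e.time_s - b[0] < 300:
                            before += 1
                        else:
                            after += 1
            return before, after
        out["sleep_before5"], out["sleep_after5"] = split5("sleep")
        out["awake_before5"], out["awake_after5"] = split5("awake")
        mid_pos = []
        for iv in stages.of_stage("midsleep"):
            for e in events:
                if iv.start_s <= e.time_s < iv.end_s:
                    mid_pos.append(e.time_s - iv.start_s)
        out["midsleep_event_offsets_s"] = np.asarray(mid_pos)
    return out


def stages_bouts(stages: StageLabels, kind: str) -> list[tuple[float, float]]:
    """Reconstruct bout spans from stage intervals (sleep = early+mid+late)."""
    if kind == "sleep":
        spans: dict[int, list[float]] = {}
        for iv in stages.intervals:
            if iv.stage in ("earlysleep", "midsleep", "latesleep"):
                spans.setdefault(iv.bout_id, [np.inf, -np.inf])
                spans[iv.bout_id][0] = min(spans[iv.bout_id][0], iv.start_s)
                spans[iv.bout_id][1] = max(spans[iv.bout_id][1], iv.end_s)
        return [tuple(v) for v in spans.values()]
    return [(iv.start_s, iv.end_s) for iv in stages.of_stage("awake")]


# ------------------------------------------------------------------ antenna

def antennal_angle(pose: pd.DataFrame, side: str = "left") -> np.ndarray:
    """Head-axis-corrected antennal angle, degrees, counterclockwise.

    The head axis is the left-base -> right-base direction; the antennal
    angle is atan2(tip - base) minus the head-axis angle, so whole-head
    rotation leaves it unchanged.  Coincident base/tip frames yield NaN.
    """
    for col in (f"{side}_antenna_base_x", f"{side}_antenna_tip_x",
                "left_antenna_base_x", "right_antenna_base_x"):
        if col not in pose.columns:
            raise ValueError(f"missing column {col}")
    hx = pose.right_antenna_base_x - pose.left_antenna_base_x
    hy = pose.right_antenna_base_y - pose.left_antenna_base_y
    head = np.arctan2(hy, hx)
    dx = pose[f"{side}_antenna_tip_x"] - pose[f"{side}_antenna_base_x"]
    dy = pose[f"{side}_antenna_tip_y"] - pose[f"{side}_antenna_base_y"]
    ang = np.degrees(np.arctan2(dy, dx) - head)
    ang = (np.asarray(ang) + 180.0) % 360.0 - 180.0
    coincident = (np.asarray(dx) == 0) & (np.asarray(dy) == 0)
    ang[coincident] = np.nan
    return ang


@dataclass
class PeriodicityResult:
    segment_starts_s: np.ndarray
    periodic: np.ndarray           # boolean per segment
    dominant_freq: np.ndarray      # Hz per segment
    fraction_sleep: float
    fraction_wake: float


def periodicity_segments(angle: np.ndarray, fps: float, segment_s: float = 30.0,
                         power_ratio_threshold: float | None = None,
                         bouts: BoutSet | None = None,
                         min_freq: float | None = None,
                         max_missing: float = 0.5) -> PeriodicityResult:
    """FFT periodicity per segment: periodic iff the dominant in-band peak
    exceeds ``power_ratio_threshold`` times the median spectral power.

    ``min_freq`` defaults to 10 cycles per segment, the slowest rhythm the
    segment can attest.  The default threshold is calibrated on the
    white-noise null: periodogram bins of noise are near-exponential with
    median = ln 2 x mean, so P(max/median > r) ~ n exp(-r ln 2) over n band
    bins, and r = log2(n / 0.05) keeps the false-positive rate near 5%."""
    if min_freq is None:
        min_freq = 10.0 / segment_s
    if segment_s < 10.0 / min_freq:
        raise ValueError("segment too short for the minimum frequency")
    nseg = int(round(segment_s * fps))
    n = len(angle) // nseg
    starts, flags, freqs = [], [], []
    for i in range(n):
        seg = np.asarray(angle[i * nseg:(i + 1) * nseg], float)
        missing = ~np.isfinite(seg)
        if missing.mean() > max_missing:
            continue
        seg = seg[np.isfinite(seg)]
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
        f = np.fft.rfftfreq(seg.size, 1.0 / fps)
        band = (f >= min_freq) & (f <= 5.0)
        if not band.any() or np.median(spec[band]) == 0:
            continue
        if power_ratio_threshold is None:
            power_ratio_threshold = float(np.log2(band.sum() / 0.05))
        ratio = spec[band].max() / np.median(spec[band])
        starts.append(i * segment_s)
        flags.append(bool(ratio > power_ratio_threshold))
        freqs.append(float(f[band][np.argmax(spec[band])]))
    starts = np.asarray(starts)
    flags = np.asarray(flags, bool)
    freqs = np.asarray(freqs)
    fs_sleep = fs_wake = float("nan")
    if bouts is not None and starts.size:
        def frac(kind):
            sel = []
            for s in starts:
                mid = s + segment_s / 2
                for b in bouts.bouts:
                    if b.start_s <= mid < b.end_s:
                        sel.append(b.kind == kind)
                        break
            sel = np.array(sel)
            rel = flags[sel] if sel.any() else np.array([])
            return float(rel.mean()) if rel.size else float("nan")
        fs_sleep, fs_wake = frac("sleep"), frac("awake")
    return PeriodicityResult(starts, flags, freqs, fs_sleep, fs_wake)


# --------------------------------------------- behavioral-rig PE detection

def resting_pe_detection(pose: pd.DataFrame, fps: float,
                         max_distance: float | None = None,
                         min_rise_s: float = 0.05,
                         prominence: float = 2.0) -> pd.DataFrame:
    """Peak-based PE detection from the distance to the median resting
    position, with artifact exclusions: peaks beyond a plausible distance,
    single-frame spikes, or implausibly fast rises are dropped."""
    disp = proboscis_displacement(pose)
    rx = np.median(pose.proboscis_x)
    ry = np.median(pose.proboscis_y)
    ang = np.degrees(np.arctan2(pose.proboscis_y - ry, pose.proboscis_x - rx))
    if max_distance is None:
        max_distance = 10 * (np.median(np.abs(disp - np.median(disp))) + 1.0)
    peaks, props = signal.find_peaks(disp, prominence=prominence,
                                     width=(None, None), rel_height=0.9)
    rows = []
    for p, w, li in zip(peaks, props["widths"], props["left_ips"]):
        if disp[p] > max_distance:
            continue                      # implausible distance
        if w <= 1.0:
            continue                      # single-frame spike
        rise_frames = p - li
        if rise_frames < min_rise_s * fps:
            continue                      # implausible instantaneous rise
        rows.append((int(p), p / fps, float(disp[p]), float(w / fps),
                     float(ang.iloc[p] if hasattr(ang, "iloc") else ang[p])))
    df = pd.DataFrame(rows, columns=["peak_frame", "time_s", "amplitude",
                                     "duration_s", "angle_deg"])
    if len(df):
        gaps = np.diff(df.time_s.to_numpy(), prepend=-np.inf)
        succ = np.diff(df.time_s.to_numpy(), append=np.inf)
        df["periodic"] = (gaps < PERIODIC_GAP_S) | (
            ~(gaps < PERIODIC_GAP_S) & (succ < PERIODIC_GAP_S))
    else:
        df["periodic"] = pd.Series(dtype=bool)
    return df


def threshold_pe_events(pose: pd.DataFrame, fps: float,
                        threshold: float) -> pd.DataFrame:
    """Alternative detector: runs where displacement exceeds a manual
    threshold, with per-event duration and median angle."""
    disp = proboscis_displacement(pose)
    rx, ry = np.median(pose.proboscis_x), np.median(pose.proboscis_y)
    ang = np.degrees(np.arctan2(pose.proboscis_y - ry,
                                pose.proboscis_x - rx)).to_numpy()
    above = disp > threshold
    rows = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            rows.append((i / fps, (j - i) / fps,
                         float(np.median(ang[i:j]))))
            i = j
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start_s", "duration_s",
                                       "median_angle_deg"])
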