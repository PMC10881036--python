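"""Ground-truth-labeled synthetic sessions.

A session bundles everything the pipeline consumes: a 16-channel LFP, a
movement readout (per-frame magnitude series or small grayscale frames), a
pose table, and truth labels (state sequence, PE events, antennal periodic
segments, polarity-reversal channel).

The LFP model is 1/f-colored background noise plus band-limited Gaussian
components whose amplitudes are modulated, per second and per channel, by
the dB gains declared in :class:`~flysleep.config.SessionConfig`.  The 5-40
Hz range is partitioned into four disjoint bands ([5,10), [10,30), [30,32),
[32,40]) so that every configured spectral contrast lands in its own band
and the realized dB difference equals the configured gain.  A common-mode
component (concentrated below 5 Hz, emulating heartbeat-like physiological
noise shared by all electrodes) is added to every channel to exercise
re-referencing.  The polarity-reversal channel carries attenuated band
components, emulating the amplitude null at the reversal point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SessionConfig
from .intervals import (Bout, BoutSet, StageLabels, SLEEP_MIN_S, STAGE_WIN_S,
                        is_day, segment_sleep_epochs)

CENTRAL_CH = tuple(range(1, 6))      # channels 1-5 (1-based)
MIDDLE_CH = tuple(range(6, 11))      # channels 6-10
PERIPHERAL_CH = tuple(range(12, 17))  # channels 12-16
STAGE_SIGNATURE_CH = (1, 2, 3)       # carries the 5-10 Hz stage profile

_BANDS = ((5.0, 10.0), (10.0, 30.0), (30.0, 32.0), (32.0, 40.0))
_REVERSAL_ATTEN_DB = -13.0           # band-component null at the reversal site
_BACKGROUND_DB = -13.0               # 1/f PSD at 10 Hz rel. to band density

POSE_PARTS = ("proboscis", "eye", "leg1_tip", "leg1_joint",
              "leg3_tip", "leg3_joint", "abdomen")
ANTENNA_PARTS = ("left_antenna_base", "left_antenna_tip",
                 "right_antenna_base", "right_antenna_tip")


@dataclass
class Truth:
    bouts: BoutSet
    stages: StageLabels
    pe_events: pd.DataFrame          # time_s, state, burst_id, occluded
    pe_bursts: pd.DataFrame          # start_s, end_s, state, n_events
    antenna_periodic: list[tuple[float, float]]
    reversal_channel: int


@dataclass
class SyntheticSession:
    config: SessionConfig
    lfp: np.ndarray | None           # (16, n_samples) float32
    fs: float
    movement_magnitude: np.ndarray | None  # per-frame contour area, a.u.
    frames: np.ndarray | None        # (T, 48, 64) uint8 when frames_mode='frames'
    fps: float
    pose: pd.DataFrame | None        # wide per-frame pose table
    truth: Truth
    clock_start: float
    fly_id: int = 0


@dataclass
class CalibrationRecording:
    lfp: np.ndarray                  # (16, n_samples)
    fs: float
    stimulus_onsets: np.ndarray      # s
    truth_reversal: int


# ---------------------------------------------------------------- bout truth

def generate_bouts(config: SessionConfig, rng: np.random.Generator) -> BoutSet:
    """Alternating wake/sleep renewal process with lognormal sleep bouts."""
    T = config.duration
    mu, sigma = config.sleep_bout_duration
    mean_sleep = float(np.exp(mu + sigma ** 2 / 2))
    if config.sleep_bout_rate > 0:
        mean_wake = max(150.0, 3600.0 / config.sleep_bout_rate - mean_sleep)
    else:
        mean_wake = np.inf
    bouts: list[Bout] = []
    t = 0.0
    while t < T:
        w = float(rng.exponential(mean_wake)) if np.isfinite(mean_wake) else T
        w = max(w, 150.0)
        w_end = min(t + w, T)
        if w_end > t:
            bouts.append(Bout(t, w_end, "awake", is_day(config.clock_start, t)))
        t = w_end
        if t >= T:
            break
        d = float(rng.lognormal(mu, sigma))
        if not is_day(config.clock_start, t):
            d *= config.night_duration_factor
        d = max(d, SLEEP_MIN_S + 5.0)
        s_end = min(t + d, T)
        if s_end - t < SLEEP_MIN_S:
            # truncated below the criterion: the fly never slept long enough
            bouts.append(Bout(t, s_end, "awake", is_day(config.clock_start, t)))
        else:
            bouts.append(Bout(t, s_end, "sleep", is_day(config.clock_start, t)))
        t = s_end
    # merge adjacent awake bouts
    merged: list[Bout] = []
    for b in bouts:
        if merged and merged[-1].kind == b.kind == "awake":
            merged[-1] = Bout(merged[-1].start_s, b.end_s, "awake",
                              merged[-1].day_flag)
        else:
            merged.append(b)
    return BoutSet(merged, T, config.clock_start)


def sleep_fraction(bouts: BoutSet) -> float:
    return sum(b.duration_s for b in bouts.sleep_bouts()) / bouts.duration_s


# ------------------------------------------------------------------ PE truth

def _place_bursts(intervals: list[tuple[float, float]], rate_per_min: float,
                  state: str, cfg: SessionConfig, rng: np.random.Generator,
                  rows: list, next_burst_id: int) -> int:
    pb = cfg.pe_burst
    for (s, e) in intervals:
        n = rng.poisson(rate_per_min * (e - s) / 60.0)
        for _ in range(n):
            L = int(rng.geometric(pb.p_single)) if pb.p_single > 0 else 4
            ivals = rng.normal(pb.inter_pe_interval_mean,
                               pb.inter_pe_interval_sd, size=max(L - 1, 0))
            ivals = np.clip(ivals, 0.8, 5.0)
            span = float(ivals.sum())
            t0 = float(rng.uniform(s + 1.0, max(e - span - 1.0, s + 1.0)))
            if t0 + span > e - 0.5:
                continue
            times = t0 + np.concatenate([[0.0], np.cumsum(ivals)])
            for tt in times:
                rows.append((float(tt), state, next_burst_id,
                             bool(rng.random() < pb.occlusion_fraction)))
            next_burst_id += 1
    return next_burst_id


def generate_pe_truth(config: SessionConfig, stages: StageLabels,
                      rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place PE bursts: mostly in midsleep, fewer in wake and flanking stages."""
    pb = config.pe_burst
    rows: list = []
    bid = 0
    mids = [(iv.start_s, iv.end_s) for iv in stages.of_stage("midsleep")
            if iv.duration_s > 10]
    wakes = [(iv.start_s, iv.end_s) for iv in stages.of_stage("awake")
             if iv.duration_s > 10]
    flanks = [(iv.start_s, iv.end_s) for st in
              ("earlysleep", "latesleep", "presleep")
              for iv in stages.of_stage(st) if iv.duration_s > 10]
    bid = _place_bursts(mids, pb.rate_midsleep_per_min, "sleep", config, rng,
                        rows, bid)
    bid = _place_bursts(wakes, pb.rate_wake_per_min, "awake", config, rng,
                        rows, bid)
    # flanking segments: early/late are sleep, presleep is awake behaviourally
    bid = _place_bursts(flanks, pb.rate_flank_per_min, "sleep",
                        config, rng, rows, bid)
    ev = pd.DataFrame(rows, columns=["time_s", "state", "burst_id", "occluded"])
    ev = ev.sort_values("time_s").reset_index(drop=True)
    # fix flank states: presleep is behaviorally awake but tagged apart
    for iv in stages.of_stage("presleep"):
        m = (ev.time_s >= iv.start_s) & (ev.time_s < iv.end_s)
        ev.loc[m, "state"] = "presleep"
    if len(ev):
        g = ev.groupby("burst_id")
        bursts = pd.DataFrame({
            "start_s": g.time_s.min(), "end_s": g.time_s.max(),
            "state": g.state.first(), "n_events": g.size()}).reset_index()
    else:
        bursts = pd.DataFrame(columns=["burst_id", "start_s", "end_s",
                                       "state", "n_events"])
    return ev, bursts


# ------------------------------------------------------------- antenna truth

def generate_antenna_periodic(config: SessionConfig, bouts: BoutSet,
                              rng: np.random.Generator
                              ) -> list[tuple[float, float]]:
    segs: list[tuple[float, float]] = []
    seg_len = 30.0
    for b in bouts.bouts:
        frac = (config.antenna.periodic_fraction_sleep if b.kind == "sleep"
                else config.antenna.periodic_fraction_wake)
        n = int(b.duration_s * frac / seg_len)
        if n == 0 and b.duration_s > seg_len and rng.random() < frac:
            n = 1
        starts = rng.uniform(b.start_s, max(b.end_s - seg_len, b.start_s),
                             size=n)
        for s in np.sort(starts):
            e = min(s + seg_len, b.end_s)
            if not segs or s > segs[-1][1]:
                segs.append((float(s), float(e)))
    return segs


# ------------------------------------------------------------------ movement

def _crepuscular_mult(config: SessionConfig, clock_s: float) -> float:
    h = clock_s / 3600.0
    if 7.0 <= h < 9.0:
        return config.crepuscular_peaks.get("dawn", 1.0)
    if 19.0 <= h < 21.0:
        return config.crepuscular_peaks.get("dusk", 1.0)
    return 1.0


def generate_movement(config: SessionConfig, bouts: BoutSet,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-frame binary moved flags consistent with the bout truth."""
    fps = config.fps_video
    n = int(round(config.duration * fps))
    moved = np.zeros(n, dtype=bool)
    for b in bouts.bouts:
        f0, f1 = int(round(b.start_s * fps)), int(round(b.end_s * fps))
        if b.kind == "sleep":
            # rare single-frame jitter noise, removed by pruning
            k = rng.poisson(0.005 * b.duration_s)
            idx = rng.integers(f0 + 60, max(f1 - 60, f0 + 61), size=k)
            moved[idx] = True
        else:
            t = b.start_s
            while t < b.end_s:
                mult = _crepuscular_mult(config,
                                         (config.clock_start + t) % 86400.0)
                run = max(1.0, rng.exponential(20.0 * mult))
                r0, r1 = int(round(t * fps)), int(round(min(t + run, b.end_s) * fps))
                moved[r0:r1] = True
                t += run
                pause = max(0.5, min(rng.exponential(20.0 / mult), 120.0))
                t += pause
            # movement hugs the bout edges so boundaries are recoverable
            moved[f0:min(f0 + int(2 * fps), n)] = True
            moved[max(f1 - int(2 * fps), 0):f1] = True
    return moved


def movement_magnitude_from_moved(moved: np.ndarray,
                                  rng: np.random.Generator,
                                  area_hi: float = 150.0,
                                  area_lo: float = 4.0) -> np.ndarray:
    mag = np.abs(rng.normal(area_lo, 2.0, size=moved.size))
    mag[moved] = np.abs(rng.normal(area_hi, 25.0, size=int(moved.sum())))
    return mag.astype(np.float32)


def render_frames(moved: np.ndarray, rng: np.random.Generator,
                  h: int = 48, w: int = 64) -> np.ndarray:
    """Small grayscale stack with a blob that jitters on moved frames."""
    n = moved.size
    frames = np.empty((n, h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy, r = w / 2.0, h / 2.0, 7.0
    for i in range(n):
        if i > 0 and moved[i]:
            cx = float(np.clip(cx + rng.uniform(-6, 6), r + 2, w - r - 2))
            cy = float(np.clip(cy + rng.uniform(-6, 6), r + 2, h - r - 2))
        img = np.full((h, w), 20.0)
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2] = 200.0
        img += rng.normal(0, 2.0, size=(h, w))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


# ---------------------------------------------------------------------- pose

def _pe_displacement(n: int, fps: float, pe_times: np.ndarray,
                     amp: float = 8.0, width_s: float = 0.4) -> np.ndarray:
    """Sum of raised-cosine displacement pulses centered at each PE time."""
    disp = np.zeros(n)
    half = int(round(width_s * fps / 2))
    win = 0.5 * (1 + np.cos(np.linspace(-np.pi, np.pi, 2 * half + 1)))
    for t in pe_times:
        c = int(round(t * fps))
        a, b = max(c - half, 0), min(c + half + 1, n)
        disp[a:b] = np.maximum(disp[a:b], amp * win[a - (c - half):
                                                    b - (c - half)])
    return disp


def generate_pose(config: SessionConfig, moved: np.ndarray,
                  pe_events: pd.DataFrame,
                  antenna_periodic: list[tuple[float, float]],
                  rng: np.random.Generator) -> pd.DataFrame:
    fps = config.fps_video
    n = moved.size
    t = np.arange(n) / fps
    cols: dict[str, np.ndarray] = {}

    def body(name, x0, y0, wake_sd, still_sd=0.08):
        sd = np.where(moved, wake_sd, still_sd)
        cols[f"{name}_x"] = x0 + rng.normal(0, 1, n) * sd
        cols[f"{name}_y"] = y0 + rng.normal(0, 1, n) * sd
        cols[f"{name}_likelihood"] = np.clip(
            rng.normal(0.95, 0.02, n), 0, 1)

    body("eye", 40.0, 30.0, 0.15, 0.08)
    for name, (x0, y0) in {"leg1_tip": (55, 50), "leg1_joint": (50, 45),
                           "leg3_tip": (30, 52), "leg3_joint": (33, 46),
                           "abdomen": (20, 38)}.items():
        body(name, float(x0), float(y0), 1.5)

    # proboscis: rest position plus PE displacement pulses along (1,1)/sqrt(2)
    disp = _pe_displacement(n, fps, pe_events.time_s.to_numpy())
    px = 46.0 + disp / np.sqrt(2) + rng.normal(0, 0.25, n)
    py = 36.0 + disp / np.sqrt(2) + rng.normal(0, 0.25, n)
    lik = np.clip(rng.normal(0.95, 0.02, n), 0, 1)
    # occlusions: likelihood dips below 0.5 during flagged PEs and at random
    occ_times = pe_events.loc[pe_events.occluded, "time_s"].to_numpy()
    for tt in occ_times:
        a = int(round((tt - 0.3) * fps))
        b = int(round((tt + 0.3) * fps))
        lik[max(a, 0):min(b, n)] = rng.uniform(0.1, 0.4)
    n_rand = rng.poisson(config.duration / 300.0)
    for s in rng.uniform(0, max(config.duration - 1, 1), size=n_rand):
        a = int(round(s * fps))
        lik[a:a + int(fps)] = rng.uniform(0.1, 0.4)
    cols["proboscis_x"], cols["proboscis_y"] = px, py
    cols["proboscis_likelihood"] = lik

    # antennae: tips oscillate about the base during periodic segments
    periodic = np.zeros(n, dtype=bool)
    for (s, e) in antenna_periodic:
        periodic[int(round(s * fps)):int(round(e * fps))] = True
    f0 = config.antenna.periodic_freq
    amp = np.deg2rad(config.antenna.amplitude_deg)
    phase = rng.uniform(0, 2 * np.pi)
    # slow bounded wander (out of the periodicity band) + white jitter;
    # a random-walk drift would spuriously trip the peak-dominance rule
    drift = 0.05 * np.sin(2 * np.pi * t / 600.0 + rng.uniform(0, 2 * np.pi))
    for side, (bx, by, theta0) in {"left": (28.0, 10.0, np.deg2rad(120)),
                                   "right": (52.0, 10.0, np.deg2rad(60))}.items():
        th = theta0 + drift + rng.normal(0, 0.01, n)
        th = th + np.where(periodic, amp * np.sin(2 * np.pi * f0 * t + phase), 0.0)
        L = 8.0
        cols[f"{side}_antenna_base_x"] = bx + rng.normal(0, 0.05, n)
        cols[f"{side}_antenna_base_y"] = by + rng.normal(0, 0.05, n)
        cols[f"{side}_antenna_tip_x"] = bx + L * np.cos(th)
        cols[f"{side}_antenna_tip_y"] = by + L * np.sin(th)
        cols[f"{side}_antenna_base_likelihood"] = np.clip(
            rng.normal(0.95, 0.02, n), 0, 1)
        cols[f"{side}_antenna_tip_likelihood"] = np.clip(
            rng.normal(0.95, 0.02, n), 0, 1)
    return pd.DataFrame(cols)


# ----------------------------------------------------------------------- LFP

def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    X[(f < lo) | (f >= hi)] = 0.0
    return np.fft.irfft(X, n)


def _pink_noise(n: int, fs: float, rng: np.random.Generator,
                f_ref: float = 10.0, knee: float = 0.5) -> np.ndarray:
    """1/f amplitude spectrum (alpha=1 in power), unit PSD at ``f_ref``."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    g = np.sqrt(f_ref / np.maximum(f, knee))
    return np.fft.irfft(X * g, n)


def _lowfreq_noise(n: int, fs: float, rng: np.random.Generator,
                   cutoff: float = 5.0) -> np.ndarray:
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    g = 1.0 / (1.0 + (f / cutoff) ** 4)
    return np.fft.irfft(X * g, n)


def _per_second_gains(config: SessionConfig, stages: StageLabels,
                      pe_bursts: pd.DataFrame) -> np.ndarray:
    """dB gain per (channel, band, second) from the configured effects."""
    n_sec = int(round(config.duration))
    gains = np.zeros((16, len(_BANDS), n_sec))
    sec_stage = np.full(n_sec, "awake", dtype=object)
    for iv in stages.intervals:
        a, b = int(iv.start_s), int(np.ceil(iv.end_s))
        st = iv.stage
        if st in ("pre2_probe",):
            st = "awake"
        elif st == "post2_probe":
            st = "awake"
        sec_stage[a:b] = st
    sleeping = np.isin(sec_stage, ("earlysleep", "midsleep", "latesleep"))
    secs = np.arange(n_sec)
    day = np.array([is_day(config.clock_start, float(s)) for s in secs])

    # wake broadband gain on all channels.  Presleep is excluded although
    # the fly still moves: the brain turns sleep-like ahead of behaviour,
    # which is what probability probing of unseen presleep epochs detects.
    wake_like = sec_stage == "awake"
    gains[:, :, wake_like] += config.wake_broadband_gain_db
    gains[:, :, sec_stage == "presleep"] += (
        config.presleep_broadband_fraction * config.wake_broadband_gain_db)
    # stage signature: central channels 1-3, 5-10 Hz band
    prof = config.stage_profile
    stage_db = np.array([prof.get(str(s), 0.0) for s in sec_stage])
    for ch in STAGE_SIGNATURE_CH:
        gains[ch - 1, 0, :] += stage_db
    # day/night sleep difference: peripheral channels, 10-30 Hz, day sleep up
    m = sleeping & day
    for ch in PERIPHERAL_CH:
        gains[ch - 1, 1, m] += config.daynight_peripheral_delta_db
    # PE effects over burst spans (padded by 0.5 s)
    for _, row in pe_bursts.iterrows():
        a = max(int(row.start_s - 0.5), 0)
        b = min(int(np.ceil(row.end_s + 0.5)), n_sec)
        if row.state in ("awake", "presleep"):   # behaviorally awake PEs
            for ch in MIDDLE_CH:
                gains[ch - 1, :, a:b] += config.pe_wake_middle_delta_db
        else:
            for ch in CENTRAL_CH:
                gains[ch - 1, 3, a:b] += config.pe_sleep_central_delta_db
    # amplitude null at the polarity-reversal channel
    gains[config.reversal_channel - 1, :, :] += _REVERSAL_ATTEN_DB
    return gains


def generate_lfp(config: SessionConfig, stages: StageLabels,
                 pe_bursts: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray:
    fs = config.fs_lfp
    n = int(round(config.duration * fs))
    sps = int(round(fs))
    gains = _per_second_gains(config, stages, pe_bursts)
    n_sec = gains.shape[2]
    common = _lowfreq_noise(n, fs, rng) * 1.0
    bg_amp = 10 ** (_BACKGROUND_DB / 20)
    lfp = np.empty((16, n), dtype=np.float32)
    for ch in range(16):
        y = common + bg_amp * _pink_noise(n, fs, rng) * (
            10 ** (_REVERSAL_ATTEN_DB / 20)
            if ch == config.reversal_channel - 1 else 1.0)
        for bi, (lo, hi) in enumerate(_BANDS):
            env = np.repeat(10 ** (gains[ch, bi] / 20.0), sps)[:n]
            if env.size < n:
                env = np.pad(env, (0, n - env.size), mode="edge")
            y = y + _band_noise(n, fs, lo, hi, rng) * env
        lfp[ch] = y.astype(np.float32)
    return lfp


# ------------------------------------------------------------------ sessions

def generate_session(config: SessionConfig) -> SyntheticSession:
    """Build one fully labeled synthetic session; deterministic in the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bouts = generate_bouts(config, rng)
    stages = segment_sleep_epochs(bouts)
    pe_events, pe_bursts = generate_pe_truth(config, stages, rng)
    ant = generate_antenna_periodic(config, bouts, rng)
    moved = generate_movement(config, bouts, rng)
    frames = None
    magnitude = None
    if config.frames_mode == "frames":
        frames = render_frames(moved, rng)
    else:
        magnitude = movement_magnitude_from_moved(moved, rng)
    pose = (generate_pose(config, moved, pe_events, ant, rng)
            if config.with_pose else None)
    lfp = (generate_lfp(config, stages, pe_bursts, rng)
           if config.with_lfp else None)
    truth = Truth(bouts, stages, pe_events, pe_bursts, ant,
                  config.reversal_channel)
    return SyntheticSession(config, lfp, config.fs_lfp, magnitude, frames,
                            config.fps_video, pose, truth, config.clock_start)


def generate_cohort(n_flies: int, config: SessionConfig,
                    seed: int) -> list[SyntheticSession]:
    """Independent sessions with per-fly seeds ``seed + fly_index``."""
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    sessions = []
    for i in range(n_flies):
        cfg = dataclasses.replace(config, seed=seed + i)
        s = generate_session(cfg)
        s.fly_id = i
        sessions.append(s)
    return sessions


# --------------------------------------------------------------- calibration

def generate_calibration(reversal_channel: int, noise_sd: float = 0.2,
                         seed: int = 0, n_trains: int = 5,
                         fs: float = 250.0) -> CalibrationRecording:
    """Visual-calibration recording: 1-Hz square-wave trains of 3 s.

    Evoked deflections are positive for channels peripheral to the reversal
    site, negative for central channels, and null at the reversal channel.
    """
    if not (2 <= reversal_channel <= 15):
        raise ValueError("reversal_channel at the array edge: reversal "
                         "undetectable (need 2..15)")
    rng = np.random.default_rng(seed)
    train_gap = 2.0
    onsets = []
    t0 = 1.0
    for _ in range(n_trains):
        onsets.extend([t0, t0 + 1.0, t0 + 2.0])
        t0 += 3.0 + train_gap
    onsets = np.asarray(onsets)
    T = t0 + 1.0
    n = int(round(T * fs))
    tau = 0.05
    tw = np.arange(int(0.25 * fs)) / fs
    wave = (tw / tau) * np.exp(1 - tw / tau)
    amp = np.tanh((np.arange(1, 17) - reversal_channel) / 2.0)
    lfp = rng.normal(0, noise_sd, size=(16, n))
    for on in onsets:
        i0 = int(round(on * fs))
        seg = slice(i0, min(i0 + wave.size, n))
        lfp[:, seg] += amp[:, None] * wave[: seg.stop - seg.start]
    return CalibrationRecording(lfp.astype(np.float32), fs, onsets,
                                reversal_channel)
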