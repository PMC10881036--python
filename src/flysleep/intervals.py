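"""Bout and sleep-stage interval bookkeeping.

All times are seconds from recording start, intervals half-open
``[start, end)``.  Clock times are seconds since midnight.  A sleep bout is a
maximal immobile run of at least 5 min; each bout is partitioned into
presleep (the 2 min of movement before immobility onset), earlysleep (first
2 min of the bout), latesleep (last 2 min) and midsleep (the remainder).
Two further probe windows flank the partition: ``pre2_probe`` (minutes -4 to
-2 before onset) and ``post2_probe`` (the 2 min after the bout ends).  These
probe windows are used only for classifier probing, never for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DAY_START_S = 8 * 3600.0   # lights on  8 a.m.
DAY_END_S = 20 * 3600.0    # lights off 8 p.m.
SLEEP_MIN_S = 300.0        # 5-min immobility criterion
STAGE_WIN_S = 120.0        # 2-min presleep/early/late windows

SLEEP_STAGES = ("awake", "presleep", "earlysleep", "midsleep", "latesleep")
PROBE_STAGES = ("pre2_probe", "post2_probe")


def clock_at(clock_start: float, t: float) -> float:
    """Clock time (s since midnight) at recording time ``t``."""
    return (clock_start + t) % 86400.0


def is_day(clock_start: float, t: float) -> bool:
    c = clock_at(clock_start, t)
    return DAY_START_S <= c < DAY_END_S


@dataclass(frozen=True)
class Bout:
    start_s: float
    end_s: float
    kind: str              # 'awake' | 'sleep'
    day_flag: bool         # assigned by bout onset clock time

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BoutSet:
    bouts: list[Bout]
    duration_s: float
    clock_start: float

    def sleep_bouts(self) -> list[Bout]:
        return [b for b in self.bouts if b.kind == "sleep"]

    def validate(self) -> None:
        t = 0.0
        for b in self.bouts:
            if abs(b.start_s - t) > 1e-9:
                raise ValueError("bouts must tile the recording without gaps")
            if b.kind == "sleep" and b.duration_s < SLEEP_MIN_S - 1e-9:
                raise ValueError("sleep bout shorter than 5 min")
            t = b.end_s
        if abs(t - self.duration_s) > 1e-9:
            raise ValueError("bouts do not cover the recording")


@dataclass(frozen=True)
class StageInterval:
    start_s: float
    end_s: float
    stage: str
    bout_id: int = -1      # index into the sleep-bout list; -1 for awake
    partial: bool = False  # truncated at a recording edge

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StageLabels:
    intervals: list[StageInterval]
    duration_s: float
    clock_start: float = 0.0
    # midsleep duration per sleep bout, for the short/long midsleep split
    midsleep_duration_s: dict[int, float] = field(default_factory=dict)

    def of_stage(self, stage: str) -> list[StageInterval]:
        return [iv for iv in self.intervals if iv.stage == stage]


def segment_sleep_epochs(bouts: BoutSet, include_probes: bool = True) -> StageLabels:
    """Partition a recording into sleep stages around each sleep bout.

    For a sleep bout ``[b0, b1)``: presleep ``[b0-120, b0)``, earlysleep
    ``[b0, b0+120)``, midsleep ``[b0+120, b1-120)``, latesleep
    ``[b1-120, b1)``; probe windows ``[b0-240, b0-120)`` and ``[b1, b1+120)``.
    Windows truncated by the recording edge (or a neighbouring bout) are
    flagged partial.  All residual time is awake.
    """
    T = bouts.duration_s
    sleeps = bouts.sleep_bouts()
    intervals: list[StageInterval] = []
    mid_durations: dict[int, float] = {}
    for i, b in enumerate(sleeps):
        if b.duration_s < SLEEP_MIN_S - 1e-9:
            raise ValueError("sleep bout shorter than the 5-min criterion")
        prev_end = sleeps[i - 1].end_s if i > 0 else 0.0
        next_start = sleeps[i + 1].start_s if i + 1 < len(sleeps) else T
        w = STAGE_WIN_S
        pre0, pre1 = b.start_s - w, b.start_s
        pre0c = max(pre0, prev_end)
        if pre1 > pre0c:
            intervals.append(StageInterval(pre0c, pre1, "presleep", i, pre0c > pre0))
        if include_probes:
            # pre2 yields to the previous bout's post2 window
            p0, p1 = b.start_s - 2 * w, b.start_s - w
            p0c = max(p0, prev_end + w)
            if min(p1, pre0c) > p0c:
                intervals.append(
                    StageInterval(p0c, min(p1, pre0c), "pre2_probe", i, p0c > p0))
        intervals.append(StageInterval(b.start_s, b.start_s + w, "earlysleep", i))
        intervals.append(StageInterval(b.start_s + w, b.end_s - w, "midsleep", i))
        intervals.append(StageInterval(b.end_s - w, b.end_s, "latesleep", i))
        mid_durations[i] = b.duration_s - 2 * w
        if include_probes:
            # post2 yields to the next bout's presleep window
            q0, q1 = b.end_s, b.end_s + w
            q1c = min(q1, next_start - w, T)
            if q1c > q0:
                intervals.append(StageInterval(q0, q1c, "post2_probe", i, q1c < q1))
    intervals.sort(key=lambda iv: iv.start_s)
    # awake = residual time
    covered = [(iv.start_s, iv.end_s) for iv in intervals]
    awake: list[StageInterval] = []
    t = 0.0
    for s, e in covered:
        if s > t + 1e-9:
            awake.append(StageInterval(t, s, "awake"))
        t = max(t, e)
    if T > t + 1e-9:
        awake.append(StageInterval(t, T, "awake"))
    intervals = sorted(intervals + awake, key=lambda iv: iv.start_s)
    return StageLabels(intervals, T, bouts.clock_start, mid_durations)


def minute_label(iv: StageInterval, offset_in_iv_s: float) -> str:
    """Minute-relative tag of an epoch starting ``offset_in_iv_s`` into ``iv``.

    Minutes are counted relative to immobility onset (0) for presleep/early
    windows and relative to the bout end (x) for late/post windows, matching
    the -4..+2 and x-2..x+2 probing axes.
    """
    m = int(offset_in_iv_s // 60)
    if iv.stage == "presleep":
        k = -2 + m
        return f"{k}:{k + 1}"
    if iv.stage == "pre2_probe":
        k = -4 + m
        return f"{k}:{k + 1}"
    if iv.stage == "earlysleep":
        return f"+{m}:+{m + 1}"
    if iv.stage == "latesleep":
        k = -2 + m
        return f"x{k}:x{k + 1}" if k + 1 < 0 else "x-1:x"
    if iv.stage == "post2_probe":
        return f"x+{m}:x+{m + 1}"
    if iv.stage == "midsleep":
        return "mid"
    return "awake"
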