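"""End-to-end drivers chaining the pipeline stages over sessions.

These are the compositions the analysis scripts, tests and acceptance
checks share: session -> movement -> bouts/stages -> preprocessed,
re-referenced LFP -> labeled epochs -> spectra -> feature tables and
contrasts.
"""

from __future__ import annotations

import numpy as np

from . import behavior, lfp as lfp_mod, spectra as spectra_mod
from .intervals import StageInterval, StageLabels, is_day
from .lfp import EpochSet, ReferencedLFP
from .spectra import SpectralMatrix
from .synth import SyntheticSession


def movement_trace(session: SyntheticSession) -> behavior.MovementTrace:
    if session.frames is not None:
        tr = behavior.quantify_movement(session.frames, fps=session.fps)
    elif session.movement_magnitude is not None:
        tr = behavior.movement_from_magnitude(session.movement_magnitude,
                                              fps=session.fps)
    else:
        raise ValueError("session has neither frames nor magnitude series")
    return behavior.prune_movement(tr)


def detected_bouts(session: SyntheticSession) -> behavior.BoutSet:
    return behavior.label_states(movement_trace(session),
                                 session.clock_start)


def detected_stage_labels(session: SyntheticSession) -> StageLabels:
    return behavior.segment_sleep_epochs(detected_bouts(session))


def referenced_lfp(session: SyntheticSession,
                   reference: int | None = None) -> ReferencedLFP:
    rec = lfp_mod.preprocess(session.lfp, session.fs,
                             session.clock_start)
    ref = session.truth.reversal_channel if reference is None else reference
    return lfp_mod.rereference(rec, ref)


def _wake_sleep_map(iv: StageInterval) -> str | None:
    if iv.stage == "awake":
        return "awake"
    if iv.stage in ("earlysleep", "midsleep", "latesleep"):
        return "sleep"
    return None


def wake_sleep_epochs(session: SyntheticSession, use_truth: bool = True,
                      epoch_s: float = 60.0) -> EpochSet:
    stages = (session.truth.stages if use_truth
              else detected_stage_labels(session))
    ref = referenced_lfp(session)
    return lfp_mod.epoch_by_labels(ref, stages, epoch_s,
                                   fly_id=session.fly_id,
                                   label_map=_wake_sleep_map)


def stage_epochs(session: SyntheticSession, use_truth: bool = True,
                 epoch_s: float = 60.0) -> EpochSet:
    stages = (session.truth.stages if use_truth
              else detected_stage_labels(session))
    ref = referenced_lfp(session)
    return lfp_mod.epoch_by_labels(ref, stages, epoch_s,
                                   fly_id=session.fly_id)


def stage_spectra(session: SyntheticSession,
                  use_truth: bool = True) -> SpectralMatrix:
    return spectra_mod.epoch_spectrum(stage_epochs(session, use_truth))


def wake_sleep_spectra(session: SyntheticSession,
                       use_truth: bool = True) -> SpectralMatrix:
    return spectra_mod.epoch_spectrum(wake_sleep_epochs(session, use_truth))


def daynight_sleep_spectra(session: SyntheticSession,
                           use_truth: bool = True) -> SpectralMatrix:
    """Sleep epochs relabeled daysleep/nightsleep by their clock time."""
    sm = wake_sleep_spectra(session, use_truth)
    stages = (session.truth.stages if use_truth
              else detected_stage_labels(session))
    # epoch start times recomputed by re-walking the tiling
    labels = sm.labels.copy()
    starts = _epoch_starts(stages, 60.0, _wake_sleep_map)
    for i, (lab, t0) in enumerate(zip(labels, starts)):
        if lab == "sleep":
            labels[i] = ("daysleep" if is_day(session.clock_start, t0)
                         else "nightsleep")
        else:
            labels[i] = "awake"
    sm.labels = labels
    return sm


def _epoch_starts(stages: StageLabels, epoch_s: float, label_map) -> list[float]:
    starts = []
    for iv in stages.intervals:
        if label_map(iv) is None:
            continue
        k = 0
        while iv.start_s + (k + 1) * epoch_s <= iv.end_s + 1e-9:
            starts.append(iv.start_s + k * epoch_s)
            k += 1
    return starts


def pe_context_epochs(session: SyntheticSession,
                      epoch_s: float = 1.0) -> EpochSet:
    """1-s epochs labeled awake/awakeprob/sleep/sleepprob.

    PE (proboscis) intervals come from the truth burst spans; the remaining
    awake/sleep time gives the no-PE baselines.
    """
    ref = referenced_lfp(session)
    stages = session.truth.stages
    bursts = session.truth.pe_bursts
    ivs: list[StageInterval] = []
    prob_lab = {"awake": "awakeprob", "presleep": "presleepprob",
                "sleep": "sleepprob"}
    for _, row in bursts.iterrows():
        ivs.append(StageInterval(max(row.start_s - 0.5, 0.0),
                                 row.end_s + 0.5, prob_lab[row.state]))
    pe_spans = [(iv.start_s, iv.end_s) for iv in ivs]

    def outside_pe(a, b):
        segs = [(a, b)]
        for (s, e) in pe_spans:
            nxt = []
            for (x, y) in segs:
                if e <= x or s >= y:
                    nxt.append((x, y))
                else:
                    if x < s:
                        nxt.append((x, s))
                    if e < y:
                        nxt.append((e, y))
            segs = nxt
        return segs

    for iv in stages.intervals:
        if iv.stage == "awake":
            lab = "awake"
        elif iv.stage in ("earlysleep", "midsleep", "latesleep"):
            lab = "sleep"
        elif iv.stage == "presleep":
            lab = "presleep"
        else:
            continue
        for (a, b) in outside_pe(iv.start_s, iv.end_s):
            if b - a >= epoch_s:
                ivs.append(StageInterval(a, b, lab))
    ivs.sort(key=lambda v: v.start_s)
    return lfp_mod.epoch_by_labels(ref, ivs, epoch_s, fly_id=session.fly_id)


def pe_context_spectra(session: SyntheticSession) -> SpectralMatrix:
    return spectra_mod.epoch_spectrum(pe_context_epochs(session))


def midsleep_durations(sessions) -> dict[int, dict[int, float]]:
    return {s.fly_id: dict(s.truth.stages.midsleep_duration_s)
            for s in sessions}
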