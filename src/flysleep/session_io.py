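"""Session bundle I/O: HDF5 for signals, wide CSV for pose, CSV for labels."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .intervals import Bout, BoutSet


def write_session(session, out_dir: str | Path, name: str = "session") -> Path:
    """One HDF5 bundle (/lfp, /frames or /movement + attrs), pose as wide
    CSV, truth labels as CSV (onset_s, offset_s, label)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5 = out / f"{name}.h5"
    with h5py.File(h5, "w") as f:
        if session.lfp is not None:
            f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        if session.frames is not None:
            f.create_dataset("frames", data=session.frames)
        if session.movement_magnitude is not None:
            f.create_dataset("movement", data=session.movement_magnitude)
        f.attrs["fs"] = session.fs
        f.attrs["fps"] = session.fps
        f.attrs["clock_start"] = session.clock_start
        f.attrs["reversal_channel"] = session.truth.reversal_channel
        f.attrs["fly_id"] = session.fly_id
    if session.pose is not None:
        session.pose.to_csv(out / f"{name}_pose.csv", index=False)
    rows = [(b.start_s, b.end_s, b.kind, int(b.day_flag))
            for b in session.truth.bouts.bouts]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "label", "day_flag"]) \
        .to_csv(out / f"{name}_labels.csv", index=False)
    return h5


def read_session_bundle(h5_path: str | Path) -> dict:
    h5_path = Path(h5_path)
    out: dict = {}
    with h5py.File(h5_path, "r") as f:
        for key in ("lfp", "frames", "movement"):
            if key in f:
                out[key] = f[key][...]
        out.update({k: f.attrs[k] for k in f.attrs})
    pose = h5_path.with_name(h5_path.stem + "_pose.csv")
    if pose.exists():
        out["pose"] = pd.read_csv(pose)
    labels = h5_path.with_name(h5_path.stem + "_labels.csv")
    if labels.exists():
        df = pd.read_csv(labels)
        bouts = [Bout(r.onset_s, r.offset_s, r.label, bool(r.day_flag))
                 for r in df.itertuples()]
        dur = df.offset_s.max() if len(df) else 0.0
        out["bouts"] = BoutSet(bouts, float(dur), float(out["clock_start"]))
    return out
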