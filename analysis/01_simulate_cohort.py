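#!/usr/bin/env python
"""Generate a labeled synthetic cohort and write the session bundles.

Each fly gets an HDF5 bundle (LFP + movement magnitude), a wide pose CSV,
and a truth-label CSV under results/sessions/.  Downstream scripts either
read these bundles or regenerate the cohort from the same seed.
"""

import argparse
from pathlib import Path

from flysleep import SessionConfig, generate_cohort
from flysleep.session_io import write_session


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-flies", type=int, default=6)
    ap.add_argument("--duration", type=float, default=3600.0)
    ap.add_argument("--seed", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/sessions"))
    args = ap.parse_args()

    cfg = SessionConfig(duration=args.duration, sleep_bout_rate=2.5)
    cohort = generate_cohort(args.n_flies, cfg, seed=args.seed)
    for s in cohort:
        path = write_session(s, args.out, f"fly{s.fly_id:02d}")
        n_sleep = len(s.truth.bouts.sleep_bouts())
        print(f"fly {s.fly_id}: {path.name}, {n_sleep} sleep bouts, "
              f"{len(s.truth.pe_events)} PE events")


if __name__ == "__main__":
    main()
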