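#!/usr/bin/env python
"""Classifier staging: SVM probability probing, midsleep-duration SVM,
five-class random forest with permutation importance, day/night forest.

Writes probability-by-minute curves, classifier reports, and the
channel x frequency importance map to results/.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from flysleep import SessionConfig, generate_cohort
from flysleep import pipeline as P
from flysleep import staging as ST


def report_dict(rep):
    return {"accuracy": rep.accuracy, "roc_auc": rep.roc_auc,
            "precision": rep.precision, "recall": rep.recall, "f1": rep.f1}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-flies", type=int, default=6)
    ap.add_argument("--seed", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore")
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SessionConfig(duration=3600.0, sleep_bout_rate=2.5,
                        with_pose=False)
    cohort = generate_cohort(args.n_flies, cfg, seed=args.seed)
    sms = [P.stage_spectra(s, use_truth=False) for s in cohort]
    table = ST.build_feature_table(sms, P.midsleep_durations(cohort))
    ST.write_feature_table(table, h5_path=args.out / "features.h5")

    # 1. awake-vs-midsleep SVM, probed on unseen stages
    model, rep = ST.train_probability_stager(table, seed=args.seed)
    probe = ST.probe_unseen_epochs(model, table)
    by_min = ST.probability_by_minute(probe)
    print("awake-class probability by minute:")
    print(by_min.round(3).to_string())
    by_min.to_csv(args.out / "probability_by_minute.csv")

    out = {"svm_awake_midsleep": report_dict(rep)}

    # 2. short vs long midsleep
    try:
        _, rep_dur = ST.train_midsleep_duration_stager(table, seed=args.seed)
        out["svm_midsleep_duration"] = report_dict(rep_dur)
    except ValueError as e:
        print(f"midsleep-duration stager skipped: {e}")

    # 3. five-class random forest with importance
    classes = ["awake", "presleep", "earlysleep", "midsleep", "latesleep"]
    res = ST.train_rf_multiclass(table, classes=classes, seed=args.seed)
    out["rf_multiclass"] = report_dict(res.report)
    print("five-class RF F1:",
          {k: round(v, 3) for k, v in res.report.f1.items()})
    imp = res.importance
    rows = [(c, f, imp.scores[i, j]) for i, c in enumerate(imp.channel_ids)
            for j, f in enumerate(imp.freq_grid)]
    pd.DataFrame(rows, columns=["channel", "freq_hz", "importance"]) \
        .to_csv(args.out / "rf_importance.csv", index=False)

    with open(args.out / "classifier_reports.json", "w") as f:
        json.dump(out, f, indent=2)


if __name__ == "__main__":
    main()
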