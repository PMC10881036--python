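# flysleep

Sleep staging and spectral analysis for long-term multichannel local field
potential (LFP) recordings in behaving *Drosophila*, with a fully labeled
synthetic-session generator so every stage of the pipeline is testable
end to end without recordings.

## The problem

Flies sleep, but fly sleep has traditionally been scored from behavior
alone: any bout of immobility longer than 5 minutes counts as sleep.  A
16-channel linear probe spanning one hemisphere (retina to central brain)
turns this into an electrophysiological question: do the stages of a sleep
bout — the 2 minutes before immobility (presleep), the first 2 minutes
(earlysleep), the interior (midsleep), and the last 2 minutes (latesleep)
— carry distinct spectral signatures, and are sleep microbehaviors such as
rhythmic proboscis extensions (PEs) driven by a distinct brain state?

The pipeline implements the full analysis chain:

* **Movement analysis** — frame-difference + contour-area movement
  detection, noise pruning, the 5-minute immobility criterion, day/night
  bout statistics and crepuscular activity profiles.
* **LFP preprocessing** — resampling to 250 Hz, zero-phase FIR bandpass
  0.5–40 Hz, 50-Hz notch, detection of the polarity-reversal channel from
  visual calibration, and re-referencing at that channel (16 → 15
  channels).  Electrode sites are localized from dye points by a PCA line
  fit sampled at 25 µm.
* **Spectral contrasts** — 60-s (or 1-s) epochs, Welch spectra in dB on a
  fixed 15 × 145 channel × frequency grid (5–40 Hz), per-fly condition
  differences, Cohen's *d* maps, and a sign-flip **cluster permutation
  test** over the channel × frequency lattice (all 2ⁿ flips for n ≤ 14
  flies; cluster mass = Σ|t| over 4-connected same-sign cells).
* **Classifier staging** — a linear-kernel SVM with calibrated
  probabilities trained only on awake vs midsleep and *probed* on epochs
  from stages it never saw; a short-vs-long (14 min) midsleep SVM; and a
  five-class random forest with SMOTE balancing, per-class
  precision/recall/F1, and permutation feature importance over the 2175
  features.
* **Microbehavior** — rbf-SVM PE detection from pose traces (with a
  likelihood-threshold augmentation rule for occlusions), 10-s burst
  construction, the <6-s periodicity rule, antennal angles and FFT
  periodicity.
* **Mixed models** — random-intercept (per-fly) linear models compared by
  likelihood-ratio χ² tests, main-effect ANOVA, and Tukey-adjusted
  pairwise post hocs.

The `flysleep.synth` module generates cohorts of sessions whose LFP is
1/f background plus band-limited components with per-second dB gains
(wake broadband gain, central-channel 5–10 Hz stage profile, peripheral
10–30 Hz day/night difference, PE signatures), plus movement, pose and
calibration data — all with ground-truth labels.

## Worked example

```python
from flysleep import SessionConfig, generate_cohort
from flysleep import pipeline as P, spectra as SP

cfg = SessionConfig(duration=4500.0, sleep_bout_rate=2.0, with_pose=False)
cohort = generate_cohort(13, cfg, seed=42)
sms = [P.wake_sleep_spectra(s, use_truth=False) for s in cohort]
diff, d = SP.condition_contrast(sms, "awake", "sleep")
res = SP.cluster_permutation(diff)
sig = res.significant()
print(len(diff.fly_ids), len(sig), res.cluster_p[0])
```

prints `10 1 0.001953125`: ten of the thirteen flies meet the 10-trial
minimum in both conditions, and the test finds exactly one significant
cluster — spanning all 15 channels and all frequencies 5–40 Hz, i.e. a
brain-wide power decrease during sleep — with a cluster p of 2/1024
under the fully enumerated 2¹⁰-flip sign-flip null.

The numbered scripts under `analysis/` run each stage as a narrative
driver (`01_simulate_cohort.py` … `06_mixed_models.py`) and write their
tables under `results/`.

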