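# Methods

## The synthetic session model

Every downstream stage is exercised against generated sessions with known
truth.  A session holds a 16-channel LFP, a movement readout, a pose
table, and labels (bout sequence, stage partition, PE events, antennal
periodic segments, polarity-reversal channel).

**Bout process.**  Wake and sleep alternate as a renewal process: wake
durations are exponential with mean `3600/rate − E[bout]` (floored at
150 s), sleep durations lognormal (default median ≈ 14 min, σ = 0.5, the
realistic day-time figure), multiplied by ≈1.6 for bouts starting after
lights-off so night bouts are longer.  Every generated sleep bout
respects the 5-minute criterion.

**LFP.**  Per channel: a 1/f (α ≈ 1) background (−13 dB relative to the
in-band noise density), a common low-frequency (<5 Hz) component shared
by all channels (heartbeat-like physiological noise, removed by
re-referencing), and four disjoint band-limited Gaussian components
([5,10), [10,30), [30,32), [32,40] Hz) whose amplitudes follow per-second
dB gains:

* broadband wake gain (+3 dB default) on all channels while the fly is
  behaviorally awake *outside presleep*.  Presleep keeps only a fraction
  (default 0.33) of this gain: the brain turns sleep-like before the body
  stops, which is precisely what classifier probing of unseen presleep
  epochs is designed to detect.
* a stage profile on central channels 1–3 in 5–10 Hz, ordered
  awake (0) > presleep (−1) > earlysleep (−2) ≈ latesleep (−2.4) >
  midsleep (−5) dB.  The early/late values are deliberately close but
  distinct; the early–mid separation is wide because in classifier
  probability terms earlysleep sits roughly halfway between wake and
  midsleep.
* a day/night difference (+2 dB, day sleep higher) on peripheral
  channels 12–16 in 10–30 Hz;
* PE signatures over burst spans: −2.5 dB broadband on middle channels
  during wake PEs, +2.5 dB at 32–40 Hz on central channels during sleep
  PEs.

The partition into disjoint bands makes each configured contrast land in
its own band, so the realized dB difference equals the configured gain up
to floor compression.  The reversal channel carries −13 dB band
components (the amplitude null at the polarity-reversal site); this also
keeps re-referencing from washing contrasts out, since the reference's
own noise is added to every output channel.  No absolute amplitudes are
claimed — all gains are free parameters in `SessionConfig`.

**Movement, pose, video.**  Wake is runs of movement (exponential
run/pause lengths, crepuscular multipliers at dawn/dusk) hugging bout
edges so boundaries are recoverable to <2 s; sleep contains only
single-frame jitter that pruning removes.  Pose traces put raised-cosine
displacement pulses (8 px, 0.4 s) on the proboscis at PE times, sinusoidal
antennal angles (default 0.8 Hz, 8°) during periodic segments, and
likelihood dips (<0.5) during a fraction of PEs and at random, forcing the
detection pipeline to use its likelihood-augmentation rule.  Video is
either a per-frame contour-area magnitude series or small 64×48 frames
with a jittering blob, exercising the real image operators at desk scale.

**What the generator does not emulate:** spike waveforms, realistic
heartbeat artifacts beyond the common-mode term, non-stationary drift,
grooming-vs-walking structure, photorealistic video, and pose-estimation
failure modes beyond likelihood dips.  Passing tests therefore show the
pipeline recovers effects of the assumed additive band-limited form at
realistic SNR; they do not certify performance on real recordings.

## Pipeline conventions and numerical choices

* Time intervals are half-open `[start, end)` seconds; frames 0-based;
  channels 1-based.  A bout straddling the light transition is assigned
  day/night by its onset.
* Stage windows are 2 min; probe windows (−4:−2 and x:x+2 min) are used
  only for classifier probing.  When bouts are close, the post-bout probe
  yields to the next bout's presleep window, and the pre-bout probe to the
  previous bout's post window, keeping the partition disjoint.  A presleep
  truncated by the recording edge is flagged partial.
* Preprocessing: polyphase resampling to 250 Hz; Hamming windowed-sinc
  FIR (transition 0.5 Hz), applied by centered convolution so the phase is
  exactly zero; 50-Hz IIR notch (Q = 25) run forward-backward; hourly
  segments joined with a 1-s linear blend.
* Reversal detection: evoked amplitude = mean of 0–200 ms post-onset
  minus the 100-ms pre-onset baseline, averaged over onsets; the reversal
  is the smallest-magnitude channel between the last negative and first
  positive channel.
* Spectra: Welch, 2-s hann windows, 50% overlap (single window for 1-s
  epochs), 10·log10, interpolated onto the fixed 145-bin grid over
  5–40 Hz chosen to pin the printed 15 × 145 feature dimension.  Epochs
  are bandpassed 5–40 Hz (zero phase) first; for 1-s epochs the filter
  length adapts to the epoch.
* Cluster test: two-sided cluster-forming threshold at α = 0.05 with
  df = n−1; 4-connectivity; same-sign clusters; full 2ⁿ sign-flip
  enumeration for n ≤ 14 else random flips; ties in the null count
  against the observed mass (conservative), with a relative tolerance so
  the identity flip always ties itself (p ≥ 1/n_perm).  Zero-variance
  cells get t = 0 with a warning.
* Trial minima per fly and condition: 10 (60-s epochs), 50 (1-s epochs).
  Epoch tiling starts at each interval onset; tails shorter than the
  epoch are dropped.
* SVM staging: majority-class downsampling, stratified 80/20 split,
  standardization fit on training rows only, linear-kernel SVM with
  Platt-style sigmoid calibration via internal cross-validation; five
  split iterations with seeds seed+0..seed+4; probabilities averaged over
  iterations when probing.  Exactly 14-minute midsleeps count as long
  (<14 is short).
* Random forest: SMOTE (hand-rolled k = 5 nearest-neighbour
  interpolation) applied before the split by default, mirroring the
  recipe it reproduces; `smote_before_split=False` gives the leakage-safe
  variant.  Defaults 100 trees, √p features; a randomized-then-grid
  search over a small documented grid is available behind `tune=True`.
  Permutation importance uses 5 shuffles per feature per split, averaged
  over the five splits, scored as the drop in mean log-probability of the
  true class — a probability-based score keeps redundant informative
  features visible when the accuracy is saturated.  Shuffled predictions
  are batched into one predict call per feature block for speed.
* PE detection: features are raw/low-pass/moving-average coordinates and
  their derivatives for proboscis, legs, eye, abdomen, plus the
  likelihood-weighted eye–proboscis distance; rbf SVM on a 70/30 split
  with training negatives downsampled (3:1); candidates augmented where
  the smoothed proboscis likelihood drops below 0.9 while raw displacement
  exceeds a robust (median + 4·MAD) threshold.  Candidate runs merge
  across gaps <0.2 s; within a run one event per local displacement peak
  (min separation 0.5 s); bursts join events ≤10 s apart; an event is
  periodic when <6 s from its predecessor (first events inherit from the
  successor).
* Antennal periodicity: per 30-s segment, periodic iff the dominant FFT
  peak exceeds log2(n_bins/0.05) ≈ 11.5 times the median band power — the
  analytic white-noise calibration for a 5% false-positive rate
  (periodogram bins are near-exponential, so
  P(max/median > r) ≈ n·2^(−r)).
* Mixed models: maximum likelihood (not REML) so LRTs on fixed effects
  are valid; the winner must both maximize log-likelihood and beat the
  null at p < 0.05 (ties → simpler model).  Main-effect F tests use a
  residual df approximation (n − p); Tukey post hocs compare estimated
  marginal means with studentized-range p values.  Periodicity responses
  are modeled as linear-probability by default.

## Problem sizes

Synthetic cohorts are desk-scale by choice: 6–13 flies, 20–90-minute
sessions, which gives every fly enough 60-s trials to clear the
inclusion minima while keeping the full suite and the acceptance script
in the minutes range.  Effect magnitudes are never scaled with the
problem size.

## Known limitations

* SMOTE-before-split (the default, for fidelity) leaks interpolated
  minority information into the test split; the flag documents and
  avoids it.
* The 145-bin grid is a convention pinned to the printed feature
  dimension; the underlying estimator's window settings are our choice.
* Importance maps are meaningful relative to the trained forest; with
  heavily redundant features the accuracy-based score would be blind,
  which is why the log-probability score is the default.
* The LRT for a factor with a boundary random-effect variance is
  asymptotic; fits flag the boundary case.
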