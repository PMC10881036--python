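"""Per-epoch power spectra and the cluster-based permutation contrast.

Spectra are Welch periodograms in dB on a fixed 145-bin grid spanning
5-40 Hz, giving the 15 x 145 channel x frequency feature plane.  Group
contrasts are per-fly mean differences; family-wise inference over the
channel x frequency lattice uses a one-sample cluster permutation test
with a sign-flipping null (all 2^n flips when n <= 14), cluster mass =
sum of |t| over 4-connected same-sign supra-threshold cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .lfp import MIN_TRIALS, EpochSet

N_FREQ_BINS = 145
FREQ_GRID = np.linspace(5.0, 40.0, N_FREQ_BINS)


@dataclass
class SpectralMatrix:
    power_db: np.ndarray           # (n_epochs, n_channels, 145)
    freq_grid: np.ndarray
    labels: np.ndarray
    minute_labels: np.ndarray
    bout_ids: np.ndarray
    channel_ids: tuple[int, ...]
    fly_id: int
    epoch_s: float


@dataclass
class DifferenceSpectrum:
    diff_db: np.ndarray            # (n_flies, n_channels, n_freqs)
    fly_ids: list[int]
    cond_a: str
    cond_b: str
    channel_ids: tuple[int, ...] = tuple(range(1, 17))
    freq_grid: np.ndarray = field(default_factory=lambda: FREQ_GRID.copy())


@dataclass
class EffectSizeMap:
    d: np.ndarray                  # (n_channels, n_freqs) Cohen's d


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    clusters: list[np.ndarray]     # boolean masks, ordered by mass desc
    cluster_p: np.ndarray
    cluster_mass: np.ndarray
    n_permutations: int
    alpha: float
    null_max: np.ndarray | None = None   # null max-mass distribution

    def significant(self, level: float | None = None) -> list[np.ndarray]:
        level = self.alpha if level is None else level
        return [m for m, p in zip(self.clusters, self.cluster_p) if p < level]


def _bandpass_5_40(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase FIR 5-40 Hz; tap count adapts to short epochs."""
    numtaps = int(3.3 * fs / 2.0)
    max_taps = x.shape[-1] // 3
    numtaps = min(numtaps, max_taps)
    numtaps += (numtaps + 1) % 2
    if numtaps < 11:
        return x
    taps = signal.firwin(numtaps, [5.0, 40.0], pass_zero=False, fs=fs,
                         window="hamming")
    return signal.fftconvolve(x, taps[None, None, :], mode="same", axes=-1)


def epoch_spectrum(epochs: EpochSet, prefilter: bool = True) -> SpectralMatrix:
    """Welch power per epoch per channel in dB on the 145-bin 5-40 Hz grid.

    60-s epochs use 2-s hann windows with 50% overlap; epochs of 2 s or
    less use a single window.  The Welch grid is interpolated onto the
    fixed 145-bin grid.
    """
    fs = epochs.fs
    x = epochs.epochs.astype(float)
    if x.shape[0] == 0:
        return SpectralMatrix(np.empty((0, x.shape[1], N_FREQ_BINS)),
                              FREQ_GRID.copy(), epochs.labels,
                              epochs.minute_labels, epochs.bout_ids,
                              epochs.channel_ids, epochs.fly_id,
                              epochs.epoch_s)
    if x.shape[-1] < int(fs):
        raise ValueError("epoch shorter than one Welch window (min 1 s)")
    nper = min(int(2 * fs), x.shape[-1])
    if prefilter:
        x = _bandpass_5_40(x, fs)
    f, pxx = signal.welch(x, fs=fs, nperseg=nper, noverlap=nper // 2,
                          window="hann", axis=-1)
    if f[-1] < 40.0:
        raise ValueError("epoch too short to resolve 40 Hz")
    pxx = np.maximum(pxx, 1e-300)
    power_db = 10.0 * np.log10(pxx)
    out = np.empty(x.shape[:2] + (N_FREQ_BINS,))
    for i in range(x.shape[0]):
        for c in range(x.shape[1]):
            out[i, c] = np.interp(FREQ_GRID, f, power_db[i, c])
    return SpectralMatrix(out, FREQ_GRID.copy(), epochs.labels,
                          epochs.minute_labels, epochs.bout_ids,
                          epochs.channel_ids, epochs.fly_id, epochs.epoch_s)


def band_power_db(sm: SpectralMatrix, lo: float, hi: float,
                  channels: tuple[int, ...] | None = None) -> np.ndarray:
    """Mean dB over a frequency band (and optional channel subset) per epoch."""
    fm = (sm.freq_grid >= lo) & (sm.freq_grid < hi)
    p = sm.power_db[:, :, fm]
    if channels is not None:
        rows = [sm.channel_ids.index(c) for c in channels]
        p = p[:, rows, :]
    return p.mean(axis=(1, 2))


def condition_contrast(spectra: list[SpectralMatrix], cond_a: str, cond_b: str,
                       min_trials: int | None = None
                       ) -> tuple[DifferenceSpectrum, EffectSizeMap]:
    """Per-fly mean(cond_a) - mean(cond_b), and across-fly Cohen's d.

    Flies lacking the per-condition trial minimum (10 for 60-s epochs, 50
    for 1-s epochs) are excluded.
    """
    diffs, fly_ids = [], []
    for sm in spectra:
        if min_trials is None:
            mt = MIN_TRIALS.get(sm.epoch_s, 1)
        else:
            mt = min_trials
        ma = sm.labels == cond_a
        mb = sm.labels == cond_b
        if ma.sum() < mt or mb.sum() < mt:
            continue
        diffs.append(sm.power_db[ma].mean(axis=0) - sm.power_db[mb].mean(axis=0))
        fly_ids.append(sm.fly_id)
    if not diffs:
        raise ValueError(f"no fly has both conditions {cond_a!r}/{cond_b!r} "
                         "with the required trial minimum")
    D = np.stack(diffs)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sd > 0, D.mean(axis=0) / sd, 0.0)
    return (DifferenceSpectrum(D, fly_ids, cond_a, cond_b,
                               spectra[0].channel_ids,
                               spectra[0].freq_grid.copy()),
            EffectSizeMap(d))


_ADJ4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _max_cluster_mass(t: np.ndarray, crit: float) -> float:
    best = 0.0
    for mask in (t > crit, t < -crit):
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=_ADJ4)
        if n:
            masses = ndimage.sum(np.abs(t), lab, index=np.arange(1, n + 1))
            best = max(best, float(np.max(masses)))
    return best


def cluster_permutation(diff: DifferenceSpectrum | np.ndarray,
                        alpha: float = 0.05,
                        n_perm: int | str = "all",
                        seed: int = 0) -> ClusterTestResult:
    """One-sample cluster permutation test on per-fly difference maps.

    t per cell (df = n-1); same-sign cells with |t| above the two-sided
    critical value are joined by 4-connectivity; cluster mass is the sum of
    |t|.  The null flips the sign of whole fly rows: all 2^n flips when
    n <= 14, else ``n_perm`` random flips.  cluster_p is the fraction of
    null max-masses >= the observed mass (ties count, conservative).
    """
    D = diff.diff_db if isinstance(diff, DifferenceSpectrum) else np.asarray(diff)
    n = D.shape[0]
    if n < 5:
        raise ValueError("need at least 5 flies for the permutation test")
    shape = D.shape[1:]
    D2 = D.reshape(n, -1)
    SS = (D2 ** 2).sum(axis=0)
    if np.any(SS - n * (D2.mean(axis=0)) ** 2 <= 1e-300):
        warnings.warn("zero variance at some cells: t set to 0 there")
    crit = float(stats.t.ppf(1 - alpha / 2, df=n - 1))

    def tmap(signs: np.ndarray) -> np.ndarray:
        M = signs @ D2 / n
        var = (SS - n * M ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 1e-300, M / np.sqrt(var / n), 0.0)
        return t

    t_obs = tmap(np.ones((1, n)))[0].reshape(shape)
    # observed clusters
    clusters, masses = [], []
    for mask in (t_obs > crit, t_obs < -crit):
        lab, k = ndimage.label(mask, structure=_ADJ4)
        for j in range(1, k + 1):
            m = lab == j
            clusters.append(m)
            masses.append(float(np.abs(t_obs)[m].sum()))
    order = np.argsort(masses)[::-1]
    clusters = [clusters[i] for i in order]
    masses = np.array([masses[i] for i in order])

    if n_perm == "all" and n <= 14:
        total = 2 ** n
        def sign_batches(batch=2048):
            for start in range(0, total, batch):
                idx = np.arange(start, min(start + batch, total))
                yield 1.0 - 2.0 * ((idx[:, None] >> np.arange(n)) & 1)
        n_null = total
    else:
        m = int(n_perm) if n_perm != "all" else 1024
        rng = np.random.default_rng(seed)
        def sign_batches(batch=2048):
            left = m
            while left > 0:
                k = min(batch, left)
                yield rng.choice([-1.0, 1.0], size=(k, n))
                left -= k
        n_null = m

    null_max = np.empty(n_null)
    pos = 0
    for S in sign_batches():
        T = tmap(S)
        for r in range(T.shape[0]):
            null_max[pos] = _max_cluster_mass(T[r].reshape(shape), crit)
            pos += 1
    # ties count as >= (conservative); tolerance guards float summation
    # order noise so the identity permutation always ties itself
    cluster_p = np.array([(null_max >= mval - 1e-9 * (1 + abs(mval))).mean()
                          for mval in masses])
    return ClusterTestResult(t_obs, clusters, cluster_p, masses, n_null,
                             alpha, null_max)


@dataclass
class SignPosthoc:
    mean_diff: float
    per_fly: np.ndarray
    t: float
    p: float
    sign: str                      # 'positive' | 'negative' | 'undetermined'


def cluster_sign_posthoc(diff: DifferenceSpectrum | np.ndarray,
                         cluster_mask: np.ndarray,
                         alpha: float = 0.05) -> SignPosthoc:
    """Direction of the effect inside a cluster: one-sample t on the per-fly
    mean difference within the mask."""
    D = diff.diff_db if isinstance(diff, DifferenceSpectrum) else np.asarray(diff)
    if not cluster_mask.any():
        raise ValueError("empty cluster mask")
    per_fly = D[:, cluster_mask].mean(axis=1)
    if np.allclose(per_fly.std(ddof=1), 0) and np.allclose(per_fly.mean(), 0):
        return SignPosthoc(0.0, per_fly, 0.0, 1.0, "undetermined")
    t, p = stats.ttest_1samp(per_fly, 0.0)
    mean = float(per_fly.mean())
    sign = "undetermined"
    if p < alpha:
        sign = "positive" if mean > 0 else "negative"
    return SignPosthoc(mean, per_fly, float(t), float(p), sign)
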