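"""Spectral estimation and the cluster permutation test, checked against
closed forms and brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from flysleep.intervals import StageInterval
from flysleep.lfp import EpochSet, ReferencedLFP, epoch_by_labels
from flysleep.spectra import (FREQ_GRID, cluster_permutation,
                              cluster_sign_posthoc, condition_contrast,
                              epoch_spectrum, SpectralMatrix)


def _epochs_from(data_list, fs=250.0, labels=None, epoch_s=60.0):
    arr = np.stack(data_list).astype(np.float32)
    n = arr.shape[0]
    labels = np.array(labels if labels is not None else ["x"] * n,
                      dtype=object)
    return EpochSet(arr, fs, epoch_s, labels, np.array(["mid"] * n, object),
                    np.zeros(n, int), tuple(k for k in range(1, 17) if k != 11))


class TestEpochSpectrum:
    def test_output_shape_15x145(self):
        rng = np.random.default_rng(0)
        es = _epochs_from([rng.normal(size=(15, 15000))])
        sm = epoch_spectrum(es)
        assert sm.power_db.shape == (1, 15, 145)
        assert sm.freq_grid.size == 145
        assert sm.freq_grid[0] == 5.0 and sm.freq_grid[-1] == 40.0
        assert np.all(np.isfinite(sm.power_db))

    def test_amplitude_doubling_6db(self):
        fs = 250.0
        t = np.arange(15000) / fs
        base = np.sin(2 * np.pi * 10 * t)
        e1 = np.tile(base, (15, 1))
        e2 = np.tile(2 * base, (15, 1))
        sm = epoch_spectrum(_epochs_from([e1, e2]), prefilter=False)
        j = int(np.argmin(np.abs(sm.freq_grid - 10.0)))
        diff = sm.power_db[1, 0, j] - sm.power_db[0, 0, j]
        assert abs(diff - 20 * np.log10(2)) < 0.1

    def test_white_noise_flat(self):
        rng = np.random.default_rng(1)
        sms = [epoch_spectrum(_epochs_from([rng.normal(size=(15, 15000))]),
                              prefilter=False) for _ in range(5)]
        slopes = []
        for sm in sms:
            y = sm.power_db[0].mean(axis=0)
            slopes.append(np.polyfit(sm.freq_grid, y, 1)[0])
        assert abs(np.mean(slopes)) < 0.01      # dB per Hz

    def test_too_short_epoch_rejected(self):
        es = _epochs_from([np.zeros((15, 100))], epoch_s=0.4)
        with pytest.raises(ValueError):
            epoch_spectrum(es)

    def test_parseval_band_power(self):
        """Integrated 5-40 Hz grid power tracks the time-domain variance of
        the 5-40 Hz filtered signal within 5%."""
        from scipy import signal as sg
        rng = np.random.default_rng(2)
        fs = 250.0
        x = rng.normal(size=(15, 60000))
        es = _epochs_from([x[:, :15000], x[:, 15000:30000],
                           x[:, 30000:45000], x[:, 45000:]])
        sm = epoch_spectrum(es)
        lin = 10 ** (sm.power_db / 10.0)
        df = np.diff(sm.freq_grid).mean()
        band_power = lin.mean(axis=0).mean(axis=0).sum() * df
        taps = sg.firwin(413, [5.0, 40.0], pass_zero=False, fs=fs)
        xf = sg.fftconvolve(x, taps[None, :], mode="same", axes=1)
        var = xf[:, 1000:-1000].var()
        assert abs(band_power - var) / var < 0.05


class TestConditionContrast:
    def _sm(self, fly, rng, n_a=12, n_b=12, shift=0.0):
        p = rng.normal(size=(n_a + n_b, 15, 145))
        p[:n_a] += shift
        labels = np.array(["a"] * n_a + ["b"] * n_b, dtype=object)
        return SpectralMatrix(p, FREQ_GRID.copy(), labels,
                              np.array(["mid"] * (n_a + n_b), object),
                              np.zeros(n_a + n_b, int),
                              tuple(k for k in range(1, 17) if k != 11),
                              fly, 60.0)

    def test_identical_conditions_zero(self):
        rng = np.random.default_rng(0)
        sms = [self._sm(i, rng) for i in range(6)]
        for sm in sms:
            sm.power_db[sm.labels == "a"] = sm.power_db[sm.labels == "b"]
        diff, d = condition_contrast(sms, "a", "b")
        assert np.allclose(diff.diff_db, 0)
        assert np.allclose(d.d, 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        sms = [self._sm(i, rng, shift=0.5) for i in range(6)]
        diff, d = condition_contrast(sms, "a", "b")
        # hand-coded two-pass oracle
        per_fly = []
        for sm in sms:
            ma, mb = sm.labels == "a", sm.labels == "b"
            per_fly.append(sm.power_db[ma].mean(0) - sm.power_db[mb].mean(0))
        per_fly = np.stack(per_fly)
        mean = per_fly.sum(axis=0) / per_fly.shape[0]
        sd = np.sqrt(((per_fly - mean) ** 2).sum(axis=0)
                     / (per_fly.shape[0] - 1))
        assert np.allclose(diff.diff_db, per_fly, atol=1e-12)
        assert np.allclose(d.d, mean / sd, atol=1e-12)

    def test_min_trial_exclusion(self):
        rng = np.random.default_rng(4)
        sms = [self._sm(0, rng, n_a=9, n_b=12), self._sm(1, rng)]
        diff, _ = condition_contrast(sms, "a", "b")
        assert diff.fly_ids == [1]
        with pytest.raises(ValueError):
            condition_contrast([self._sm(0, rng, n_a=2, n_b=2)], "a", "b")


def _bfs_max_mass(t, crit):
    """Independent oracle: max cluster mass by breadth-first search over
    4-connected same-sign supra-threshold cells."""
    C, F = t.shape
    seen = np.zeros((C, F), bool)
    best = 0.0
    for c in range(C):
        for f in range(F):
            if seen[c, f] or abs(t[c, f]) <= crit:
                continue
            sgn = np.sign(t[c, f])
            stack, mass = [(c, f)], 0.0
            seen[c, f] = True
            while stack:
                (i, j) = stack.pop()
                mass += abs(t[i, j])
                for (a, b) in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    if 0 <= a < C and 0 <= b < F and not seen[a, b] \
                            and abs(t[a, b]) > crit \
                            and np.sign(t[a, b]) == sgn:
                        seen[a, b] = True
                        stack.append((a, b))
            best = max(best, mass)
    return best


class TestClusterPermutation:
    def test_enumeration_matches_bruteforce_oracle(self):
        """For n=6 flies the sign-flip null equals full enumeration exactly
        (same max-mass distribution)."""
        rng = np.random.default_rng(0)
        D = rng.normal(size=(6, 4, 6)) + 0.8
        res = cluster_permutation(D)
        crit = float(stats.t.ppf(0.975, 5))
        oracle = []
        for signs in itertools.product([1.0, -1.0], repeat=6):
            S = np.asarray(signs)[:, None, None]
            X = D * S
            m = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            t = np.where(sd > 0, m / (sd / np.sqrt(6)), 0.0)
            oracle.append(_bfs_max_mass(t, crit))
        assert res.n_permutations == 64
        assert np.allclose(np.sort(res.null_max), np.sort(oracle),
                           atol=1e-9)

    def test_type_one_error_controlled(self):
        """Pure-noise per-fly differences produce a significant cluster in
        at most ~alpha of repeated fixtures."""
        rng = np.random.default_rng(1)
        hits = 0
        n_fix = 150
        for _ in range(n_fix):
            D = rng.normal(size=(7, 6, 10))
            res = cluster_permutation(D)
            hits += bool(res.significant())
        assert hits / n_fix <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_fix)

    def test_global_shift_one_cluster_all_channels(self):
        rng = np.random.default_rng(2)
        D = rng.normal(scale=0.5, size=(13, 15, 145)) + 2.0
        res = cluster_permutation(D)
        sig = res.significant()
        assert len(sig) == 1
        assert sig[0].all()

    def test_confined_effect_recovered(self):
        rng = np.random.default_rng(3)
        D = rng.normal(scale=0.4, size=(10, 15, 145))
        block = np.zeros((15, 145), bool)
        fmask = (FREQ_GRID >= 32) & (FREQ_GRID <= 40)
        block[:5, fmask] = True          # channels 1-5 x 32-40 Hz
        D[:, block] += 2.0
        res = cluster_permutation(D)
        sig = res.significant()
        assert len(sig) >= 1
        from scipy import ndimage
        dilated = ndimage.binary_dilation(
            block, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        assert sig[0][~dilated].sum() == 0
        assert (sig[0] & block).sum() > 0.9 * block.sum()

    def test_scaling_monotonicity(self):
        rng = np.random.default_rng(4)
        D = rng.normal(size=(8, 5, 8)) + 0.7
        p1 = cluster_permutation(D).cluster_p
        p2 = cluster_permutation(3.0 * D).cluster_p
        if p1.size and p2.size:
            assert p2[0] <= p1[0]

    def test_channel_relabeling_invariance(self):
        """Reversing channel order preserves adjacency, so cluster p values
        are unchanged."""
        rng = np.random.default_rng(5)
        D = rng.normal(size=(8, 6, 10)) + 0.6
        r1 = cluster_permutation(D)
        r2 = cluster_permutation(D[:, ::-1, :])
        assert np.allclose(np.sort(r1.cluster_p), np.sort(r2.cluster_p))

    def test_too_few_flies(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 5, 5)))


class TestSignPosthoc:
    def test_all_positive(self):
        D = np.abs(np.random.default_rng(0).normal(size=(8, 5, 5))) + 0.5
        mask = np.ones((5, 5), bool)
        ph = cluster_sign_posthoc(D, mask)
        assert ph.sign == "positive"

    def test_antisymmetric_undetermined(self):
        D = np.concatenate([np.ones((4, 5, 5)), -np.ones((4, 5, 5))])
        ph = cluster_sign_posthoc(D, np.ones((5, 5), bool))
        assert abs(ph.mean_diff) < 1e-12
        assert ph.sign == "undetermined"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cluster_sign_posthoc(np.ones((6, 5, 5)), np.zeros((5, 5), bool))
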