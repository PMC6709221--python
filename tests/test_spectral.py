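"""Morlet transform fidelity and wPLI-D estimator behaviour."""

import numpy as np
import pytest

from hinet.cardiac import EpochSet
from hinet.spectral import (
    ConnectivityStack,
    TFCoefficients,
    connectivity_stack,
    ecg_region_wpli,
    morlet_tf,
    morlet_wavelet,
    window_average,
    wpli_debiased,
)


def _epochs(data, fs=250.0, t0=-900.0):
    n_t = data.shape[1]
    taxis = t0 + np.arange(n_t) / fs * 1000.0
    return EpochSet(data=data, time_axis=taxis, sampling_rate=fs)


def _tone_epochs(freq=5.0, fs=250.0, n_trials=3, phase=0.0):
    n_t = int(2.7 * fs)
    t = (np.arange(n_t) / fs) - 0.9
    trace = np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(trace[None, :, None], (1, 1, n_trials))
    return _epochs(data, fs=fs)


class TestMorlet:
    def test_pure_tone_peak_frequency_and_phase_advance(self):
        tf = morlet_tf(_tone_epochs(freq=5.0), freqs=(4, 5, 6, 7))
        amp = np.abs(tf.coeffs[0, 0]).mean(axis=0)  # per frequency
        assert np.argmax(amp) == 1  # 5 Hz
        # phase advances 2*pi per 200 ms at 5 Hz
        phases = np.angle(tf.coeffs[0, 0, :, 1])
        step_200ms = 10  # 200 ms on the 20 ms grid
        dphi = np.exp(1j * (phases[step_200ms:] - phases[:-step_200ms]))
        assert np.allclose(dphi, 1.0, atol=0.05)

    def test_zero_signal_zero_coefficients(self):
        data = np.zeros((2, int(2.7 * 250), 2))
        tf = morlet_tf(_epochs(data))
        assert np.all(tf.coeffs == 0)

    def test_direct_convolution_oracle(self, rng):
        """FFT path matches an explicit time-domain sum to 1e-6 relative."""
        fs = 250.0
        data = rng.normal(size=(2, int(2.7 * fs), 3))
        eps = _epochs(data, fs=fs)
        tf = morlet_tf(eps, freqs=(4, 7), time_step=100.0)
        for fi, f in enumerate(tf.freqs):
            w = morlet_wavelet(f, fs, 4.0)
            h = (w.size - 1) // 2
            for gi, t_ms in enumerate(tf.time_points):
                idx = int(round((t_ms - eps.time_axis[0]) * fs / 1000.0))
                for ch in range(2):
                    for tr in range(3):
                        direct = sum(
                            data[ch, idx - m, tr] * w[m + h] for m in range(-h, h + 1)
                        )
                        got = tf.coeffs[ch, tr, gi, fi]
                        assert abs(got - direct) <= 1e-6 * max(1.0, abs(direct))

    def test_support_outside_epoch_errors(self):
        data = np.zeros((1, int(1.0 * 250), 2))  # 1 s epoch: too short for 4 Hz support
        with pytest.raises(ValueError, match="support"):
            morlet_tf(_epochs(data, t0=-300.0))

    def test_mne_phase_crosscheck(self):
        """Phase difference of two lagged 5 Hz tones matches mne's Morlet TF."""
        mne = pytest.importorskip("mne")
        fs, lag = 250.0, np.pi / 3
        e0 = _tone_epochs(5.0, fs)
        e1 = _tone_epochs(5.0, fs, phase=lag)
        data = np.concatenate([e0.data, e1.data], axis=0)
        tf = morlet_tf(_epochs(data, fs=fs), freqs=(5.0,), time_step=100.0,
                       time_range=(-200.0, 500.0))
        ours = np.angle(tf.coeffs[1, 0, :, 0]) - np.angle(tf.coeffs[0, 0, :, 0])
        arr = np.moveaxis(data, 2, 0)  # trials x ch x time
        out = mne.time_frequency.tfr_array_morlet(
            arr, sfreq=fs, freqs=[5.0], n_cycles=4.0, output="complex", verbose=False
        )
        idx = [int(round((t - e0.time_axis[0]) * fs / 1000.0)) for t in tf.time_points]
        theirs = np.angle(out[0, 1, 0, idx]) - np.angle(out[0, 0, 0, idx])
        delta = np.exp(1j * (ours - theirs))
        assert np.allclose(delta, 1.0, atol=1e-3)


class TestWpliDebiased:
    def test_perfect_lag_exactly_one(self):
        a = np.exp(1j * np.linspace(0, 5, 20))
        b = a * np.exp(-1j * np.pi / 2)  # constant +90 deg lag
        assert wpli_debiased(a, b) == 1.0

    def test_zero_lag_exactly_zero(self):
        a = np.exp(1j * np.linspace(0, 5, 20)) * np.linspace(1, 2, 20)
        assert wpli_debiased(a, a * 3.0) == 0.0

    def test_trial_mismatch_and_min_trials(self):
        with pytest.raises(ValueError):
            wpli_debiased(np.ones(3, complex), np.ones(4, complex))
        with pytest.raises(ValueError):
            wpli_debiased(np.ones(1, complex), np.ones(1, complex))

    def test_debiased_null_mean_near_zero(self, rng):
        """1000 independent-phase trial sets: estimator mean within 3 SE of 0."""
        vals = np.empty(1000)
        for k in range(1000):
            a = np.exp(1j * rng.uniform(0, 2 * np.pi, 20))
            b = np.exp(1j * rng.uniform(0, 2 * np.pi, 20))
            vals[k] = wpli_debiased(a, b)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_constant_gain_invariance(self, rng):
        a = np.exp(1j * rng.uniform(0, 2 * np.pi, 30))
        b = np.exp(1j * rng.uniform(0, 2 * np.pi, 30))
        base = wpli_debiased(a, b)
        assert wpli_debiased(3.7 * a, 0.2 * b) == pytest.approx(base, rel=1e-12)

    def test_zero_lag_mixing_immunity(self, rng):
        """Zero-lag mixing of two independent sources stays within the null."""
        n_rep, n_trials = 200, 100
        null = np.empty(n_rep)
        for k in range(n_rep):
            s1 = np.exp(1j * rng.uniform(0, 2 * np.pi, n_trials))
            s2 = np.exp(1j * rng.uniform(0, 2 * np.pi, n_trials))
            null[k] = abs(wpli_debiased(s1, s2))
        s1 = np.exp(1j * rng.uniform(0, 2 * np.pi, n_trials))
        s2 = np.exp(1j * rng.uniform(0, 2 * np.pi, n_trials))
        mixed = abs(wpli_debiased(s1 + 0.5 * s2, 0.5 * s1 + s2))
        assert mixed < np.quantile(null, 0.95)


class TestConnectivityStack:
    def _tf_random(self, rng, n_ch=4, n_tr=30, n_t=5, n_f=4):
        c = np.exp(1j * rng.uniform(0, 2 * np.pi, (n_ch, n_tr, n_t, n_f)))
        return TFCoefficients(c, np.arange(n_t) * 20.0, np.arange(4, 4 + n_f, 1.0), 4.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        st = connectivity_stack(self._tf_random(rng))
        assert np.allclose(st.wpli_d, np.transpose(st.wpli_d, (1, 0, 2)))
        assert np.all(np.diagonal(st.wpli_d, axis1=0, axis2=1) == 0)

    def test_matches_scalar_estimator(self, rng):
        tf = self._tf_random(rng)
        st = connectivity_stack(tf)
        manual = np.mean(
            [wpli_debiased(tf.coeffs[1, :, 2, f], tf.coeffs[3, :, 2, f]) for f in range(4)]
        )
        assert st.wpli_d[1, 3, 2] == pytest.approx(manual, rel=1e-12)

    def test_frequency_average_linearity(self, rng):
        tf = self._tf_random(rng)
        full = connectivity_stack(tf, freq_average=False).wpli_d
        avg = connectivity_stack(tf, freq_average=True).wpli_d
        assert np.allclose(avg, full.mean(axis=3))

    def test_too_few_trials_or_channels(self, rng):
        with pytest.raises(ValueError):
            connectivity_stack(self._tf_random(rng, n_tr=1))
        with pytest.raises(ValueError):
            connectivity_stack(self._tf_random(rng, n_ch=1))


class TestWindowAverage:
    def _stack(self):
        grid = -300.0 + 20.0 * np.arange(46)
        w = np.tile(np.arange(46.0)[None, None, :], (3, 3, 1))
        return ConnectivityStack(w, grid, (4.0, 7.0), 10)

    def test_point_counts_in_named_windows(self):
        st = self._stack()
        base = window_average(st, (-300.0, -100.0)).matrix
        ind = window_average(st, (200.0, 600.0)).matrix
        assert base[0, 1] == pytest.approx(np.mean(np.arange(0, 11)))  # 11 points
        assert ind[0, 1] == pytest.approx(np.mean(np.arange(25, 46)))  # 21 points

    def test_constant_stack(self):
        st = self._stack()
        st.wpli_d = np.full_like(st.wpli_d, 0.3)
        assert np.allclose(window_average(st, (200.0, 600.0)).matrix, 0.3)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError):
            window_average(self._stack(), (700.0, 800.0))


class TestEcgRegionWpli:
    def _tf(self, coeffs):
        n_t = coeffs.shape[2]
        grid = -300.0 + 20.0 * np.arange(n_t)
        return TFCoefficients(coeffs, grid, np.arange(4.0, 8.0), 4.0)

    def test_output_lengths_and_zero_lag_copy(self, rng):
        n_t = 46
        ecg = np.exp(1j * rng.uniform(0, 2 * np.pi, (1, 40, n_t, 4)))
        regions = np.exp(1j * rng.uniform(0, 2 * np.pi, (5, 40, n_t, 4)))
        regions[2] = 2.0 * ecg[0]  # exact zero-lag copy
        res = ecg_region_wpli(self._tf(ecg), self._tf(regions))
        assert res.baseline.shape == (5,) and res.induced.shape == (5,)
        assert res.baseline[2] == 0.0 and res.induced[2] == 0.0
        # independent regions hover near the estimator null
        assert np.abs(np.delete(res.induced, 2)).max() < 0.3
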