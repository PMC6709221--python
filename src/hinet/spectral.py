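"""Complex Morlet time-frequency decomposition and debiased wPLI connectivity.

The debiased weighted phase-lag index (wPLI-D) quantifies consistently lagged
phase relations between two signals across trials. Writing the per-trial
cross-spectrum Z_j = a_j * conj(b_j) and its imaginary part I_j,

    wPLI-D = [ (sum_j I_j)^2 - sum_j I_j^2 ] / [ (sum_j |I_j|)^2 - sum_j I_j^2 ]

which estimates the square of the weighted phase-lag index without the
positive sample-size bias of the direct estimator. Zero-lag (purely real)
cross-spectra give exactly 0, so connectivity driven by instantaneous linear
mixing (volume conduction / field spread) is suppressed by construction. The
estimator can be slightly negative in finite samples; raw values are reported
unclipped.

Wavelets are unit-energy complex Morlets with a Gaussian envelope
(sigma_t = n_cycles / (2 pi f)) truncated to a compact support of exactly
``n_cycles`` carrier periods, so the stated epoch padding requirement
(half the longest wavelet) is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .cardiac import EpochSet

__all__ = [
    "TFCoefficients",
    "ConnectivityStack",
    "WindowedMatrix",
    "EcgCoupling",
    "morlet_wavelet",
    "morlet_tf",
    "wpli_debiased",
    "connectivity_stack",
    "window_average",
    "ecg_region_wpli",
]

THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (14.0, 29.0)
DEFAULT_FREQS = (4.0, 5.0, 6.0, 7.0)
BASELINE_WINDOW = (-300.0, -100.0)
INDUCED_WINDOW = (200.0, 600.0)

_TOL_MS = 1e-6


@dataclass
class TFCoefficients:
    """Complex Morlet coefficients, channels x trials x time x frequency."""

    coeffs: np.ndarray
    time_points: np.ndarray  # ms relative to the R-peak
    freqs: np.ndarray  # Hz
    n_cycles: float

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class ConnectivityStack:
    """Frequency-averaged wPLI-D matrices, regions x regions x time."""

    wpli_d: np.ndarray
    time_points: np.ndarray
    band: tuple
    n_trials: int


@dataclass
class WindowedMatrix:
    """Time-averaged connectivity matrix over a named window (ms)."""

    matrix: np.ndarray
    window: tuple


@dataclass
class EcgCoupling:
    """Per-region ECG-cortex wPLI-D in the baseline and induced windows."""

    baseline: np.ndarray
    induced: np.ndarray
    timecourse: np.ndarray  # regions x time, frequency-averaged
    time_points: np.ndarray


def morlet_wavelet(freq: float, sampling_rate: float, n_cycles: float = 4.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet with compact n_cycles support."""
    half_s = n_cycles / (2.0 * freq)
    n_half = int(np.floor(half_s * sampling_rate))
    t = np.arange(-n_half, n_half + 1) / sampling_rate
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return w / np.linalg.norm(w)


def _resolve_epochs(epochs, time_axis, sampling_rate):
    if isinstance(epochs, EpochSet):
        return epochs.data, epochs.time_axis, epochs.sampling_rate
    data = np.asarray(epochs, dtype=float)
    if time_axis is None or sampling_rate is None:
        raise ValueError("raw arrays need time_axis (ms) and sampling_rate")
    return data, np.asarray(time_axis, dtype=float), float(sampling_rate)


def morlet_tf(
    epochs,
    freqs=DEFAULT_FREQS,
    n_cycles: float = 4.0,
    time_step: float = 20.0,
    time_range: tuple = (-300.0, 600.0),
    time_axis: np.ndarray | None = None,
    sampling_rate: float | None = None,
) -> TFCoefficients:
    """Morlet coefficients on a regular ms grid inside the epoch.

    ``epochs`` is an EpochSet (or a channels x time x trials array with
    explicit ``time_axis``/``sampling_rate``). Every requested grid point must
    keep the full wavelet support inside the epoch; otherwise an error is
    raised rather than returning edge-contaminated coefficients.
    """
    data, taxis, fs = _resolve_epochs(epochs, time_axis, sampling_rate)
    if data.ndim == 2:
        data = data[:, :, None]
    freqs = np.asarray(sorted(freqs), dtype=float)
    t0, t1 = time_range
    n_grid = int(round((t1 - t0) / time_step)) + 1
    grid = t0 + time_step * np.arange(n_grid)
    if grid[-1] > t1 + _TOL_MS:
        grid = grid[grid <= t1 + _TOL_MS]

    half_support_ms = 1000.0 * n_cycles / (2.0 * freqs.min())
    if grid[0] - half_support_ms < taxis[0] - _TOL_MS or grid[-1] + half_support_ms > taxis[-1] + _TOL_MS:
        raise ValueError(
            f"wavelet support (+/-{half_support_ms:.0f} ms at {freqs.min():g} Hz) exceeds the "
            f"epoch [{taxis[0]:.0f}, {taxis[-1]:.0f}] ms for the requested grid"
        )
    grid_idx = np.round((grid - taxis[0]) * fs / 1000.0).astype(int)
    if grid_idx.min() < 0 or grid_idx.max() >= taxis.size:
        raise ValueError("requested grid falls outside the epoch samples")

    swapped = np.ascontiguousarray(np.moveaxis(data, 2, 1))  # ch x trials x time
    out = np.empty(
        (data.shape[0], data.shape[2], grid_idx.size, freqs.size), dtype=np.complex128
    )
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, n_cycles)
        conv = _sig.fftconvolve(swapped.astype(np.complex128), w[None, None, :], mode="same", axes=2)
        out[:, :, :, fi] = conv[:, :, grid_idx]
    return TFCoefficients(coeffs=out, time_points=grid, freqs=freqs, n_cycles=n_cycles)


def wpli_debiased(coeffs_a: np.ndarray, coeffs_b: np.ndarray) -> float:
    """Debiased squared wPLI between two per-trial complex coefficient sets.

    Returns 0 when the denominator vanishes (all imaginary cross-spectrum
    parts zero: a pure zero-phase relation carries no lag evidence).
    """
    a = np.asarray(coeffs_a)
    b = np.asarray(coeffs_b)
    if a.shape != b.shape:
        raise ValueError("trial counts of the two channels differ")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need >= 2 trials")
    imag = _imag_cross(a, b)
    s = imag.sum()
    s2 = (imag**2).sum()
    sa = np.abs(imag).sum()
    den = sa**2 - s2
    if den == 0:
        return 0.0
    return float((s**2 - s2) / den)


def _imag_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Im(a * conj(b)) computed term-by-term.

    Written as ya*xb - xa*yb with separate rounding of the two products so
    that mathematically proportional channels (pure zero-lag relations) give
    exactly zero; the fused complex multiply leaves O(eps) residuals there.
    """
    return np.imag(a) * np.real(b) - np.real(a) * np.imag(b)


def _wpli_from_imag(imag: np.ndarray, trial_axis: int = -1) -> np.ndarray:
    """Vectorized debiased wPLI from imaginary cross-spectrum parts."""
    s = imag.sum(axis=trial_axis)
    s2 = (imag**2).sum(axis=trial_axis)
    sa = np.abs(imag).sum(axis=trial_axis)
    num = s**2 - s2
    den = sa**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), 0.0)
    return out


def connectivity_stack(tf: TFCoefficients, freq_average: bool = True) -> ConnectivityStack:
    """All-pairs wPLI-D per time point, averaged across frequencies.

    The diagonal is zero (a channel paired with itself is excluded) and the
    matrices are symmetric by construction.
    """
    c = tf.coeffs
    n_ch, n_tr, n_t, n_f = c.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if n_tr < 2:
        raise ValueError("need at least 2 trials")
    iu, ju = np.triu_indices(n_ch, k=1)
    stack = np.zeros((n_ch, n_ch, n_t, n_f))
    for ti in range(n_t):
        for fi in range(n_f):
            x = c[:, :, ti, fi]  # ch x trials
            imag = _imag_cross(x[iu], x[ju])  # pairs x trials
            vals = _wpli_from_imag(imag, trial_axis=-1)
            stack[iu, ju, ti, fi] = vals
            stack[ju, iu, ti, fi] = vals
    out = stack.mean(axis=3) if freq_average else stack
    return ConnectivityStack(
        wpli_d=out,
        time_points=tf.time_points,
        band=(float(tf.freqs.min()), float(tf.freqs.max())),
        n_trials=n_tr,
    )


def window_average(stack: ConnectivityStack, window: tuple) -> WindowedMatrix:
    """Mean matrix over time points whose centres lie in [start, end] inclusive."""
    w0, w1 = window
    sel = (stack.time_points >= w0 - _TOL_MS) & (stack.time_points <= w1 + _TOL_MS)
    if not sel.any():
        raise ValueError(f"window {window} contains no stack time points")
    return WindowedMatrix(matrix=stack.wpli_d[:, :, sel].mean(axis=2), window=(w0, w1))


def ecg_region_wpli(
    tf_ecg: TFCoefficients,
    tf_regions: TFCoefficients,
    baseline_window: tuple = BASELINE_WINDOW,
    induced_window: tuple = INDUCED_WINDOW,
) -> EcgCoupling:
    """wPLI-D between the ECG channel and every cortical region.

    Both inputs must be epoched on the same trial set and time grid. Returns
    per-region values averaged over each window plus the full frequency-
    averaged time course.
    """
    if tf_ecg.coeffs.shape[1:] != tf_regions.coeffs.shape[1:]:
        raise ValueError("ECG and region coefficients must share trials/grid/frequencies")
    if tf_ecg.n_channels != 1:
        raise ValueError("tf_ecg must contain exactly one channel")
    if tf_ecg.n_trials < 2:
        raise ValueError("need >= 2 trials")
    if not np.allclose(tf_ecg.time_points, tf_regions.time_points):
        warnings.warn("ECG and region time grids differ; using the region grid")
    e = tf_ecg.coeffs[0]  # trials x time x freq
    r = tf_regions.coeffs  # ch x trials x time x freq
    imag = _imag_cross(r, e[None])  # ch x trials x time x freq
    wpli = _wpli_from_imag(imag, trial_axis=1)  # ch x time x freq
    tc = wpli.mean(axis=2)  # ch x time

    def _win(window):
        w0, w1 = window
        sel = (tf_regions.time_points >= w0 - _TOL_MS) & (tf_regions.time_points <= w1 + _TOL_MS)
        if not sel.any():
            raise ValueError(f"window {window} contains no time points")
        return tc[:, sel].mean(axis=1)

    return EcgCoupling(
        baseline=_win(baseline_window),
        induced=_win(induced_window),
        timecourse=tc,
        time_points=tf_regions.time_points,
    )
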