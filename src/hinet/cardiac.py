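"""R-peak detection and heartbeat-locked epoching.

Implements the Pan-Tompkins QRS detector (band-pass, derivative, squaring,
moving-window integration, adaptive dual thresholds with search-back and a
200 ms refractory period), reassembly of segmented recordings with explicit
NaN gaps, and extraction of fixed-length epochs around each R-peak with
rejection of epochs that touch a gap.

Epochs here deliberately *may* overlap neighbouring heartbeats: the default
window (-900 ms .. +1800 ms) is wider than a typical interbeat interval, and
no overlap exclusion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simulate import RPeakTrain

__all__ = [
    "NoPeaksError",
    "ContinuousRecording",
    "EpochSet",
    "detect_rpeaks",
    "concatenate_segments",
    "extract_epochs",
    "ibi_summary",
]


class NoPeaksError(ValueError):
    """Raised when a trace contains no detectable QRS complexes."""


@dataclass
class ContinuousRecording:
    """Channels x samples data with an explicit missing-sample mask.

    Missing samples (e.g. removed bad segments) carry NaN in ``data`` and
    True in ``missing_mask``.
    """

    data: np.ndarray
    missing_mask: np.ndarray
    sampling_rate: float
    channel_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (self.data.shape[1],):
            raise ValueError("missing_mask length must equal the sample count")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Regions x time x trials array time-locked to R-peaks."""

    data: np.ndarray
    time_axis: np.ndarray  # ms relative to the R-peak
    sampling_rate: float
    n_rejected: int = 0
    n_boundary_dropped: int = 0
    channel_labels: list = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def _ms_to_samples(ms: float, sampling_rate: float) -> int:
    return int(round(ms * sampling_rate / 1000.0))


def detect_rpeaks(ecg: np.ndarray, sampling_rate: float) -> RPeakTrain:
    """Pan-Tompkins QRS detection on a single-channel ECG trace.

    Stages: 5-15 Hz band-pass (zero-phase Butterworth), differentiation,
    squaring, 150 ms moving-window integration, peak picking with a 200 ms
    refractory period, adaptive signal/noise thresholds, and search-back at
    half threshold when more than 1.66 x the running RR average elapses
    without a detection. Each detection is finally snapped to the local ECG
    maximum so the returned index is the R-peak sample itself.
    """
    x = np.asarray(ecg, dtype=float).ravel()
    fs = float(sampling_rate)
    if x.size < 2 * fs:
        raise ValueError("ECG trace must be at least 2 s long")
    if fs < 100:
        raise ValueError("sampling_rate must be at least 100 Hz")
    finite = np.isfinite(x)
    if not finite.any() or np.nanstd(x) == 0:
        raise NoPeaksError("flat or all-missing ECG trace")
    x = np.where(finite, x, 0.0)

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(filtered) * fs
    squared = deriv**2
    win = max(1, _ms_to_samples(150.0, fs))
    integrated = signal.fftconvolve(squared, np.ones(win) / win, mode="same")

    refractory = _ms_to_samples(200.0, fs)
    cand, _ = signal.find_peaks(integrated, distance=refractory)
    if cand.size == 0:
        raise NoPeaksError("no candidate peaks in the integrated signal")

    head = integrated[: int(2 * fs)]
    spki = 0.8 * head.max()
    npki = 0.5 * head.mean()
    qrs: list[int] = []
    rr: list[float] = []

    def thr1() -> float:
        return npki + 0.25 * (spki - npki)

    amps = integrated[cand]
    accepted = np.zeros(cand.size, dtype=bool)
    for k, (p, a) in enumerate(zip(cand, amps)):
        if a >= thr1():
            qrs.append(int(p))
            accepted[k] = True
            spki = 0.125 * a + 0.875 * spki
            if len(qrs) > 1:
                rr.append(qrs[-1] - qrs[-2])
                del rr[:-8]
        else:
            npki = 0.125 * a + 0.875 * npki
            # search-back: a beat was probably missed
            if qrs and rr and (p - qrs[-1]) > 1.66 * np.mean(rr):
                in_gap = (cand > qrs[-1]) & (cand <= p) & ~accepted
                if in_gap.any():
                    sub = np.where(in_gap)[0]
                    best = sub[np.argmax(amps[sub])]
                    if amps[best] >= 0.5 * thr1():
                        qrs.append(int(cand[best]))
                        accepted[best] = True
                        spki = 0.25 * amps[best] + 0.75 * spki
                        qrs.sort()
                        rr.append(qrs[-1] - qrs[-2])
                        del rr[:-8]
    if not qrs:
        raise NoPeaksError("no peaks crossed the adaptive threshold")

    # snap each detection to the local raw-ECG maximum
    half = _ms_to_samples(100.0, fs)
    refined = []
    for p in qrs:
        lo = max(0, p - half)
        hi = min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # enforce the refractory period on the refined peaks
    keep: list[int] = []
    for p in refined:
        if keep and p - keep[-1] < refractory:
            if x[p] > x[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return RPeakTrain(np.asarray(keep, dtype=np.int64), fs)


def concatenate_segments(
    segments: list[np.ndarray],
    original_positions: list[int],
    total_length: int,
    sampling_rate: float,
    channel_labels: list | None = None,
) -> ContinuousRecording:
    """Re-assemble segments at their original sample offsets.

    Samples covered by no segment are marked missing (NaN). Overlapping
    segments are an error.
    """
    if len(segments) != len(original_positions):
        raise ValueError("need one offset per segment")
    segments = [np.atleast_2d(np.asarray(s, dtype=float)) for s in segments]
    if not segments:
        raise ValueError("no segments given")
    n_ch = segments[0].shape[0]
    if any(s.shape[0] != n_ch for s in segments):
        raise ValueError("all segments must have the same channel count")
    data = np.full((n_ch, int(total_length)), np.nan)
    covered = np.zeros(int(total_length), dtype=bool)
    for seg, off in sorted(zip(segments, original_positions), key=lambda t: t[1]):
        off = int(off)
        if off < 0 or off + seg.shape[1] > total_length:
            raise ValueError("segment exceeds total_length")
        if covered[off : off + seg.shape[1]].any():
            raise ValueError("segments overlap")
        data[:, off : off + seg.shape[1]] = seg
        covered[off : off + seg.shape[1]] = True
    return ContinuousRecording(
        data=data,
        missing_mask=~covered,
        sampling_rate=sampling_rate,
        channel_labels=channel_labels or [],
    )


def extract_epochs(
    recording: ContinuousRecording | np.ndarray,
    rpeaks: RPeakTrain,
    window: tuple[float, float] = (-900.0, 1800.0),
) -> EpochSet:
    """One fixed-length epoch per R-peak, gap-containing epochs rejected.

    Peaks whose window exceeds the recording bounds are silently dropped
    (counted separately in ``n_boundary_dropped``); epochs overlapping any
    missing sample are rejected and counted in ``n_rejected``.
    """
    w0, w1 = window
    if not (w0 < 0 < w1):
        raise ValueError("window must straddle the R-peak (start < 0 < end)")
    if isinstance(recording, ContinuousRecording):
        data = recording.data
        missing = recording.missing_mask
        labels = list(recording.channel_labels)
    else:
        data = np.atleast_2d(np.asarray(recording, dtype=float))
        missing = ~np.all(np.isfinite(data), axis=0)
        labels = []
    fs = rpeaks.sampling_rate
    off0 = _ms_to_samples(w0, fs)
    n_times = _ms_to_samples(w1 - w0, fs)
    n_samples = data.shape[1]

    epochs = []
    n_rejected = 0
    n_boundary = 0
    for p in rpeaks.peak_samples:
        lo = int(p) + off0
        hi = lo + n_times
        if lo < 0 or hi > n_samples:
            n_boundary += 1
            continue
        if missing[lo:hi].any():
            n_rejected += 1
            continue
        epochs.append(data[:, lo:hi])
    if not epochs:
        raise ValueError("zero epochs survived extraction")
    stacked = np.stack(epochs, axis=-1)  # channels x time x trials
    time_axis = (off0 + np.arange(n_times)) / fs * 1000.0
    return EpochSet(
        data=stacked,
        time_axis=time_axis,
        sampling_rate=fs,
        n_rejected=n_rejected,
        n_boundary_dropped=n_boundary,
        channel_labels=labels,
    )


def ibi_summary(rpeaks: RPeakTrain) -> dict:
    """Mean/SD interbeat interval (ms) and the corresponding heart rate."""
    if len(rpeaks) < 2:
        raise ValueError("need at least two peaks to compute interbeat intervals")
    ibis = np.diff(rpeaks.peak_samples) * 1000.0 / rpeaks.sampling_rate
    mean_ibi = float(ibis.mean())
    return {
        "mean_ibi_ms": mean_ibi,
        "sd_ibi_ms": float(ibis.std(ddof=1)) if ibis.size > 1 else 0.0,
        "bpm": 60000.0 / mean_ibi,
        "n_beats": len(rpeaks),
    }
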