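"""Synthetic resting-state recordings with planted heartbeat-locked structure.

This module generates the inputs the heartbeat-induced-network analysis
expects: an ECG-like trace with a stereotyped QRS complex at each R-peak,
multi-region "source" time series with controllable heartbeat-*induced*
(time-locked but not phase-locked) theta coupling, heartbeat-*evoked*
(phase-locked) components, a linear forward (mixing) model, and affect survey
scores tied to a latent mood factor.

The defaults reflect the scale of a resting-state MEG study: ~195 cortical
regions, ~840 heartbeat epochs per subject, a 508.68 Hz sampling rate, and a
mean interbeat interval of 981.8 ms (SD 151.5 ms).

Induced vs evoked, operationally:

* an *induced* coupled edge injects, on each heartbeat (with probability
  ``coupling_prob``), a Hann-windowed theta burst into both endpoint regions.
  The burst's absolute phase is drawn uniformly per heartbeat, but the
  between-region phase difference is fixed at the edge's ``relative_phase_lag``
  — so the coupling is invisible to averaging across trials yet detectable by
  a lag-based phase metric.
* an *evoked* region receives the identical deterministic waveform on every
  heartbeat (constant phase across heartbeats). Each evoked region carries its
  own fixed phase offset, so distributed evoked responses produce spurious
  lagged phase relations between regions — the failure mode the
  trial-shuffled surrogate control is designed to expose.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "RPeakTrain",
    "SubjectRecording",
    "AFFECT_COLUMNS",
    "generate_rpeaks",
    "generate_sources",
    "generate_forward",
    "generate_affect",
    "simulate_subject",
    "simulate_group",
]

#: Physiological floor on the interbeat interval (ms); normal draws are
#: truncated below at this bound so QRS templates never coincide.
IBI_FLOOR_MS = 300.0

#: Epoch window (ms relative to the R-peak) the downstream analysis uses;
#: planted induced windows must fit inside it.
DEFAULT_EPOCH_WINDOW = (-900.0, 1800.0)

AFFECT_COLUMNS = [
    "anger_affect",
    "anger_hostility",
    "anger_aggression",
    "fear_affect",
    "fear_somatic",
    "sadness",
    "positive_affect",
]

_GOLDEN_ANGLE = 2.0 * math.pi * (1.0 - 1.0 / ((1.0 + math.sqrt(5.0)) / 2.0))


@dataclass
class SimulationConfig:
    """Parameters of one simulated subject.

    ``coupled_edges`` entries are ``(region_i, region_j, relative_phase_lag,
    coupling_prob)``; the lag is in radians and must not be 0 or pi (a purely
    real cross-spectrum carries no detectable lag).
    """

    n_regions: int = 195
    n_sensors: int = 248
    n_heartbeats: int = 840
    sampling_rate: float = 508.68
    mean_ibi: float = 981.8
    ibi_sd: float = 151.5
    coupled_edges: list = field(default_factory=list)
    carrier_freq: float = 5.5
    induced_window: tuple = (200.0, 600.0)
    burst_amplitude: float = 2.0
    evoked_regions: tuple = ()
    evoked_amplitude: float = 0.0
    noise_sd: float = 1.0
    pink_noise: bool = False
    mixing_condition: float = 5.0
    affect_slope: float = 0.0
    affect_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be non-negative")
        if self.n_regions < 1:
            raise ValueError("need at least one region")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.induced_window
        if not lo < hi:
            raise ValueError("induced_window must be ordered (start < end)")
        if lo < DEFAULT_EPOCH_WINDOW[0] or hi > DEFAULT_EPOCH_WINDOW[1]:
            raise ValueError(
                f"induced_window {self.induced_window} lies outside the epoch bounds "
                f"{DEFAULT_EPOCH_WINDOW}"
            )
        for edge in self.coupled_edges:
            i, j, lag, prob = edge
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"edge {edge} has a region index out of range")
            if i == j:
                raise ValueError("coupled edge endpoints must differ")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("coupling_prob must lie in [0, 1]")
            if abs(math.sin(lag)) < 1e-9:  # lag = 0 (mod pi): no imaginary cross-spectrum
                raise ValueError(
                    f"relative_phase_lag of edge {edge} is 0 or pi (mod 2*pi); "
                    "a lag-based metric cannot detect such coupling"
                )
        for r in self.evoked_regions:
            if not 0 <= r < self.n_regions:
                raise ValueError(f"evoked region {r} out of range")


@dataclass
class GroundTruth:
    """What was planted: edges, implied module labels, affect slope."""

    planted_edges: list
    planted_partition: np.ndarray
    affect_slope: float

    def to_dict(self) -> dict:
        return {
            "planted_edges": [[int(i), int(j)] for i, j in self.planted_edges],
            "planted_partition": [int(v) for v in self.planted_partition],
            "affect_slope": float(self.affect_slope),
        }


@dataclass
class RPeakTrain:
    """Strictly increasing R-peak sample indices at a given sampling rate."""

    peak_samples: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.peak_samples = np.asarray(self.peak_samples, dtype=np.int64)
        if self.peak_samples.ndim != 1:
            raise ValueError("peak_samples must be one-dimensional")
        if self.peak_samples.size and np.any(np.diff(self.peak_samples) <= 0):
            raise ValueError("peak_samples must be strictly increasing")

    @property
    def times_ms(self) -> np.ndarray:
        return self.peak_samples * 1000.0 / self.sampling_rate

    def __len__(self) -> int:
        return int(self.peak_samples.size)


@dataclass
class SubjectRecording:
    """One simulated subject's raw materials."""

    ecg: np.ndarray
    rpeaks: RPeakTrain
    sources: np.ndarray  # regions x samples
    leadfield: np.ndarray | None
    ground_truth: GroundTruth
    sampling_rate: float
    config: SimulationConfig


def _ecg_template(sampling_rate: float) -> tuple[np.ndarray, int]:
    """Stereotyped P-QRS-T waveform; returns (template, index of the R-peak)."""
    half_ms = 260.0
    n_half = int(round(half_ms * sampling_rate / 1000.0))
    t = np.arange(-n_half, n_half + 1) / sampling_rate * 1000.0  # ms
    waves = [  # (amplitude, center ms, width ms)
        (0.12, -180.0, 22.0),
        (-0.15, -22.0, 9.0),
        (1.00, 0.0, 11.0),
        (-0.22, 25.0, 10.0),
        (0.20, 160.0, 45.0),
    ]
    tpl = np.zeros_like(t)
    for amp, mu, sd in waves:
        tpl += amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return tpl, n_half


def generate_rpeaks(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[RPeakTrain, np.ndarray]:
    """Draw an R-peak train and synthesize the matching ECG trace.

    Interbeat intervals are Normal(mean_ibi, ibi_sd) truncated below at
    300 ms. The ECG is baseline noise plus the stereotyped template centred
    at every peak, padded by ~1 s before the first peak and ~2 s after the
    last so that epoching windows fit.
    """
    config.validate()
    if config.n_heartbeats == 0:
        raise ValueError("n_heartbeats is zero: cannot generate an empty R-peak train")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_ibi = config.n_heartbeats - 1
    if config.ibi_sd == 0:
        ibis = np.full(n_ibi, config.mean_ibi)
    else:
        a = (IBI_FLOOR_MS - config.mean_ibi) / config.ibi_sd
        ibis = stats.truncnorm.rvs(
            a, np.inf, loc=config.mean_ibi, scale=config.ibi_sd, size=n_ibi, random_state=rng
        )
    peak_times_ms = 1000.0 + np.concatenate(([0.0], np.cumsum(ibis)))
    fs = config.sampling_rate
    peak_samples = np.round(peak_times_ms * fs / 1000.0).astype(np.int64)
    n_samples = int(peak_samples[-1] + round(2.0 * fs))

    ecg = rng.normal(0.0, 0.02, n_samples)
    tpl, r_idx = _ecg_template(fs)
    for p in peak_samples:
        lo = p - r_idx
        hi = lo + tpl.size
        a = max(lo, 0)
        b = min(hi, n_samples)
        ecg[a:b] += tpl[a - lo : b - lo]
    return RPeakTrain(peak_samples, fs), ecg


def _pink_filter(noise: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Impose a 1/f amplitude spectrum on white noise (per row)."""
    spec = np.fft.rfft(noise, axis=-1)
    f = np.fft.rfftfreq(noise.shape[-1])
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz] / f[nz][0])
    out = np.fft.irfft(spec * scale, n=noise.shape[-1], axis=-1)
    # restore per-row variance
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd * noise.std(axis=-1, keepdims=True)


def _planted_partition(n_regions: int, edges: list) -> np.ndarray:
    """Module labels implied by the planted edge graph.

    Connected components of the planted graph are numbered 1..k; regions with
    no planted edge get label 0 (background).
    """
    labels = np.zeros(n_regions, dtype=np.int64)
    parent = list(range(n_regions))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, *_ in edges:
        parent[find(int(i))] = find(int(j))
    touched = sorted({int(v) for e in edges for v in e[:2]})
    roots = {}
    for v in touched:
        r = find(v)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[v] = roots[r]
    return labels


def generate_sources(
    config: SimulationConfig,
    rpeaks: RPeakTrain,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Region x time source array with planted induced/evoked structure."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    fs = config.sampling_rate
    if n_samples is None:
        n_samples = int(rpeaks.peak_samples[-1] + round(2.0 * fs))
    if np.any(rpeaks.peak_samples >= n_samples) or np.any(rpeaks.peak_samples < 0):
        raise ValueError("R-peaks fall outside the recording duration")
    w0, w1 = config.induced_window
    e0, e1 = DEFAULT_EPOCH_WINDOW
    if w0 < e0 or w1 > e1:
        raise ValueError(
            f"induced_window {config.induced_window} lies outside the epoch bounds {DEFAULT_EPOCH_WINDOW}"
        )

    sources = rng.normal(0.0, config.noise_sd, (config.n_regions, n_samples))
    if config.pink_noise and config.noise_sd > 0:
        sources = _pink_filter(sources, rng)

    i0 = int(round(w0 * fs / 1000.0))
    i1 = int(round(w1 * fs / 1000.0))
    burst_len = i1 - i0
    hann = np.hanning(burst_len)
    t_burst = (np.arange(burst_len) + i0) / fs  # seconds relative to the R-peak
    omega = 2.0 * math.pi * config.carrier_freq

    for (ri, rj, lag, prob) in config.coupled_edges:
        for p in rpeaks.peak_samples:
            if rng.random() >= prob:
                continue
            phase = rng.uniform(0.0, 2.0 * math.pi)
            lo = p + i0
            hi = p + i1
            if lo < 0 or hi > n_samples:
                continue
            burst_i = config.burst_amplitude * hann * np.cos(omega * t_burst + phase)
            burst_j = config.burst_amplitude * hann * np.cos(omega * t_burst + phase + lag)
            sources[int(ri), lo:hi] += burst_i
            sources[int(rj), lo:hi] += burst_j

    if config.evoked_amplitude != 0 and len(config.evoked_regions):
        for k, r in enumerate(config.evoked_regions):
            phase_r = (k * _GOLDEN_ANGLE) % (2.0 * math.pi)
            wave = config.evoked_amplitude * hann * np.cos(omega * t_burst + phase_r)
            for p in rpeaks.peak_samples:
                lo, hi = p + i0, p + i1
                if lo < 0 or hi > n_samples:
                    continue
                sources[int(r), lo:hi] += wave

    truth = GroundTruth(
        planted_edges=[(int(i), int(j)) for i, j, *_ in config.coupled_edges],
        planted_partition=_planted_partition(config.n_regions, config.coupled_edges),
        affect_slope=config.affect_slope,
    )
    return sources, truth


def generate_forward(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random sensors x regions mixing matrix with a controlled condition number.

    Built from an SVD with log-spaced singular values from 1 down to
    1/mixing_condition, so the matrix has full column rank and condition
    number exactly the requested bound (orthogonal columns when the bound
    is 1).
    """
    config.validate()
    if config.n_sensors < config.n_regions:
        raise ValueError("n_sensors must be >= n_regions for a full-column-rank leadfield")
    if config.mixing_condition < 1.0:
        raise ValueError("mixing_condition must be >= 1 (infeasible target)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    u, _ = np.linalg.qr(rng.normal(size=(config.n_sensors, config.n_regions)))
    v, _ = np.linalg.qr(rng.normal(size=(config.n_regions, config.n_regions)))
    s = np.geomspace(1.0, 1.0 / config.mixing_condition, config.n_regions)
    return (u * s) @ v.T


def generate_affect(
    config: SimulationConfig,
    module_sync_per_subject: np.ndarray,
    rng: np.random.Generator | None = None,
):
    """Seven affect scores per subject tied to a latent mood factor.

    latent mood = affect_slope * z(module sync) + noise; the positive-affect
    column loads positively on mood, the six negative columns load
    negatively. Scores are written on a T-score-like scale (50 +/- 10).
    """
    import pandas as pd

    sync = np.asarray(module_sync_per_subject, dtype=float)
    if sync.ndim != 1 or sync.size < 2:
        raise ValueError("need one synchronization value per subject (>=2 subjects)")
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    z = (sync - sync.mean()) / (sync.std() if sync.std() > 0 else 1.0)
    mood = config.affect_slope * z + rng.normal(0.0, config.affect_noise_sd, sync.size)
    loadings = {
        "anger_affect": -0.85,
        "anger_hostility": -0.80,
        "anger_aggression": -0.70,
        "fear_affect": -0.82,
        "fear_somatic": -0.72,
        "sadness": -0.80,
        "positive_affect": 0.82,
    }
    cols = {}
    for name in AFFECT_COLUMNS:
        unique = rng.normal(0.0, 0.6, sync.size)
        cols[name] = 50.0 + 10.0 * (loadings[name] * mood + unique)
    return pd.DataFrame(cols)


def simulate_subject(
    config: SimulationConfig, with_forward: bool = False
) -> SubjectRecording:
    """Generate one subject (ECG, R-peaks, sources, optional leadfield)."""
    rng = np.random.default_rng(config.seed)
    rpeaks, ecg = generate_rpeaks(config, rng)
    sources, truth = generate_sources(config, rpeaks, n_samples=ecg.size, rng=rng)
    leadfield = generate_forward(config, rng) if with_forward else None
    return SubjectRecording(
        ecg=ecg,
        rpeaks=rpeaks,
        sources=sources,
        leadfield=leadfield,
        ground_truth=truth,
        sampling_rate=config.sampling_rate,
        config=config,
    )


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Independent per-subject seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_subjects)]

def simulate_group(
    config: SimulationConfig, n_subjects: int, master_seed: int | None = None,
    with_forward: bool = False,
) -> list[SubjectRecording]:
    """Simulate i.i.d. subjects with per-subject seeds from a master seed."""
    if master_seed is None:
        master_seed = config.seed
    subjects = []
    for s in subject_seeds(master_seed, n_subjects):
        cfg = dataclasses.replace(config, seed=s)
        subjects.append(simulate_subject(cfg, with_forward=with_forward))
    return subjects
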