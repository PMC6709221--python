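"""Minimal forward/inverse source machinery.

Scalar (single-orientation) sources, a dense leadfield, an LCMV beamformer
with diagonal-loading regularization, and vertex-to-region averaging. This is
exactly the machinery the trial-shuffled surrogate control needs: shuffled
source data are pushed through the forward model and reconstructed with the
*same* spatial filter as the real data, so the surrogate inherits the linear
signal spread of acquisition plus inverse modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForwardModel",
    "InverseOperator",
    "project_to_sensors",
    "epochs_covariance",
    "lcmv_filter",
    "reconstruct_sources",
    "average_rois",
]


@dataclass
class ForwardModel:
    """Dense sensors x sources leadfield plus a source -> region map."""

    leadfield: np.ndarray
    labels: np.ndarray  # region index per source column

    def __post_init__(self):
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.leadfield.ndim != 2:
            raise ValueError("leadfield must be 2-D (sensors x sources)")
        if self.labels.shape != (self.leadfield.shape[1],):
            raise ValueError("need one region label per source")
        if np.linalg.matrix_rank(self.leadfield) < self.leadfield.shape[1]:
            raise ValueError("leadfield is column-rank deficient")

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_sources(self) -> int:
        return self.leadfield.shape[1]


@dataclass
class InverseOperator:
    """Sources x sensors spatial-filter weights."""

    weights: np.ndarray
    regularization: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("inverse weights must be finite")


def project_to_sensors(sources: np.ndarray, forward: ForwardModel) -> np.ndarray:
    """Apply the leadfield: (sources, time[, trials]) -> (sensors, time[, trials])."""
    sources = np.asarray(sources, dtype=float)
    if sources.shape[0] != forward.n_sources:
        raise ValueError(
            f"source count {sources.shape[0]} does not match leadfield columns {forward.n_sources}"
        )
    return np.tensordot(forward.leadfield, sources, axes=(1, 0))


def epochs_covariance(sensor_epochs: np.ndarray) -> np.ndarray:
    """Sensor covariance from all epochs' concatenated data."""
    x = np.asarray(sensor_epochs, dtype=float)
    x = x.reshape(x.shape[0], -1)
    x = x - x.mean(axis=1, keepdims=True)
    return x @ x.T / max(1, x.shape[1] - 1)


def lcmv_filter(
    forward: ForwardModel,
    sensor_covariance: np.ndarray,
    regularization: float = 0.05,
) -> InverseOperator:
    """Unit-gain LCMV beamformer weights, one row per source.

    w_s = (l_s' C^-1 l_s)^-1 l_s' C^-1 with C regularized by diagonal
    loading: C + regularization * mean(diag C) * I. By construction
    w_s l_s = 1 for every source (unit gain on its own leadfield column).
    """
    c = np.asarray(sensor_covariance, dtype=float)
    if c.shape != (forward.n_sensors, forward.n_sensors):
        raise ValueError("covariance shape does not match the sensor count")
    if not np.allclose(c, c.T, atol=1e-8 * max(1.0, np.abs(c).max())):
        raise ValueError("covariance must be symmetric")
    creg = c + regularization * np.mean(np.diag(c)) * np.eye(c.shape[0])
    try:
        cinv_l = np.linalg.solve(creg, forward.leadfield)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"regularized covariance is singular: {err}") from err
    denom = np.einsum("ij,ij->j", forward.leadfield, cinv_l)
    if np.any(np.abs(denom) < 1e-300) or not np.all(np.isfinite(denom)):
        raise np.linalg.LinAlgError("degenerate leadfield column under the regularized covariance")
    weights = (cinv_l / denom).T  # sources x sensors
    return InverseOperator(weights=weights, regularization=regularization)


def reconstruct_sources(sensor_epochs: np.ndarray, inverse: InverseOperator) -> np.ndarray:
    """Apply filter weights: (sensors, time[, trials]) -> (sources, time[, trials])."""
    x = np.asarray(sensor_epochs, dtype=float)
    if x.shape[0] != inverse.weights.shape[1]:
        raise ValueError(
            f"sensor count {x.shape[0]} does not match filter columns {inverse.weights.shape[1]}"
        )
    return np.tensordot(inverse.weights, x, axes=(1, 0))


def average_rois(
    source_epochs: np.ndarray, labels: np.ndarray, n_regions: int | None = None
) -> np.ndarray:
    """Average source traces within each region label.

    A region with zero member sources is an error (mirrors the exclusion of
    atlas regions in which time-course extraction failed).
    """
    x = np.asarray(source_epochs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (x.shape[0],):
        raise ValueError("need one region label per source")
    if n_regions is None:
        n_regions = int(labels.max()) + 1
    out = np.empty((n_regions,) + x.shape[1:], dtype=float)
    for r in range(n_regions):
        members = labels == r
        if not members.any():
            raise ValueError(f"region {r} has no member sources")
        out[r] = x[members].mean(axis=0)
    return out
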