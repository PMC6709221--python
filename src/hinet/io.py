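"""Annotated-array containers and plain-text exports.

Recordings travel in an HDF5 container with datasets /ecg, /sources,
/rpeaks, /leadfield and a sampling_rate attribute; ground truth is JSON;
partitions, metrics tables and edge lists are delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import GroundTruth, RPeakTrain

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "load_ground_truth",
    "write_partition",
    "write_edge_list",
    "write_matrix",
]


def save_recording(path, ecg, sources, rpeaks: RPeakTrain, sampling_rate,
                   leadfield=None, region_labels=None):
    with h5py.File(path, "w") as f:
        f.create_dataset("ecg", data=np.asarray(ecg, dtype=float))
        f.create_dataset("sources", data=np.asarray(sources, dtype=float))
        f.create_dataset("rpeaks", data=np.asarray(rpeaks.peak_samples, dtype=np.int64))
        if leadfield is not None:
            f.create_dataset("leadfield", data=np.asarray(leadfield, dtype=float))
        f.attrs["sampling_rate"] = float(sampling_rate)
        if region_labels:
            f.attrs["region_labels"] = [str(r) for r in region_labels]


def load_recording(path) -> dict:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        out = {
            "ecg": f["ecg"][()],
            "sources": f["sources"][()],
            "rpeaks": RPeakTrain(f["rpeaks"][()], fs),
            "sampling_rate": fs,
            "leadfield": f["leadfield"][()] if "leadfield" in f else None,
            "region_labels": list(f.attrs.get("region_labels", [])),
        }
    return out


def save_ground_truth(path, truth: GroundTruth):
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def load_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_edges=[tuple(e) for e in d["planted_edges"]],
        planted_partition=np.asarray(d["planted_partition"], dtype=np.int64),
        affect_slope=float(d["affect_slope"]),
    )


def write_partition(path, partition, region_labels=None):
    labels = region_labels or [f"region_{i}" for i in range(len(partition))]
    lines = [f"{name}\t{int(m)}" for name, m in zip(labels, partition)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(path, weights: np.ndarray, region_labels=None):
    n = weights.shape[0]
    labels = region_labels or [f"region_{i}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    lines = [
        f"{labels[i]}\t{labels[j]}\t{weights[i, j]:.6g}"
        for i, j in zip(iu, ju)
        if weights[i, j] != 0
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix(path, matrix: np.ndarray, region_labels=None):
    n = matrix.shape[0]
    labels = region_labels or [f"region_{i}" for i in range(n)]
    header = "\t".join([""] + list(map(str, labels)))
    rows = [header]
    for name, row in zip(labels, matrix):
        rows.append("\t".join([str(name)] + [f"{v:.6g}" for v in row]))
    Path(path).write_text("\n".join(rows) + "\n")
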