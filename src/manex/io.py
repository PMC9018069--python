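"""Tab-delimited readers and writers for ROI time series, matrices, trials.

ROI time-series layout: first row ROI labels, second row network labels,
then one row per volume.  Square matrices carry a single ROI-label header
row.  All floats are written at full precision so write-then-read is the
identity for finite values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_roi_timeseries",
    "read_roi_timeseries",
    "write_matrix",
    "read_matrix",
    "write_trials",
    "read_trials",
]

_FMT = "%.17g"


def write_roi_timeseries(path, data, roi_labels, network_labels) -> None:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(roi_labels):
        raise ValueError("data must be (volumes x ROIs) matching roi_labels")
    if len(network_labels) != len(roi_labels):
        raise ValueError("network_labels must match roi_labels")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, roi_labels)) + "\n")
        fh.write("\t".join(map(str, network_labels)) + "\n")
        np.savetxt(fh, data, fmt=_FMT, delimiter="\t")


def read_roi_timeseries(path):
    """Returns ``(data, roi_labels, network_labels)``; validates layout."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: expected 2 header rows plus data")
    roi_labels = lines[0].split("\t")
    network_labels = lines[1].split("\t")
    if len(set(roi_labels)) != len(roi_labels):
        dup = next(x for x in roi_labels if roi_labels.count(x) > 1)
        raise ValueError(f"{path}: duplicate ROI label {dup!r}")
    if len(network_labels) != len(roi_labels):
        raise ValueError(f"{path}: network label row length mismatch")
    p = len(roi_labels)
    rows = []
    for r, ln in enumerate(lines[2:], start=3):
        cells = ln.split("\t")
        if len(cells) != p:
            raise ValueError(f"{path}: ragged row {r} ({len(cells)} != {p} cells)")
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at row {r}: {exc}") from None
    return np.array(rows), roi_labels, network_labels


def write_matrix(path, m, labels) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("m must be square and match labels")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, labels)) + "\n")
        np.savetxt(fh, m, fmt=_FMT, delimiter="\t")


def read_matrix(path):
    """Returns ``(matrix, labels)`` from a labeled square TSV."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    labels = lines[0].split("\t")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate labels")
    p = len(labels)
    if len(lines) - 1 != p:
        raise ValueError(f"{path}: expected {p} rows, found {len(lines) - 1}")
    rows = []
    for r, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != p:
            raise ValueError(f"{path}: ragged row {r}")
        rows.append([float(c) for c in cells])
    return np.array(rows), labels


def write_trials(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format=_FMT)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
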