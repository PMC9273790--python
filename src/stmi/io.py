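"""Trial container and report I/O.

Trials travel in a single HDF5 file with datasets ``X`` (trials x 3 x
samples, channel order C3, Cz, C4), ``y`` (0 = left, 1 = right) and a
root attribute ``fs``.  An adapter ingests mat-style dictionaries with
``x_train`` / ``x_test`` / ``y_train`` arrays, the shape the competition
exports commonly take.  Reports serialize to JSON and round-trip
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import DataError
from .synthetic import LABELS, EEGTrial

__all__ = ["save_trials", "load_trials", "trials_from_arrays", "save_report_dict", "load_report_dict", "load_config_yaml"]


def save_trials(path: str | Path, trials: list[EEGTrial]) -> None:
    if not trials:
        raise DataError("no trials to save")
    fs = trials[0].fs
    X = np.stack([t.data for t in trials])
    y = np.array([LABELS.index(t.label) for t in trials], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("y", data=y)
        f.attrs["fs"] = fs


def load_trials(path: str | Path) -> list[EEGTrial]:
    with h5py.File(path, "r") as f:
        X = np.asarray(f["X"])
        y = np.asarray(f["y"])
        fs = int(f.attrs["fs"])
    return trials_from_arrays(X, y, fs)


def trials_from_arrays(X: np.ndarray, y: np.ndarray, fs: int) -> list[EEGTrial]:
    """Build trials from (n, 3, samples) data and 0/1 labels."""
    if X.ndim != 3 or X.shape[1] != 3:
        raise DataError(f"X must be (trials, 3, samples), got {X.shape}")
    if len(X) != len(y):
        raise DataError("X and y length mismatch")
    trials = []
    for i, (xi, yi) in enumerate(zip(X, y)):
        t = EEGTrial(data=xi, fs=fs, label=LABELS[int(yi)])
        t.trial_id = i
        trials.append(t)
    return trials


def save_report_dict(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2))


def load_report_dict(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
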