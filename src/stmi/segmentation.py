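"""Sliding-window trial segmentation and leakage-free train/test splitting.

Motor imagery starts at the cue (3 s into the trial); segments of 2, 3 or
4 s are slid over the post-cue span with a 250 ms stride to locate the
most discriminative time window.  Because neighboring windows overlap
almost entirely, the train/test split is performed at the *trial* level:
all windows of a trial land on the same side, so near-duplicate segments
can never leak across the split.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .synthetic import EEGTrial

__all__ = ["Segment", "sliding_windows", "train_test_split"]

_EPS = 1e-9


@dataclass
class Segment:
    """A fixed-length window cut from one trial."""

    data: np.ndarray  # (channels, samples)
    t_start: float  # seconds, relative to trial start
    t_end: float
    parent_trial_id: int
    label: str
    fs: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def sliding_windows(
    trial: EEGTrial,
    win_s: float,
    stride_s: float = 0.25,
    t_start: float = 3.0,
    t_end: float | None = None,
) -> list[Segment]:
    """Extract all windows [s, s+win_s] with s = t_start, t_start+stride, ...

    Windows are kept while s + win_s <= t_end (trial end by default), so
    the count is floor((t_end - t_start - win_s)/stride) + 1.  Sample
    indices are round(fs * t); every window in a run has the same sample
    count.
    """
    if t_end is None:
        t_end = trial.t0 + trial.n_samples / trial.fs
    if stride_s <= 0:
        raise ParameterError(f"stride must be positive, got {stride_s}")
    if win_s > t_end - t_start + _EPS:
        raise ParameterError(
            f"window of {win_s} s does not fit in [{t_start}, {t_end}] s"
        )
    n_samp = round(trial.fs * win_s)
    segments = []
    i = 0
    while t_start + i * stride_s + win_s <= t_end + _EPS:
        s = t_start + i * stride_s
        i0 = round(trial.fs * (s - trial.t0))
        segments.append(
            Segment(
                data=trial.data[:, i0 : i0 + n_samp],
                t_start=s,
                t_end=s + win_s,
                parent_trial_id=trial.trial_id,
                label=trial.label,
                fs=trial.fs,
            )
        )
        i += 1
    return segments


def train_test_split(
    segments: list[Segment], fraction: float = 0.5, seed: int = 0
) -> tuple[list[Segment], list[Segment]]:
    """Stratified trial-level split: fraction of trials per class to train.

    All windows of a trial go to the same side of the split, preventing
    leakage between overlapping windows; reproducible from the seed.
    """
    if not segments:
        raise ParameterError("cannot split an empty segment list")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")

    by_trial: dict[int, str] = {}
    for seg in segments:
        by_trial[seg.parent_trial_id] = seg.label
    per_class: dict[str, list[int]] = defaultdict(list)
    for tid in sorted(by_trial):
        per_class[by_trial[tid]].append(tid)

    rng = np.random.default_rng(seed)
    train_ids: set[int] = set()
    for label in sorted(per_class):
        ids = np.array(per_class[label])
        rng.shuffle(ids)
        n_train = round(fraction * len(ids))
        train_ids.update(ids[:n_train].tolist())

    train = [s for s in segments if s.parent_trial_id in train_ids]
    test = [s for s in segments if s.parent_trial_id not in train_ids]
    return train, test
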