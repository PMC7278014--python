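"""Sliding-window segmentation of continuous recordings into trials.

A preprocessed recording is cut into overlapping fixed-length windows
(default 4 s, advanced by 1 s), each window becoming one trial of shape
channels x window-samples. Windows are half-open in samples; a final
partial window is dropped rather than padded, so every trial has the same
shape. Each trial inherits the subject/state/group labels of its source
recording verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import Recording

__all__ = ["SegmentSet", "segment_recording", "segment_cohort", "Segmenter",
           "SegmentationError", "n_trials_expected"]


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentSet:
    """A stack of equally shaped trials with per-trial labels.

    Attributes
    ----------
    trials : ndarray, shape (n_trials, n_channels, window_samples)
    channels : list of canonical labels shared by all trials
    fs : sampling rate in Hz
    window_s, stride_s : segmentation parameters in seconds
    labels : DataFrame with columns subject_id, state, group (one row/trial)
    """

    trials: np.ndarray
    channels: list[str]
    fs: float
    window_s: float
    stride_s: float
    labels: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        if self.trials.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.labels is None or len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def select_channels(self, labels: list[str]) -> "SegmentSet":
        """Restrict all trials to the given channels, in the given order."""
        from .signal_io import LabelingError, normalize_label

        labels = [normalize_label(l) for l in labels]
        index = {c: i for i, c in enumerate(self.channels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise LabelingError(f"channels not present in trials: {missing}")
        rows = [index[l] for l in labels]
        return SegmentSet(
            trials=self.trials[:, rows, :].copy(),
            channels=list(labels),
            fs=self.fs,
            window_s=self.window_s,
            stride_s=self.stride_s,
            labels=self.labels.reset_index(drop=True),
        )


def n_trials_expected(n_samples: int, window: int, stride: int) -> int:
    """floor((L - W) / S) + 1 for a full-window sliding segmentation."""
    if n_samples < window:
        return 0
    return (n_samples - window) // stride + 1


def segment_recording(rec: Recording, window_s: float = 4.0,
                      stride_s: float = 1.0) -> SegmentSet:
    """Slice one recording into overlapping trials.

    Trials start at offsets 0, stride, 2*stride, ... while a full window
    still fits; no zero padding.
    """
    window = int(round(window_s * rec.fs))
    stride = int(round(stride_s * rec.fs))
    if window < 1 or stride < 1:
        raise SegmentationError("window and stride must be at least one sample")
    if rec.n_samples < window:
        raise SegmentationError(
            f"recording of {rec.duration_s:.3f} s is shorter than the "
            f"{window_s} s window"
        )
    n = n_trials_expected(rec.n_samples, window, stride)
    starts = np.arange(n) * stride
    trials = np.stack([rec.samples[:, s: s + window] for s in starts])
    labels = pd.DataFrame(
        {
            "subject_id": [rec.subject_id] * n,
            "state": [rec.state] * n,
            "group": [rec.group] * n,
        }
    )
    return SegmentSet(trials=trials, channels=list(rec.channels), fs=rec.fs,
                      window_s=window_s, stride_s=stride_s, labels=labels)


def segment_cohort(recordings, window_s: float = 4.0,
                   stride_s: float = 1.0) -> SegmentSet:
    """Segment several recordings and stack their trials in order."""
    parts = [segment_recording(r, window_s, stride_s) for r in recordings]
    if not parts:
        raise SegmentationError("no recordings to segment")
    chans = parts[0].channels
    fs = parts[0].fs
    for p in parts[1:]:
        if p.channels != chans or p.fs != fs:
            raise SegmentationError(
                "all recordings must share channel order and sampling rate"
            )
    return SegmentSet(
        trials=np.concatenate([p.trials for p in parts]),
        channels=chans,
        fs=fs,
        window_s=window_s,
        stride_s=stride_s,
        labels=pd.concat([p.labels for p in parts], ignore_index=True),
    )


class Segmenter:
    """Transformer-style wrapper over :func:`segment_recording`."""

    def __init__(self, window_s: float = 4.0, stride_s: float = 1.0):
        self.window_s = window_s
        self.stride_s = stride_s

    def fit(self, X=None, y=None):
        return self

    def transform(self, rec_or_list):
        if isinstance(rec_or_list, Recording):
            return segment_recording(rec_or_list, self.window_s, self.stride_s)
        return segment_cohort(rec_or_list, self.window_s, self.stride_s)

    def get_params(self, deep: bool = True) -> dict:
        return {"window_s": self.window_s, "stride_s": self.stride_s}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
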