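"""Reading and writing EEG recordings, montages, manifests and feature tables.

The pipeline works on 19 scalp channels of the International 10/20 system,
named with the older temporal labels (T3/T4/T5/T6 rather than T7/T8/P7/P8).
All readers normalise channel names to this canonical spelling so that the
rest of the pipeline can match channels by exact label.

Recordings are stored either as European Data Format (EDF) files or as
delimited text tables (CSV, one column per channel, header row of channel
labels). Sample values are microvolts throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_CHANNELS",
    "Recording",
    "Montage",
    "ManifestEntry",
    "CohortManifest",
    "LabelingError",
    "FormatError",
    "default_montage",
    "normalize_label",
    "read_recording",
    "write_recording_csv",
    "select_channels",
    "write_feature_table",
    "read_feature_table",
    "read_manifest",
    "write_manifest",
    "read_montage",
    "write_montage",
]

#: The 19 scalp electrodes of the montage, in a fixed canonical order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "T3", "T4", "T5", "T6",
    "C3", "C4", "Cz",
    "P3", "P4", "Pz",
    "O1", "O2",
)

#: Modern 10/10-style synonyms mapped back to the older 10/20 names used here.
_SYNONYMS = {
    "T7": "T3",
    "T8": "T4",
    "P7": "T5",
    "P8": "T6",
}

_CANONICAL_BY_UPPER = {c.upper(): c for c in CANONICAL_CHANNELS}
_SYNONYMS_BY_UPPER = {k.upper(): v for k, v in _SYNONYMS.items()}

STATES = ("rest", "task")
GROUPS = ("low_stress", "high_stress", "unknown")


class LabelingError(ValueError):
    """Channel labels could not be resolved against the montage."""


class FormatError(ValueError):
    """A delimited file does not have the expected layout."""


def normalize_label(label: str) -> str:
    """Map a channel label to its canonical 10/20 spelling.

    Matching is case-insensitive and accepts the modern temporal synonyms
    (``T7 -> T3`` etc.). Raises :class:`LabelingError` for unknown labels.
    """
    key = label.strip().upper()
    if key in _CANONICAL_BY_UPPER:
        return _CANONICAL_BY_UPPER[key]
    if key in _SYNONYMS_BY_UPPER:
        return _SYNONYMS_BY_UPPER[key]
    raise LabelingError(f"unknown channel label: {label!r}")


@dataclass
class Recording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    channels : list of str
        Ordered canonical 10/20 labels, one per row of ``samples``.
    fs : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Signal values in microvolts.
    state : {"rest", "task"}
        Recording condition: relaxed counting (rest) or serial-subtraction
        arithmetic (task, the stressor).
    group : {"low_stress", "high_stress", "unknown"}
        Subject-level stress group assigned from task performance.
    """

    subject_id: str
    channels: list[str]
    fs: float
    samples: np.ndarray
    state: str = "rest"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channels):
            raise LabelingError(
                f"{len(self.channels)} channel labels but "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise LabelingError(f"duplicate channel labels: {self.channels}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


@dataclass
class Montage:
    """Grouping of electrode labels by scalp site."""

    site_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for site, labels in self.site_map.items():
            dup = seen.intersection(labels)
            if dup:
                raise LabelingError(
                    f"labels {sorted(dup)} appear in more than one site"
                )
            seen.update(labels)

    @property
    def all_channels(self) -> list[str]:
        out: list[str] = []
        for labels in self.site_map.values():
            out.extend(labels)
        return out

    def site(self, name: str) -> list[str]:
        return list(self.site_map[name])


def default_montage() -> Montage:
    """The study montage: 19 electrodes over five scalp sites.

    The frontal site pools the prefrontal pair (Fp1, Fp2) with the other
    frontal electrodes, giving seven frontal channels in total.
    """
    return Montage(
        site_map={
            "frontal": ["Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8"],
            "temporal": ["T3", "T4", "T5", "T6"],
            "central": ["C3", "C4", "Cz"],
            "parietal": ["P3", "P4", "Pz"],
            "occipital": ["O1", "O2"],
        }
    )


@dataclass
class ManifestEntry:
    subject_id: str
    path: str
    state: str
    group: str
    fs: float


@dataclass
class CohortManifest:
    """Index of the files that make up a cohort of recordings."""

    entries: list[ManifestEntry] = field(default_factory=list)
    notes: str = ""

    def subjects(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.subject_id not in out:
                out.append(e.subject_id)
        return out

    def validate_two_state(self) -> None:
        """Check every subject has at least one rest and one task entry."""
        by_subject: dict[str, set[str]] = {}
        for e in self.entries:
            by_subject.setdefault(e.subject_id, set()).add(e.state)
        missing = {s: st for s, st in by_subject.items() if len(st) < 2}
        if missing:
            raise ValueError(
                f"subjects missing a rest or task recording: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# recording I/O


def _normalize_channel_list(raw_labels: Sequence[str]) -> tuple[list[str], list[int]]:
    """Normalise labels, dropping unresolvable ones with a warning.

    Returns the kept canonical labels and the indices of the kept columns.
    Raises if duplicates arise after normalisation.
    """
    kept_labels: list[str] = []
    kept_idx: list[int] = []
    dropped: list[str] = []
    for i, lab in enumerate(raw_labels):
        try:
            canon = normalize_label(lab)
        except LabelingError:
            dropped.append(lab)
            continue
        kept_labels.append(canon)
        kept_idx.append(i)
    if dropped:
        warnings.warn(
            f"dropping channels not in the 19-label montage: {dropped}",
            stacklevel=3,
        )
    if not kept_labels:
        raise LabelingError(f"no montage channels found among {list(raw_labels)}")
    if len(set(kept_labels)) != len(kept_labels):
        dups = sorted({l for l in kept_labels if kept_labels.count(l) > 1})
        raise LabelingError(f"duplicate channel labels after normalisation: {dups}")
    return kept_labels, kept_idx


def read_recording(path: str | Path, manifest_entry: ManifestEntry) -> Recording:
    """Read one recording (EDF or delimited CSV) described by a manifest entry.

    Channel labels are normalised to canonical spelling; channels that do not
    belong to the montage (reference/ground or auxiliary channels) are dropped
    with a warning. The channel order of the file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        samples, labels, fs = _read_edf(path)
    else:
        samples, labels, fs = _read_csv_recording(path, manifest_entry.fs)
    return Recording(
        subject_id=manifest_entry.subject_id,
        channels=labels,
        fs=fs,
        samples=samples,
        state=manifest_entry.state,
        group=manifest_entry.group,
    )


def _read_edf(path: Path) -> tuple[np.ndarray, list[str], float]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels, kept_idx = _normalize_channel_list(raw.ch_names)
    data = raw.get_data()[kept_idx] * 1e6  # mne loads Volts; we use microvolts
    return data, labels, float(raw.info["sfreq"])


def _read_csv_recording(path: Path, fs: float) -> tuple[np.ndarray, list[str], float]:
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise FormatError(f"empty recording table: {path}")
    labels, kept_idx = _normalize_channel_list([str(c) for c in df.columns])
    data = df.iloc[:, kept_idx].to_numpy(dtype=float).T
    if not np.isfinite(data).all():
        raise FormatError(f"non-numeric or non-finite values in {path}")
    return data, labels, float(fs)


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as a delimited table, one column per channel."""
    df = pd.DataFrame(rec.samples.T, columns=rec.channels)
    df.to_csv(path, index=False)


def select_channels(rec: Recording, labels: Sequence[str]) -> Recording:
    """Restrict a recording to the requested labels, in the requested order.

    Metadata is preserved; sample values are copied bit-exactly.
    """
    labels = [normalize_label(l) for l in labels]
    index = {c: i for i, c in enumerate(rec.channels)}
    missing = [l for l in labels if l not in index]
    if missing:
        raise LabelingError(f"channels not present in recording: {missing}")
    rows = [index[l] for l in labels]
    return rec.copy_with(channels=list(labels), samples=rec.samples[rows].copy())


# ---------------------------------------------------------------------------
# feature tables

_LABEL_COLUMNS = ("subject_id", "state", "group")


def write_feature_table(fm, path: str | Path) -> None:
    """Write a feature matrix as CSV with subject/state/group label columns."""
    if fm.n_trials == 0:
        raise ValueError("refusing to write an empty feature matrix")
    df = fm.labels[list(_LABEL_COLUMNS)].copy()
    for name in fm.feature_names:
        df[name] = fm.data[name].to_numpy()
    df.insert(0, "feature_set", fm.feature_set)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path):
    """Read a feature table written by :func:`write_feature_table`."""
    from .features import FeatureMatrix

    df = pd.read_csv(path)
    missing = [c for c in ("feature_set",) + _LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}: {path}")
    tags = df["feature_set"].unique()
    if len(tags) != 1:
        raise FormatError(f"mixed feature_set tags in one table: {tags}")
    feature_cols = [c for c in df.columns if c not in ("feature_set",) + _LABEL_COLUMNS]
    if not feature_cols:
        raise FormatError(f"no feature columns in {path}")
    data = df[feature_cols]
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise FormatError(f"non-finite feature values in {path}")
    labels = df[list(_LABEL_COLUMNS)].astype(str).reset_index(drop=True)
    return FeatureMatrix(data=data.reset_index(drop=True), labels=labels,
                         feature_set=str(tags[0]))


# ---------------------------------------------------------------------------
# YAML montage / manifest


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"sites": montage.site_map}, fh, sort_keys=False)


def read_montage(path: str | Path) -> Montage:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    sites = {
        site: [normalize_label(l) for l in labels]
        for site, labels in doc["sites"].items()
    }
    return Montage(site_map=sites)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    doc = {
        "notes": manifest.notes,
        "entries": [dataclasses.asdict(e) for e in manifest.entries],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: str | Path) -> CohortManifest:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    entries = [ManifestEntry(**e) for e in doc.get("entries", [])]
    return CohortManifest(entries=entries, notes=doc.get("notes", ""))


def load_cohort(manifest: CohortManifest, base_dir: str | Path = ".") -> Iterable[Recording]:
    """Yield the recordings of a manifest in entry order."""
    base = Path(base_dir)
    for entry in manifest.entries:
        p = Path(entry.path)
        if not p.is_absolute():
            p = base / p
        yield read_recording(p, entry)
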