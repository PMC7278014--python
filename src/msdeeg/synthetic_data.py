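"""Synthetic EEG cohorts with the statistical structure the pipeline assumes.

Each subject contributes one rest recording (relaxed counting, 3 min by
default) and one task recording (serial-subtraction arithmetic, 1 min),
sampled at 500 Hz on the 19-channel 10/20 montage. Subjects belong to a
low-stress or high-stress group (default split 26/10, an imbalanced cohort).

A recording is a sum of band-limited stochastic oscillations — Gaussian
noise band-passed into the delta (0.5-4 Hz), theta (4-8), alpha (8-13) and
beta (13-30 Hz) bands and scaled to a configured RMS amplitude — plus white
sensor noise and an optional 50 Hz power-line component. Stress is emulated
as multiplicative band-power changes concentrated on the frontal channels:
task-state recordings show beta enhancement and alpha suppression, and
high-stress subjects show a stronger beta response during the task. Each
subject carries a random overall gain and per-band power jitter, so
leave-one-subject-out validation is genuinely harder than trial-wise
cross-validation.

Everything is driven by one seed; the same seed reproduces the cohort
bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .signal_io import (CANONICAL_CHANNELS, CohortManifest, ManifestEntry,
                        Recording, write_manifest, write_recording_csv)

__all__ = [
    "BANDS",
    "GeneratorConfig",
    "default_task_effects",
    "default_group_effects",
    "generate_recording",
    "generate_cohort",
    "iter_cohort",
    "write_cohort",
]

#: EEG frequency bands in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_FRONTAL = ("Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8")


def default_task_effects() -> dict[str, dict[str, float]]:
    """Band-power multipliers applied during the arithmetic task.

    The classic frontal desynchronization signature of strenuous mental
    load: beta power rises sharply while alpha and the slow bands drop.
    Posterior channels are untouched, so frontal electrodes carry the
    discriminative signal.
    """
    return {ch: {"beta": 4.5, "alpha": 0.3, "theta": 0.6, "delta": 0.5}
            for ch in _FRONTAL}


def default_group_effects() -> dict[str, dict[str, float]]:
    """Extra multipliers for high-stress subjects' task recordings.

    Subjects who struggle with the task show a stronger frontal response
    (more beta, less theta suppression) on top of the common task effect.
    """
    return {ch: {"beta": 2.0, "theta": 1.6} for ch in _FRONTAL}


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator.

    ``band_amps`` are per-band RMS amplitudes in microvolts at rest;
    ``noise_sd`` the white sensor-noise standard deviation;
    ``subject_gain_sd`` / ``band_jitter_sd`` the log-scale spreads of the
    per-subject overall gain and per-subject per-band power jitter.
    Effect maps give multiplicative band-POWER changes per channel.
    """

    n_subjects: int = 36
    group_split: tuple[int, int] = (26, 10)  # (low_stress, high_stress)
    fs: float = 500.0
    rest_s: float = 180.0
    task_s: float = 60.0
    band_amps: dict = field(default_factory=lambda: {
        "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 8.0})
    noise_sd: float = 3.0
    line_noise_amp: float = 2.0
    line_freq: float = 50.0
    task_effects: dict = field(default_factory=default_task_effects)
    group_effects: dict = field(default_factory=default_group_effects)
    subject_gain_sd: float = 0.10
    band_jitter_sd: float = 0.15
    seed: int = 0

    def validate(self, window_s: float = 4.0) -> None:
        if sum(self.group_split) != self.n_subjects:
            raise ValueError(
                f"group_split {self.group_split} does not sum to "
                f"n_subjects={self.n_subjects}"
            )
        if min(self.rest_s, self.task_s) < window_s:
            raise ValueError(
                f"recording durations must cover the {window_s} s window"
            )
        if self.fs <= 2 * max(hi for _, hi in BANDS.values()):
            raise ValueError("sampling rate too low for the configured bands")

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def group_of(self, subject_id: str) -> str:
        idx = self.subject_ids().index(subject_id)
        return "low_stress" if idx < self.group_split[0] else "high_stress"


def _rng(cfg: GeneratorConfig, subject_id: str, stream: int) -> np.random.Generator:
    # subject-keyed, platform-stable derivation from the master seed
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, zlib.crc32(subject_id.encode()), stream])
    )


def _subject_params(cfg: GeneratorConfig, subject_id: str):
    rng = _rng(cfg, subject_id, 0xA11CE)
    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd)))
    jitter = {b: float(np.exp(rng.normal(0.0, cfg.band_jitter_sd)))
              for b in BANDS}
    return gain, jitter


def _band_component(rng: np.random.Generator, n_ch: int, n: int,
                    lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, one row per channel."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def generate_recording(cfg: GeneratorConfig, subject_id: str, state: str,
                       group: str) -> Recording:
    """Simulate one recording of one subject in one state.

    The same configuration and subject always reproduce the same recording;
    per-subject gain and band jitter are shared between the subject's rest
    and task recordings so that only the configured effects (plus noise
    realisation) differ between states.
    """
    cfg.validate()
    if state not in ("rest", "task"):
        raise ValueError(f"state must be rest or task, got {state!r}")
    n = int(round((cfg.rest_s if state == "rest" else cfg.task_s) * cfg.fs))
    n_ch = len(CANONICAL_CHANNELS)
    gain, jitter = _subject_params(cfg, subject_id)
    rng = _rng(cfg, subject_id, 1 if state == "rest" else 2)

    x = np.zeros((n_ch, n))
    for band, (lo, hi) in BANDS.items():
        comp = _band_component(rng, n_ch, n, lo, hi, cfg.fs)
        amp = np.full(n_ch, cfg.band_amps[band] * gain * np.sqrt(jitter[band]))
        if state == "task":
            for ci, ch in enumerate(CANONICAL_CHANNELS):
                mult = cfg.task_effects.get(ch, {}).get(band, 1.0)
                if group == "high_stress":
                    mult *= cfg.group_effects.get(ch, {}).get(band, 1.0)
                amp[ci] *= np.sqrt(mult)
        x += amp[:, None] * comp

    x += rng.normal(0.0, cfg.noise_sd, size=(n_ch, n))
    if cfg.line_noise_amp > 0:
        t = np.arange(n) / cfg.fs
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        x += cfg.line_noise_amp * np.sin(
            2 * np.pi * cfg.line_freq * t[None, :] + phases[:, None])

    return Recording(subject_id=subject_id, channels=list(CANONICAL_CHANNELS),
                     fs=cfg.fs, samples=x, state=state, group=group)


def iter_cohort(cfg: GeneratorConfig):
    """Yield (manifest entry, recording) pairs, one rest and one task per
    subject, without holding the whole cohort in memory."""
    cfg.validate()
    for sid in cfg.subject_ids():
        group = cfg.group_of(sid)
        for state in ("rest", "task"):
            entry = ManifestEntry(subject_id=sid, path=f"{sid}_{state}.csv",
                                  state=state, group=group, fs=cfg.fs)
            yield entry, generate_recording(cfg, sid, state, group)


def generate_cohort(cfg: GeneratorConfig) -> tuple[CohortManifest, list[Recording]]:
    """Materialise the full cohort: manifest plus recordings in entry order."""
    entries: list[ManifestEntry] = []
    recordings: list[Recording] = []
    for entry, rec in iter_cohort(cfg):
        entries.append(entry)
        recordings.append(rec)
    manifest = CohortManifest(entries=entries,
                              notes=f"synthetic cohort, seed={cfg.seed}")
    return manifest, recordings


def write_cohort(cfg: GeneratorConfig, out_dir: str | Path) -> CohortManifest:
    """Write the cohort as CSV recordings plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    for entry, rec in iter_cohort(cfg):
        write_recording_csv(rec, out / entry.path)
        entries.append(entry)
    manifest = CohortManifest(entries=entries,
                              notes=f"synthetic cohort, seed={cfg.seed}")
    write_manifest(manifest, out / "manifest.yaml")
    return manifest
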