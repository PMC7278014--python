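"""Hybrid time/frequency feature extraction from EEG trials.

Per channel and per trial, twelve features are computed:

* Frequency domain (feature set 1, 5 features): the median frequency MDF
  (frequency splitting the power spectral density into two halves of equal
  power), the amplitude-spectrum median MFMD (same construction on the
  amplitude spectrum), and the root spectral moments m0, m2, m4 — square
  roots of the 0th/2nd/4th frequency-index-weighted sums of the
  phase-excluded power spectrum ``P_k = |X_k X_k*| / N``.
* Time domain (feature set 2, 7 features): the root-mean-square amplitude
  and the six coefficients of a sixth-order autoregressive model
  ``x_i = sum_d a_d x_{i-d} + e`` fitted per channel.

Set 3 is the per-channel concatenation of sets 1 and 2, giving 12 features
per channel — 228 on the full 19-channel montage.

Spectra come from a single unwindowed periodogram of each 4-s trial. The
phase-excluded power spectrum is stored folded onto the one-sided grid
(interior bins doubled), so its plain sum equals the two-sided sum and, by
Parseval's theorem, the time-domain energy ``sum x_i^2``. The moment index
k is the one-sided frequency-bin index, not Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import SegmentSet

__all__ = [
    "SpectrumEstimate",
    "FeatureMatrix",
    "estimate_spectrum",
    "frequency_features",
    "time_features",
    "build_feature_matrix",
    "FeatureExtractor",
    "SET1_FEATURES",
    "SET2_FEATURES",
    "SET3_FEATURES",
]

SET1_FEATURES = ("mdf", "mfmd", "m0", "m2", "m4")
SET2_FEATURES = ("rms", "ar1", "ar2", "ar3", "ar4", "ar5", "ar6")
SET3_FEATURES = SET1_FEATURES + SET2_FEATURES

_FEATURES_BY_SET = {"set1": SET1_FEATURES, "set2": SET2_FEATURES,
                    "set3": SET3_FEATURES}

AR_ORDER = 6


class DataError(ValueError):
    """Input samples are unusable (non-finite, or degenerate spectrum)."""


@dataclass
class SpectrumEstimate:
    """One-sided spectral estimates of a single trial channel.

    ``pk`` is the phase-excluded power spectrum |X_k|^2 / N folded onto the
    one-sided grid, so ``pk.sum()`` equals the full two-sided sum and hence
    the time-domain energy (Parseval). ``psd`` is ``pk / fs``; ``amp`` is
    the amplitude spectrum scaled so a unit sinusoid peaks near 1.
    """

    freqs: np.ndarray
    psd: np.ndarray
    amp: np.ndarray
    pk: np.ndarray
    fs: float
    n: int


def _fold_onesided(power_two_sided_half: np.ndarray, n: int) -> np.ndarray:
    """Fold |X_k|^2-type quantities from rfft output onto one-sided bins."""
    folded = power_two_sided_half.copy()
    if n % 2 == 0:
        folded[..., 1:-1] *= 2.0  # Nyquist bin is unique
    else:
        folded[..., 1:] *= 2.0
    return folded


def estimate_spectrum(trial_channel: np.ndarray, fs: float) -> SpectrumEstimate:
    """Periodogram-style spectral estimate of one trial channel."""
    x = np.asarray(trial_channel, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("trial channel must be a 1-D vector of length >= 4")
    if not np.isfinite(x).all():
        raise DataError("non-finite samples in trial")
    n = x.size
    X = np.fft.rfft(x)
    mag2 = np.abs(X) ** 2
    pk = _fold_onesided(mag2, n) / n
    psd = pk / fs
    amp = np.abs(X) / n
    if n % 2 == 0:
        amp[1:-1] *= 2.0
    else:
        amp[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumEstimate(freqs=freqs, psd=psd, amp=amp, pk=pk, fs=fs, n=n)


def _half_mass_frequency(freqs: np.ndarray, weights: np.ndarray) -> float:
    """First grid frequency where the cumulative weight reaches half the total."""
    total = weights.sum()
    if total <= 0:
        raise DataError("all-zero spectrum: median frequency undefined")
    idx = int(np.searchsorted(np.cumsum(weights), 0.5 * total))
    return float(freqs[min(idx, len(freqs) - 1)])


def frequency_features(spec: SpectrumEstimate, root_moments: bool = True):
    """MDF, MFMD and the spectral moments m0, m2, m4 of one spectrum.

    MDF/MFMD return the first grid frequency at which the cumulative PSD /
    amplitude spectrum meets half its total (no interpolation). Moments are
    frequency-bin-index weighted sums of the phase-excluded power spectrum;
    with ``root_moments`` their square roots are returned, giving m0 the
    units of the signal energy's square root.
    """
    mdf = _half_mass_frequency(spec.freqs, spec.psd)
    mfmd = _half_mass_frequency(spec.freqs, spec.amp)
    k = np.arange(spec.pk.size, dtype=float)
    m0 = spec.pk.sum()
    m2 = (k**2 * spec.pk).sum()
    m4 = (k**4 * spec.pk).sum()
    if root_moments:
        m0, m2, m4 = np.sqrt(m0), np.sqrt(m2), np.sqrt(m4)
    return mdf, mfmd, float(m0), float(m2), float(m4)


# ---------------------------------------------------------------------------
# autoregressive fit


def _autocov_batch(x: np.ndarray, maxlag: int) -> np.ndarray:
    """Biased autocovariances r_0..r_maxlag of each row, via FFT."""
    x = x - x.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    F = np.fft.rfft(x, n=nfft, axis=-1)
    acov = np.fft.irfft(np.abs(F) ** 2, n=nfft, axis=-1)[..., : maxlag + 1]
    return acov / n


def _yule_walker_batch(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Yule-Walker AR coefficients for each row of ``x``.

    Solves the Toeplitz normal equations built from biased autocovariances.
    Degenerate rows (constant signals) get all-zero coefficients.
    """
    r = _autocov_batch(x, order)
    b, _ = x.shape
    coefs = np.zeros((b, order))
    ok = r[:, 0] > np.finfo(float).tiny
    if ok.any():
        idx = np.abs(np.arange(order)[:, None] - np.arange(order)[None, :])
        R = r[ok][:, idx]  # (b_ok, order, order) Toeplitz matrices
        rhs = r[ok][:, 1 : order + 1]
        try:
            coefs[ok] = np.linalg.solve(R, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for i in np.flatnonzero(ok):
                Ri = r[i][idx]
                try:
                    coefs[i] = np.linalg.solve(Ri, r[i][1 : order + 1])
                except np.linalg.LinAlgError:
                    coefs[i] = 0.0
    if not ok.all():
        warnings.warn("degenerate (constant) channel: AR coefficients set to 0")
    return coefs


def _burg_single(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg's method for one signal; used when ar_method='burg'.

    Returns coefficients in the prediction convention
    ``x_i ~ sum_d a_d x_{i-d}`` (negated error-polynomial coefficients).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        return np.zeros(order)
    a = np.zeros(order + 1)
    a[0] = 1.0
    f = x.copy()
    b = x.copy()
    for m in range(1, order + 1):
        ff = f[m:]          # forward error at t = m..N-1
        bb = b[m - 1 : -1]  # backward error at t-1
        denom = ff @ ff + bb @ bb
        k = -2.0 * (ff @ bb) / denom if denom > 0 else 0.0
        a_new = a.copy()
        a_new[1 : m + 1] = a[1 : m + 1] + k * a[:m][::-1]
        a = a_new
        f_next = f.copy()
        b_next = b.copy()
        f_next[m:] = ff + k * bb
        b_next[m:] = bb + k * ff
        f, b = f_next, b_next
    return -a[1:]


def time_features(trial_channel: np.ndarray, order: int = AR_ORDER,
                  ar_method: str = "yule_walker"):
    """RMS amplitude and AR(6) coefficients of one trial channel.

    Coefficients follow the prediction convention
    ``x_i ~ sum_d a_d x_{i-d}``: for an AR process they estimate the
    generating coefficients directly.
    """
    x = np.asarray(trial_channel, dtype=float)
    if x.ndim != 1 or x.size <= order:
        raise ValueError(f"need more than {order} samples")
    if not np.isfinite(x).all():
        raise DataError("non-finite samples in trial")
    rms = float(np.sqrt(np.mean(x**2)))
    if ar_method == "yule_walker":
        coefs = _yule_walker_batch(x[None, :], order)[0]
    elif ar_method == "burg":
        coefs = _burg_single(x, order)
    else:
        raise ValueError(f"unknown ar_method {ar_method!r}")
    return (rms, *map(float, coefs))


# ---------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Trials x named features, with per-trial labels.

    Columns are channel-qualified, e.g. ``Fp1__mdf``; ``labels`` carries
    subject_id/state/group per trial (row-aligned with ``data``).
    """

    data: pd.DataFrame
    labels: pd.DataFrame = field(repr=False, default=None)
    feature_set: str = "set3"

    def __post_init__(self) -> None:
        if self.labels is None or len(self.labels) != len(self.data):
            raise ValueError("labels must be row-aligned with data")

    @property
    def n_trials(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def channels(self) -> list[str]:
        out: list[str] = []
        for name in self.data.columns:
            ch = name.split("__", 1)[0]
            if ch not in out:
                out.append(ch)
        return out

    def select_channels(self, labels: list[str]) -> "FeatureMatrix":
        """Subset the columns belonging to the given channels.

        Features are computed per channel independently, so this equals
        re-extracting features from the channel-restricted trials.
        """
        from .signal_io import LabelingError, normalize_label

        labels = [normalize_label(l) for l in labels]
        missing = [l for l in labels if l not in self.channels]
        if missing:
            raise LabelingError(f"channels not present in features: {missing}")
        feats = _FEATURES_BY_SET[self.feature_set]
        cols = [f"{ch}__{f}" for ch in labels for f in feats]
        return FeatureMatrix(data=self.data[cols].copy(),
                             labels=self.labels.reset_index(drop=True),
                             feature_set=self.feature_set)

    def subset_rows(self, mask) -> "FeatureMatrix":
        return FeatureMatrix(
            data=self.data.loc[mask].reset_index(drop=True),
            labels=self.labels.loc[mask].reset_index(drop=True),
            feature_set=self.feature_set,
        )


def _batch_features(flat: np.ndarray, fs: float, which: tuple[str, ...],
                    root_moments: bool, ar_method: str) -> dict[str, np.ndarray]:
    """Compute the requested features for every row of ``flat`` at once."""
    out: dict[str, np.ndarray] = {}
    if not np.isfinite(flat).all():
        raise DataError("non-finite samples in trials")
    need_spec = any(f in which for f in SET1_FEATURES)
    if need_spec:
        n = flat.shape[-1]
        X = np.fft.rfft(flat, axis=-1)
        pk = _fold_onesided(np.abs(X) ** 2, n) / n
        psd = pk / fs
        amp = np.abs(X) / n
        if n % 2 == 0:
            amp[..., 1:-1] *= 2.0
        else:
            amp[..., 1:] *= 2.0
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        tot_psd = psd.sum(axis=-1)
        tot_amp = amp.sum(axis=-1)
        if np.any(tot_psd <= 0):
            raise DataError("all-zero trial: median frequency undefined")
        cum_psd = np.cumsum(psd, axis=-1)
        cum_amp = np.cumsum(amp, axis=-1)
        idx_mdf = (cum_psd >= 0.5 * tot_psd[:, None]).argmax(axis=-1)
        idx_mfmd = (cum_amp >= 0.5 * tot_amp[:, None]).argmax(axis=-1)
        out["mdf"] = freqs[idx_mdf]
        out["mfmd"] = freqs[idx_mfmd]
        k = np.arange(pk.shape[-1], dtype=float)
        m0 = pk.sum(axis=-1)
        m2 = (pk * k**2).sum(axis=-1)
        m4 = (pk * k**4).sum(axis=-1)
        if root_moments:
            m0, m2, m4 = np.sqrt(m0), np.sqrt(m2), np.sqrt(m4)
        out["m0"], out["m2"], out["m4"] = m0, m2, m4
    if "rms" in which:
        out["rms"] = np.sqrt(np.mean(flat**2, axis=-1))
    if "ar1" in which:
        if ar_method == "yule_walker":
            coefs = _yule_walker_batch(flat, AR_ORDER)
        elif ar_method == "burg":
            coefs = np.stack([_burg_single(row, AR_ORDER) for row in flat])
        else:
            raise ValueError(f"unknown ar_method {ar_method!r}")
        for d in range(AR_ORDER):
            out[f"ar{d + 1}"] = coefs[:, d]
    return out


def build_feature_matrix(segs: SegmentSet, set_tag: str = "set3",
                         root_moments: bool = True,
                         ar_method: str = "yule_walker") -> FeatureMatrix:
    """Extract one feature set from every trial of a segment set.

    Columns are ordered channel-major: all features of the first channel,
    then the next. For ``set3`` each channel block is the set-1 features
    followed by the set-2 features, so set 3 is bit-identical to the
    column-wise concatenation of sets 1 and 2.
    """
    if set_tag not in _FEATURES_BY_SET:
        raise ValueError(f"set_tag must be one of {sorted(_FEATURES_BY_SET)}")
    if segs.n_trials == 0:
        raise ValueError("empty segment set")
    which = _FEATURES_BY_SET[set_tag]
    n_tr, n_ch, n_s = segs.trials.shape
    flat = segs.trials.reshape(n_tr * n_ch, n_s)
    feats = _batch_features(flat, segs.fs, which, root_moments, ar_method)
    columns: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(segs.channels):
        for f in which:
            columns[f"{ch}__{f}"] = feats[f].reshape(n_tr, n_ch)[:, ci]
    data = pd.DataFrame(columns)
    return FeatureMatrix(data=data, labels=segs.labels.reset_index(drop=True),
                         feature_set=set_tag)


class FeatureExtractor:
    """Transformer-style wrapper over :func:`build_feature_matrix`."""

    def __init__(self, feature_set: str = "set3", root_moments: bool = True,
                 ar_method: str = "yule_walker"):
        self.feature_set = feature_set
        self.root_moments = root_moments
        self.ar_method = ar_method

    def fit(self, X=None, y=None):
        return self

    def transform(self, segs: SegmentSet) -> FeatureMatrix:
        return build_feature_matrix(segs, self.feature_set,
                                    self.root_moments, self.ar_method)

    def get_params(self, deep: bool = True) -> dict:
        return {"feature_set": self.feature_set,
                "root_moments": self.root_moments,
                "ar_method": self.ar_method}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


def concat_feature_matrices(parts: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack row-blocks of feature matrices with identical columns."""
    if not parts:
        raise ValueError("nothing to concatenate")
    cols = parts[0].feature_names
    tag = parts[0].feature_set
    for p in parts[1:]:
        if p.feature_names != cols or p.feature_set != tag:
            raise ValueError("feature matrices have mismatched columns")
    return FeatureMatrix(
        data=pd.concat([p.data for p in parts], ignore_index=True),
        labels=pd.concat([p.labels for p in parts], ignore_index=True),
        feature_set=tag,
    )
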