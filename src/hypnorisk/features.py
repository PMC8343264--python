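"""Per-epoch spectral, entropy and wavelet features for sleep staging.

Twenty-one features are computed for each 30-s epoch of a single channel:

* mean dominant frequency and spectral median frequency (1-25 Hz),
* absolute and relative power in five bands: delta 1-3 Hz, theta 3-7 Hz,
  alpha 7-12 Hz, low beta 12-15 Hz, high beta 15-20 Hz,
* normalised spectral entropy in each band plus a broadband 1-25 Hz band,
* relative discrete-wavelet energies of three detail levels covering
  roughly 2-16 Hz (the wavelet triplet completes the 21-feature set; its
  exact composition is a reconstruction, see docs/methods.md).

Feature scaling across long recordings is handled by 5th/95th-quantile
normalisation with clipping, fitted per patient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .core import DegenerateSignalError, EPOCH_S, ParameterError

#: Scoring bands as (name, low_hz, high_hz); edges are half-open [low, high).
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 3.0),
    ("theta", 3.0, 7.0),
    ("alpha", 7.0, 12.0),
    ("low_beta", 12.0, 15.0),
    ("high_beta", 15.0, 20.0),
)

#: Broadband limits used for entropy, dominant and median frequencies.
BROADBAND: tuple[float, float] = (1.0, 25.0)

#: Wavelet detail bands (labels only; realised band edges depend on fs).
_WAVELET_BANDS: tuple[tuple[float, float], ...] = ((8.0, 16.0), (4.0, 8.0), (2.0, 4.0))

#: Canonical feature ordering; stable across the package.
FEATURE_NAMES: tuple[str, ...] = (
    ("mean_dominant_freq", "spectral_median_freq")
    + tuple(f"abs_power_{b}" for b, *_ in BANDS)
    + tuple(f"rel_power_{b}" for b, *_ in BANDS)
    + tuple(f"spectral_entropy_{b}" for b, *_ in BANDS)
    + ("spectral_entropy_broadband",)
    + tuple(f"wavelet_rel_energy_{int(lo)}_{int(hi)}" for lo, hi in _WAVELET_BANDS)
)

_WELCH_WINDOW_S = 4.0  # Welch segment length; 50% overlap, Hann taper


def _check_epoch(x: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < int(_WELCH_WINDOW_S * fs):
        raise ParameterError("epoch too short for spectral estimation")
    if not np.all(np.isfinite(x)):
        raise ParameterError("epoch contains non-finite samples")
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("constant (zero-variance) epoch")
    return x


def compute_psd(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of one epoch.

    Uses 4-s Hann windows with 50% overlap, so the frequency resolution is
    0.25 Hz and band edges at integer frequencies fall on bin edges.
    Returns ``(freqs, psd)`` with psd in signal-units^2 per Hz.
    """
    x = _check_epoch(epoch, fs)
    nper = int(_WELCH_WINDOW_S * fs)
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend="constant")
    return freqs, psd


def band_powers(
    freqs: np.ndarray, psd: np.ndarray, bands=BANDS
) -> tuple[dict[str, float], dict[str, float]]:
    """Absolute and relative band powers.

    Band membership is half-open ``[low, high)`` so shared edges are not
    double counted; relative power is the band integral divided by the
    total 1-25 Hz integral.
    """
    df = freqs[1] - freqs[0]
    lo, hi = BROADBAND
    total = psd[(freqs >= lo) & (freqs < hi)].sum() * df
    if total <= 0:
        raise DegenerateSignalError("no power in the 1-25 Hz band")
    absolute, relative = {}, {}
    for name, b_lo, b_hi in bands:
        p = psd[(freqs >= b_lo) & (freqs < b_hi)].sum() * df
        absolute[name] = float(p)
        relative[name] = float(p / total)
    return absolute, relative


def frequency_stats(epoch: np.ndarray, fs: float) -> tuple[float, float]:
    """Mean dominant frequency and spectral median frequency (1-25 Hz).

    The dominant frequency is the mean over Welch sub-windows of each
    window's peak frequency; the median frequency splits the 1-25 Hz Welch
    spectrum into two halves of equal power (linear interpolation within
    the crossing bin).
    """
    x = _check_epoch(epoch, fs)
    nper = int(_WELCH_WINDOW_S * fs)
    freqs, _, spec = sps.spectrogram(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant", mode="psd",
    )
    lo, hi = BROADBAND
    sel = (freqs >= lo) & (freqs < hi)
    band_f = freqs[sel]
    sub = spec[sel]
    if not np.all(sub.sum(axis=0) > 0):
        raise DegenerateSignalError("no power in the 1-25 Hz band")
    dominant = float(band_f[np.argmax(sub, axis=0)].mean())

    f_w, psd = compute_psd(x, fs)
    sel_w = (f_w >= lo) & (f_w < hi)
    p = psd[sel_w]
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError("no power in the 1-25 Hz band")
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, total / 2.0))
    k = min(k, p.size - 1)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (total / 2.0 - prev) / p[k] if p[k] > 0 else 0.5
    df = f_w[1] - f_w[0]
    # bin-centred linear interpolation: a pure tone lands on its own bin
    median = float(f_w[sel_w][k] + (frac - 0.5) * df)
    return dominant, median


def spectral_entropy(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> float:
    """Shannon entropy of the within-band normalised PSD, scaled to [0, 1].

    A single spectral line gives 0; a flat spectrum gives 1.
    """
    lo, hi = band
    sel = (freqs >= lo) & (freqs < hi)
    if sel.sum() < 2:
        raise ParameterError("entropy band needs at least two frequency bins")
    p = psd[sel]
    total = p.sum()
    if total <= 0:
        raise DegenerateSignalError(f"no power in the {lo}-{hi} Hz band")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(sel.sum()))


def wavelet_energies(epoch: np.ndarray, fs: float) -> dict[str, float]:
    """Relative energies of three wavelet detail levels covering ~2-16 Hz.

    Daubechies-4 multilevel decomposition; detail level ``j`` spans
    approximately ``fs / 2**(j+1)`` to ``fs / 2**j`` Hz, so the levels whose
    nominal bands are 8-16, 4-8 and 2-4 Hz are selected from the sampling
    rate. Energies are relative to the total energy of all coefficients
    (equal to the signal energy for an orthogonal wavelet).
    """
    x = _check_epoch(epoch, fs)
    x = x - x.mean()
    j_top = int(round(np.log2(fs / 16.0)))
    if j_top < 1:
        raise ParameterError("sampling rate too low for the 8-16 Hz detail level")
    max_level = j_top + 2
    coeffs = pywt.wavedec(x, "db4", level=max_level)
    total = sum(float(np.square(c).sum()) for c in coeffs)
    if total <= 0:
        raise DegenerateSignalError("zero wavelet energy")
    # coeffs = [approx, detail_max_level, ..., detail_1]
    out = {}
    for (lo, hi), j in zip(_WAVELET_BANDS, (j_top, j_top + 1, j_top + 2)):
        det = coeffs[len(coeffs) - j]
        out[f"wavelet_rel_energy_{int(lo)}_{int(hi)}"] = float(
            np.square(det).sum() / total
        )
    return out


def extract_epoch_features(epoch: np.ndarray, fs: float) -> dict[str, float]:
    """All 21 features for one epoch, keyed by :data:`FEATURE_NAMES`."""
    freqs, psd = compute_psd(epoch, fs)
    dominant, median = frequency_stats(epoch, fs)
    absolute, relative = band_powers(freqs, psd)
    feats = {"mean_dominant_freq": dominant, "spectral_median_freq": median}
    for name, *_ in BANDS:
        feats[f"abs_power_{name}"] = absolute[name]
    for name, *_ in BANDS:
        feats[f"rel_power_{name}"] = relative[name]
    for name, lo, hi in BANDS:
        feats[f"spectral_entropy_{name}"] = spectral_entropy(freqs, psd, (lo, hi))
    feats["spectral_entropy_broadband"] = spectral_entropy(freqs, psd, BROADBAND)
    feats.update(wavelet_energies(epoch, fs))
    return feats


def extract_features(
    signal: np.ndarray, fs: float, artifact_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Feature matrix for a stack of epochs.

    Parameters
    ----------
    signal : array
        Either ``(n_epochs, n_samples)`` pre-segmented epochs (NaN rows are
        treated as missing) or a 1-D series that is reshaped into
        contiguous 30-s epochs.
    fs : float
        Sampling rate in Hz.
    artifact_mask : bool array, optional
        Epochs flagged artefactual; their rows are returned as NaN.

    Returns
    -------
    DataFrame with the 21 canonical feature columns; missing, artefactual
    or degenerate epochs give all-NaN rows.
    """
    signal = np.asarray(signal)
    if signal.ndim == 1:
        n = int(round(EPOCH_S * fs))
        n_ep = signal.size // n
        signal = signal[: n_ep * n].reshape(n_ep, n)
    n_epochs = signal.shape[0]
    if artifact_mask is not None and len(artifact_mask) != n_epochs:
        raise ParameterError("artifact mask misaligned with epochs")
    rows = np.full((n_epochs, len(FEATURE_NAMES)), np.nan)

    ok = np.all(np.isfinite(signal), axis=1) & (np.ptp(signal, axis=1) > 0)
    if artifact_mask is not None:
        ok &= ~np.asarray(artifact_mask, dtype=bool)
    if ok.any():
        rows[ok] = _extract_batch(np.asarray(signal[ok], dtype=float), fs)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


def _extract_batch(X: np.ndarray, fs: float) -> np.ndarray:
    """Vectorised feature computation for a stack of valid epochs.

    Mirrors the per-epoch functions exactly (same Welch settings, band
    conventions and interpolation rules); epochs that turn out degenerate
    (no 1-25 Hz power) come back as NaN rows.
    """
    n_ep = X.shape[0]
    out = np.full((n_ep, len(FEATURE_NAMES)), np.nan)
    col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    nper = int(_WELCH_WINDOW_S * fs)

    freqs, psd = sps.welch(X, fs=fs, window="hann", nperseg=nper,
                           noverlap=nper // 2, detrend="constant", axis=-1)
    lo, hi = BROADBAND
    bb = (freqs >= lo) & (freqs < hi)
    df = freqs[1] - freqs[0]
    total = psd[:, bb].sum(axis=1) * df
    good = total > 0

    # band powers
    for name, b_lo, b_hi in BANDS:
        sel = (freqs >= b_lo) & (freqs < b_hi)
        p = psd[:, sel].sum(axis=1) * df
        out[:, col[f"abs_power_{name}"]] = p
        out[good, col[f"rel_power_{name}"]] = p[good] / total[good]

    # spectral entropies
    for name, b_lo, b_hi in list(BANDS) + [("broadband", lo, hi)]:
        sel = (freqs >= b_lo) & (freqs < b_hi)
        p = psd[:, sel]
        tot = p.sum(axis=1, keepdims=True)
        okb = tot[:, 0] > 0
        q = np.where(tot > 0, p / np.where(tot > 0, tot, 1.0), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1) / np.log(
                sel.sum()
            )
        out[okb, col[f"spectral_entropy_{name}"]] = ent[okb]

    # median frequency: bin-centred interpolation of the cumulative power
    pb = psd[:, bb]
    cum = np.cumsum(pb, axis=1)
    half = total / 2.0 / df
    k = np.minimum(
        np.array([np.searchsorted(cum[i], half[i]) for i in range(n_ep)]),
        pb.shape[1] - 1,
    )
    idx = np.arange(n_ep)
    prev = np.where(k > 0, cum[idx, np.maximum(k - 1, 0)], 0.0)
    pk = pb[idx, k]
    frac = np.where(pk > 0, (half - prev) / np.where(pk > 0, pk, 1.0), 0.5)
    out[good, col["spectral_median_freq"]] = (
        freqs[bb][k] + (frac - 0.5) * df
    )[good]

    # dominant frequency: mean of per-window peak frequencies
    f_s, _, spec = sps.spectrogram(
        X, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2,
        detrend="constant", mode="psd", axis=-1,
    )
    sel = (f_s >= lo) & (f_s < hi)
    band_f = f_s[sel]
    sub = spec[:, sel, :]
    out[good, col["mean_dominant_freq"]] = band_f[
        np.argmax(sub, axis=1)
    ].mean(axis=1)[good]

    # wavelet relative energies
    Xc = X - X.mean(axis=1, keepdims=True)
    j_top = int(round(np.log2(fs / 16.0)))
    coeffs = pywt.wavedec(Xc, "db4", level=j_top + 2, axis=-1)
    wtot = sum(np.square(c).sum(axis=1) for c in coeffs)
    wok = wtot > 0
    for (b_lo, b_hi), j in zip(_WAVELET_BANDS, (j_top, j_top + 1, j_top + 2)):
        det = coeffs[len(coeffs) - j]
        e = np.square(det).sum(axis=1)
        out[wok & good, col[f"wavelet_rel_energy_{int(b_lo)}_{int(b_hi)}"]] = (
            e / np.where(wok, wtot, 1.0)
        )[wok & good]

    out[~good] = np.nan
    return out


@dataclass
class NormalizationParams:
    """Per-feature 5th/95th quantiles used for scaling, plus unusable flags."""

    q05: dict[str, float]
    q95: dict[str, float]
    unusable: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"q05": self.q05, "q95": self.q95, "unusable": self.unusable}, fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(q05=d["q05"], q95=d["q95"], unusable=list(d["unusable"]))


CLIP_RANGE: tuple[float, float] = (-0.5, 1.5)


def quantile_normalize(
    matrix: pd.DataFrame, params: NormalizationParams | None = None
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Scale each feature by its 5th/95th quantiles: ``(x - q05)/(q95 - q05)``.

    Values are clipped to ``[-0.5, 1.5]`` to bound the influence of energy
    outliers. When ``params`` is None the quantiles are fitted on the
    non-missing rows (at least 20 required); constant features (q05 == q95)
    are flagged unusable and returned as NaN rather than divided by zero.
    """
    if params is None:
        valid = matrix.dropna()
        if len(valid) < 20:
            raise ParameterError("need at least 20 non-missing epochs to fit")
        q05 = valid.quantile(0.05)
        q95 = valid.quantile(0.95)
        unusable = [c for c in matrix.columns if q95[c] - q05[c] <= 0]
        params = NormalizationParams(
            q05=q05.to_dict(), q95=q95.to_dict(), unusable=unusable
        )
    out = matrix.copy()
    for col in matrix.columns:
        if col in params.unusable:
            out[col] = np.nan
            continue
        lo, hi = params.q05[col], params.q95[col]
        out[col] = ((matrix[col] - lo) / (hi - lo)).clip(*CLIP_RANGE)
    return out, params


def denormalize(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Inverse of :func:`quantile_normalize` on the unclipped range."""
    out = matrix.copy()
    for col in matrix.columns:
        if col in params.unusable:
            continue
        lo, hi = params.q05[col], params.q95[col]
        out[col] = matrix[col] * (hi - lo) + lo
    return out
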