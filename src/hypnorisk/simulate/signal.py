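"""Synthetic one-channel signal segments with state-specific spectra.

Segments are coloured Gaussian noise generated in the frequency domain:
the target power spectral density is piecewise-constant over the five
scoring bands (1-3, 3-7, 7-12, 12-15, 15-20 Hz) with relative band powers
taken from the state's profile, plus a flat broadband noise floor. This
gives exact control over expected relative band powers at any sampling
rate without claiming biophysical realism.
"""

from __future__ import annotations

import numpy as np

from ..core import DegenerateSignalError, EPOCH_S, Hypnogram
from ..features import BANDS
from .params import SignalModel


def _target_psd(profile, noise_floor: float, freqs: np.ndarray,
                total_power: float) -> np.ndarray:
    """Piecewise-constant PSD with unit total power times ``total_power``."""
    psd = np.zeros_like(freqs)
    rel = np.asarray(profile, dtype=float)
    rel = rel / rel.sum() if rel.sum() > 0 else rel
    for (name, lo, hi), p in zip(BANDS, rel):
        sel = (freqs >= lo) & (freqs < hi)
        if sel.any():
            psd[sel] += p / (hi - lo)
    broad = (freqs >= 0.5) & (freqs < freqs[-1])
    psd[broad] += noise_floor / (freqs[-1] - 0.5)
    return psd * total_power / (1.0 + noise_floor)


def generate_signal(
    hypnogram: Hypnogram, model: SignalModel, seed: int
) -> np.ndarray:
    """Per-epoch signal segments for every non-UNKNOWN epoch.

    Returns an ``(n_epochs, 30 * fs)`` float32 array; UNKNOWN epochs are
    rows of NaN. For long recordings, call this on day slices to bound
    memory (one day at 128 Hz is about 42 MB).
    """
    model.validate()
    if model.amplitude_scale <= 0:
        raise DegenerateSignalError("amplitude_scale must be positive")
    fs = model.sampling_rate
    n = int(round(EPOCH_S * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    rng = np.random.default_rng(seed)
    out = np.full((len(hypnogram), n), np.nan, dtype=np.float32)
    total_power = model.amplitude_scale**2

    labels = hypnogram.labels
    # deterministic order: iterate states in profile order, epochs in order
    for state, profile in model.band_profiles.items():
        idx = np.flatnonzero(labels == state)
        if idx.size == 0:
            continue
        psd = _target_psd(profile, model.noise_floor, freqs, total_power)
        # E|Z_k|^2 = S_k * fs * n / 2 makes the periodogram match S_k
        amp = np.sqrt(psd * fs * n / 4.0)
        amp[0] = 0.0  # no DC
        if n % 2 == 0:
            amp[-1] = 0.0
        z = rng.standard_normal((idx.size, amp.size)) + 1j * rng.standard_normal(
            (idx.size, amp.size)
        )
        out[idx] = np.fft.irfft(z * amp, n=n, axis=1).astype(np.float32)
    return out
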