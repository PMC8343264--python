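import numpy as np
import pandas as pd
import pytest

from hypnorisk.core import DegenerateSignalError, ParameterError
from hypnorisk.features import (
    BANDS,
    BROADBAND,
    FEATURE_NAMES,
    band_powers,
    compute_psd,
    denormalize,
    extract_epoch_features,
    extract_features,
    frequency_stats,
    quantile_normalize,
    spectral_entropy,
    wavelet_energies,
)

FS = 128.0


def sine(freq, seconds=30.0, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def white(seconds=30.0, fs=FS, seed=0):
    return np.random.default_rng(seed).standard_normal(int(seconds * fs))


# -- PSD --------------------------------------------------------------------

def test_psd_parseval_on_white_noise():
    x = white(seconds=30, seed=1)
    freqs, psd = compute_psd(x, FS)
    total = psd.sum() * (freqs[1] - freqs[0])
    assert abs(total - np.var(x)) / np.var(x) < 0.01


def test_psd_peak_at_tone_frequency():
    freqs, psd = compute_psd(sine(10.0), FS)
    assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=0.25)


def test_psd_rejects_degenerate_and_bad_input():
    with pytest.raises(DegenerateSignalError):
        compute_psd(np.zeros(int(30 * FS)), FS)
    with pytest.raises(ParameterError):
        compute_psd(np.full(int(30 * FS), np.nan), FS)
    with pytest.raises(ParameterError):
        compute_psd(np.ones(10), FS)


# -- band powers ------------------------------------------------------------

def test_pure_tone_concentrates_in_its_band():
    freqs, psd = compute_psd(sine(10.0), FS)
    _, rel = band_powers(freqs, psd)
    assert rel["alpha"] > 0.98
    assert sum(v for k, v in rel.items() if k != "alpha") < 0.02


def test_equal_tones_split_power_between_bands():
    x = sine(5.0) + sine(10.0)
    freqs, psd = compute_psd(x, FS)
    _, rel = band_powers(freqs, psd)
    assert rel["theta"] == pytest.approx(0.5, abs=0.02)
    assert rel["alpha"] == pytest.approx(0.5, abs=0.02)


def test_flat_spectrum_relative_powers_equal_bandwidth_ratios():
    x = white(seconds=240, seed=2)  # long epoch to tame estimator noise
    freqs, psd = compute_psd(x, FS)
    _, rel = band_powers(freqs, psd)
    span = BROADBAND[1] - BROADBAND[0]
    for name, lo, hi in BANDS:
        assert rel[name] == pytest.approx((hi - lo) / span, abs=0.02)


# -- frequency statistics ---------------------------------------------------

def test_tone_dominant_and_median_frequency():
    dom, med = frequency_stats(sine(5.0), FS)
    assert dom == pytest.approx(5.0, abs=0.25)
    assert med == pytest.approx(5.0, abs=0.25)


def test_two_tone_median_matches_cumulative_power_oracle():
    x = sine(5.0) + sine(15.0)
    _, med = frequency_stats(x, FS)
    assert 5.0 < med < 15.0
    # independent oracle: cumulative power over the broadband PSD
    freqs, psd = compute_psd(x, FS)
    sel = (freqs >= BROADBAND[0]) & (freqs < BROADBAND[1])
    p, f = psd[sel], freqs[sel]
    cum = np.cumsum(p)
    k = np.searchsorted(cum, cum[-1] / 2)
    prev = cum[k - 1] if k else 0.0
    expected = f[k] + ((cum[-1] / 2 - prev) / p[k] - 0.5) * (f[1] - f[0])
    assert med == pytest.approx(expected, abs=1e-9)


def test_flat_spectrum_median_near_band_midpoint():
    _, med = frequency_stats(white(seconds=240, seed=3), FS)
    assert med == pytest.approx(13.0, abs=0.3)


# -- spectral entropy -------------------------------------------------------

def test_entropy_limits_tone_and_noise():
    # a bin-centred tone under a Hann taper occupies exactly three bins
    # with weights (1/6, 2/3, 1/6); that is the tone's entropy floor
    freqs, psd = compute_psd(sine(10.0), FS)
    n_bins = int(np.sum((freqs >= 7.0) & (freqs < 12.0)))
    h_hann = -(2 / 3 * np.log(2 / 3) + 2 * (1 / 6) * np.log(1 / 6))
    val = spectral_entropy(freqs, psd, (7.0, 12.0))
    assert val == pytest.approx(h_hann / np.log(n_bins), abs=1e-6)
    # exact single-line spectrum: entropy is exactly zero
    line = np.zeros_like(freqs)
    line[np.flatnonzero(freqs == 10.0)[0]] = 1.0
    assert spectral_entropy(freqs, line, (7.0, 12.0)) == 0.0
    freqs, psd = compute_psd(white(seconds=240, seed=4), FS)
    assert spectral_entropy(freqs, psd, BROADBAND) > 0.97


def test_entropy_two_equal_bins_closed_form():
    freqs = np.arange(0, 26, 0.25)
    psd = np.zeros_like(freqs)
    band = (1.0, 25.0)
    n_bins = int(np.sum((freqs >= 1) & (freqs < 25)))
    psd[8] = psd[40] = 1.0  # 2.0 Hz and 10.0 Hz bins
    val = spectral_entropy(freqs, psd, band)
    assert val == pytest.approx(np.log(2) / np.log(n_bins), abs=1e-12)


def test_entropy_errors():
    freqs = np.arange(0, 26, 0.25)
    with pytest.raises(DegenerateSignalError):
        spectral_entropy(freqs, np.zeros_like(freqs), (1.0, 25.0))
    with pytest.raises(ParameterError):
        spectral_entropy(freqs, np.ones_like(freqs), (1.0, 1.1))


# -- wavelet energies -------------------------------------------------------

def test_low_frequency_sine_loads_deepest_level():
    e = wavelet_energies(sine(2.0), FS)
    assert e["wavelet_rel_energy_2_4"] == max(e.values())


def test_white_noise_wavelet_energies_near_bandwidth_ratios():
    x = white(seconds=240, seed=5)
    e = wavelet_energies(x, FS)
    nyquist = FS / 2
    assert e["wavelet_rel_energy_8_16"] == pytest.approx(8 / nyquist, abs=0.02)
    assert e["wavelet_rel_energy_4_8"] == pytest.approx(4 / nyquist, abs=0.02)
    assert e["wavelet_rel_energy_2_4"] == pytest.approx(2 / nyquist, abs=0.02)


def test_wavelet_zero_epoch_rejected():
    with pytest.raises(DegenerateSignalError):
        wavelet_energies(np.zeros(int(30 * FS)), FS)


# -- full extraction --------------------------------------------------------

def test_feature_count_and_stable_names():
    assert len(FEATURE_NAMES) == 21
    mat = extract_features(np.vstack([white(seed=i) for i in range(3)]), FS)
    assert list(mat.columns) == list(FEATURE_NAMES)
    assert mat.notna().all().all()


def test_artifact_and_degenerate_rows_are_missing():
    epochs = np.vstack([white(seed=1), np.zeros(int(30 * FS)), white(seed=2)])
    mat = extract_features(epochs, FS, artifact_mask=[False, False, True])
    assert mat.iloc[0].notna().all()
    assert mat.iloc[1].isna().all()  # degenerate
    assert mat.iloc[2].isna().all()  # artifact


def test_batch_extraction_matches_per_epoch_path():
    epochs = np.vstack([white(seed=i) + sine(6.0, amp=0.5) for i in range(4)])
    mat = extract_features(epochs, FS)
    for i in range(4):
        ref = extract_epoch_features(epochs[i], FS)
        for name in FEATURE_NAMES:
            assert mat.iloc[i][name] == pytest.approx(ref[name], rel=1e-9)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-3, max_value=1e3))
def test_scale_equivariance_property(c):
    """For any positive gain, shape features are invariant and absolute
    powers scale quadratically."""
    x = white(seed=42) + sine(9.0, amp=0.7)
    f1 = extract_epoch_features(x, FS)
    f2 = extract_epoch_features(c * x, FS)
    assert f2["rel_power_alpha"] == pytest.approx(f1["rel_power_alpha"], rel=1e-6)
    assert f2["spectral_median_freq"] == pytest.approx(
        f1["spectral_median_freq"], abs=1e-9
    )
    assert f2["abs_power_delta"] == pytest.approx(
        c**2 * f1["abs_power_delta"], rel=1e-6
    )


@pytest.mark.parametrize("c", [0.1, 3.7])
def test_scale_equivariance(c):
    """Scaling the signal leaves shape features unchanged; absolute powers
    scale by c^2."""
    x = white(seed=6) + sine(9.0, amp=0.7)
    f1 = extract_epoch_features(x, FS)
    f2 = extract_epoch_features(c * x, FS)
    for name in FEATURE_NAMES:
        if name.startswith("abs_power"):
            assert f2[name] == pytest.approx(c**2 * f1[name], rel=1e-8)
        else:
            assert f2[name] == pytest.approx(f1[name], rel=1e-6, abs=1e-9)


# -- quantile normalisation -------------------------------------------------

def _noise_matrix(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )


def test_quantile_endpoints_map_to_unit_interval():
    mat = _noise_matrix()
    normed, params = quantile_normalize(mat)
    col = FEATURE_NAMES[0]
    lo, hi = params.q05[col], params.q95[col]
    out, _ = quantile_normalize(
        pd.DataFrame({c: [lo if c == col else 0.0] for c in mat.columns}), params
    )
    assert out[col].iloc[0] == pytest.approx(0.0, abs=1e-12)
    out, _ = quantile_normalize(
        pd.DataFrame({c: [hi if c == col else 0.0] for c in mat.columns}), params
    )
    assert out[col].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_constant_feature_flagged_not_divided():
    mat = _noise_matrix()
    mat[FEATURE_NAMES[3]] = 1.0
    normed, params = quantile_normalize(mat)
    assert FEATURE_NAMES[3] in params.unusable
    assert normed[FEATURE_NAMES[3]].isna().all()


def test_standard_normal_quantiles_recovered():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame({c: rng.standard_normal(40_000) for c in FEATURE_NAMES[:2]})
    _, params = quantile_normalize(mat)
    assert params.q05[FEATURE_NAMES[0]] == pytest.approx(-1.645, abs=0.03)
    assert params.q95[FEATURE_NAMES[0]] == pytest.approx(1.645, abs=0.03)


def test_normalize_round_trip_unclipped():
    mat = _noise_matrix(seed=2)
    normed, params = quantile_normalize(mat)
    # restrict to rows that were not clipped
    back = denormalize(normed, params)
    unclipped = ((normed > -0.5) & (normed < 1.5)).all(axis=1)
    pd.testing.assert_frame_equal(
        back[unclipped], mat[unclipped], check_exact=False, atol=1e-10
    )


def test_fit_requires_enough_epochs():
    with pytest.raises(ParameterError):
        quantile_normalize(_noise_matrix(n=10))


def test_normalization_params_json_round_trip(tmp_path):
    _, params = quantile_normalize(_noise_matrix())
    path = tmp_path / "norm.json"
    params.to_json(path)
    from hypnorisk.features import NormalizationParams

    back = NormalizationParams.from_json(path)
    assert back.q05 == pytest.approx(params.q05)
    assert back.unusable == params.unusable
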