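"""Numerical-primitive tests: each operator against an independent oracle,
closed form, or analytic identity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apnea_mer import dsp


# ---------------------------------------------------------------------------
# LZ76
# ---------------------------------------------------------------------------

def lz76_oracle(bits: str) -> int:
    """Exhaustive reference parser: greedy left-to-right phrases, a phrase is
    novel when it is absent from the explicit substring set of the prefix."""
    n = len(bits)
    if n == 0:
        return 0
    c, i = 0, 0
    while i < n:
        l = 1
        while i + l <= n:
            prefix = bits[: i + l - 1]
            subs = {prefix[a:b] for a in range(len(prefix))
                    for b in range(a + 1, len(prefix) + 1)}
            if bits[i:i + l] not in subs:
                break
            l += 1
        if i + l <= n:
            c += 1
        i += l
    return max(c, 1)


def test_lz76_constant_is_single_phrase():
    for n in (2, 5, 20):
        assert dsp.lz76_phrase_count("1" * n) == 1
        assert lz76_oracle("1" * n) == 1


def test_lz76_alternating_matches_oracle():
    s = "01" * 10
    assert dsp.lz76_phrase_count(s) == lz76_oracle(s)


def test_lz_complexity_random_exceeds_periodic():
    rng = np.random.default_rng(0)
    rand = rng.choice([-1.0, 1.0], 512)
    periodic = np.tile([-1.0, 1.0], 256)
    assert dsp.lz_complexity(rand) > dsp.lz_complexity(periodic)


def test_lz_complexity_constant_series_is_minimal():
    n = 64
    assert dsp.lz_complexity(np.full(n, 7.0)) == pytest.approx(np.log2(n) / n)


@given(st.lists(st.integers(0, 1), min_size=1, max_size=24))
def test_lz76_matches_oracle_on_random_bits(bits):
    s = "".join(map(str, bits))
    assert dsp.lz76_phrase_count(s) == lz76_oracle(s)


# ---------------------------------------------------------------------------
# PSD estimators
# ---------------------------------------------------------------------------

def _ar1(n, phi, seed):
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    e = rng.standard_normal(n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def test_yule_walker_recovers_ar1_spectrum():
    x = _ar1(4096, 0.9, seed=1)
    psd = dsp.yule_walker_psd(x, order=5, fs=1.0, nfft=256)
    w = 2 * np.pi * psd.freqs_hz
    truth = 1.0 / np.abs(1 - 0.9 * np.exp(-1j * w)) ** 2
    truth[1:-1] *= 2  # one-sided
    rel = np.linalg.norm(psd.power - truth) / np.linalg.norm(truth)
    assert rel < 0.1


def test_yule_walker_white_noise_is_flat():
    x = np.random.default_rng(2).standard_normal(4096)
    psd = dsp.yule_walker_psd(x, order=5, fs=1.0)
    assert psd.power.max() / psd.power.min() < 10


def test_yule_walker_integrated_power_matches_variance():
    x = _ar1(4096, 0.7, seed=3)
    psd = dsp.yule_walker_psd(x, order=5, fs=1.0)
    total = np.trapezoid(psd.power, psd.freqs_hz)
    assert total == pytest.approx(np.var(x), rel=0.1)


def test_yule_walker_constant_input_degenerates_quietly():
    psd = dsp.yule_walker_psd(np.full(100, 3.0), order=5, fs=1.0)
    assert np.all(psd.power < 1e-12)


def test_yule_walker_segment_averaging_runs():
    x = _ar1(400, 0.8, seed=4)
    seg = dsp.yule_walker_psd(x, order=5, fs=10.0, segment_len=40)
    assert seg.freqs_hz[-1] == pytest.approx(5.0)
    assert np.all(seg.power >= 0)


def test_welch_sine_peak_and_shape():
    t = np.arange(600)
    psd = dsp.welch_psd(np.sin(2 * np.pi * 0.25 * t), 5, 2, fs=1.0, nfft=256)
    assert psd.power.size == 129
    peak = psd.freqs_hz[np.argmax(psd.power)]
    assert abs(peak - 0.25) <= 1.0 / 256


def test_welch_constant_power_concentrates_at_dc():
    psd = dsp.welch_psd(np.full(100, 2.0), 5, 2, fs=1.0, nfft=256)
    # Hann mainlobe + one-sided doubling can favour the first nonzero bin;
    # the peak must still lie within one grid bin of 0 Hz
    assert psd.freqs_hz[np.argmax(psd.power)] <= 1.0 / 256


def test_band_stat_examples():
    freqs = np.linspace(0, 0.5, 129)
    flat = dsp.PsdEstimate(freqs, np.full(129, 3.0), "welch")
    assert dsp.band_stat(flat, 0.1, 0.3, "mean") == pytest.approx(3.0)
    assert dsp.band_stat(flat, 0.0, 0.5, "sum") >= dsp.band_stat(flat, 0.1, 0.3, "sum")
    spike = np.zeros(129)
    spike[np.argmin(np.abs(freqs - 0.3))] = 5.0
    psd = dsp.PsdEstimate(freqs, spike, "welch")
    assert dsp.band_stat(psd, 0.03, 0.5, "argmax_freq") == pytest.approx(0.3, abs=0.01)


def test_band_stat_normalized_convention_above_nyquist():
    # a band printed as 80-100 on a 10 Hz channel (Nyquist 5 Hz) must be
    # read as the uppermost fifth of the spectrum, 4-5 Hz
    freqs = np.linspace(0, 5.0, 129)
    power = np.where(freqs >= 4.0, 7.0, 1.0)
    psd = dsp.PsdEstimate(freqs, power, "yule_walker")
    assert dsp.band_stat(psd, 80.0, 100.0, "mean") == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# wavelets + entropy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("wavelet,level,n", [("db3", 3, 600), ("db2", 2, 600),
                                             ("sym3", 7, 1024)])
def test_wavelet_parseval(wavelet, level, n):
    x = np.random.default_rng(7).standard_normal(n)
    stats, dec = dsp.wavelet_stats(x, wavelet, level)
    energy_in = float(np.sum(x ** 2))
    assert abs(dec.energy() - energy_in) / energy_in < 1e-8
    assert len(dec.details) == level


def test_wavelet_constant_details_vanish():
    stats, _ = dsp.wavelet_stats(np.full(256, 4.0), "db3", 3)
    for i in (1, 2, 3):
        assert abs(stats[f"D{i}"]["mean"]) < 1e-8
        assert stats[f"D{i}"]["energy"] < 1e-8


def test_shannon_entropy_analytic_cases():
    assert dsp.shannon_entropy_coeffs(np.array([0.0, 3.0, 0.0])) == 0.0
    n = 16
    assert dsp.shannon_entropy_coeffs(np.full(n, 2.0)) == pytest.approx(np.log2(n))
    c = np.random.default_rng(8).standard_normal(32)
    assert 0.0 <= dsp.shannon_entropy_coeffs(c) <= np.log2(32)


# ---------------------------------------------------------------------------
# Poincare, serial correlation, zero crossings
# ---------------------------------------------------------------------------

def test_sd1_constant_and_alternating():
    assert dsp.poincare_sd1(np.full(50, 9.0)) == 0.0
    x = np.tile([95.0, 97.0], 25)
    d = np.diff(x)
    assert dsp.poincare_sd1(x) == pytest.approx(np.sqrt(np.var(d) / 2.0))


@given(st.lists(st.floats(-100, 100), min_size=2, max_size=60))
def test_sd1_matches_bruteforce_variance_oracle(vals):
    x = np.asarray(vals)
    d = np.diff(x)
    oracle = np.sqrt(0.5 * np.mean((d - d.mean()) ** 2))
    assert dsp.poincare_sd1(x) == pytest.approx(oracle, abs=1e-9)


def test_serial_corr_contracts():
    assert dsp.serial_corr(np.arange(10.0), 0) == 1.0
    assert dsp.serial_corr(np.full(20, 5.0), 3) == 0.0


@given(st.lists(st.floats(-50, 50), min_size=8, max_size=60), st.integers(1, 4))
def test_serial_corr_matches_bruteforce_pearson(vals, lag):
    x = np.asarray(vals)
    a, b = x[:-lag], x[lag:]
    if a.size < 2 or np.std(a) < 1e-12 or np.std(b) < 1e-12:
        assert dsp.serial_corr(x, lag) == 0.0
    else:
        num = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = num / (np.std(a) * np.std(b))
        assert dsp.serial_corr(x, lag) == pytest.approx(np.clip(oracle, -1, 1), abs=1e-9)


def brute_zero_crossings(x):
    y = x - np.mean(x)
    count, prev = 0, 0.0
    for v in y:
        s = np.sign(v)
        if s == 0:
            continue
        if prev != 0 and s != prev:
            count += 1
        prev = s
    return count


def test_zero_crossings_examples():
    assert dsp.zero_crossings(np.full(30, 1.0)) == 0
    # three runs around the mean -> exactly 2 strict sign changes
    x = np.concatenate([np.ones(10), -np.ones(10), np.ones(10)])
    assert dsp.zero_crossings(x) == 2


@given(st.lists(st.floats(-10, 10), min_size=2, max_size=80))
def test_zero_crossings_matches_brute_scan(vals):
    x = np.asarray(vals)
    assert dsp.zero_crossings(x) == brute_zero_crossings(x)


# ---------------------------------------------------------------------------
# spectral shape + kPCA
# ---------------------------------------------------------------------------

def test_spectral_spread_examples():
    freqs = np.linspace(0, 10, 21)
    single = np.zeros(21)
    single[7] = 4.0
    assert dsp.spectral_spread(dsp.PsdEstimate(freqs, single, "welch")) == 0.0
    two = np.zeros(21)
    two[4], two[12] = 1.0, 1.0  # bins at 2 Hz and 6 Hz
    assert dsp.spectral_spread(dsp.PsdEstimate(freqs, two, "welch")) == pytest.approx(2.0)


def test_spectral_decrease_flat_is_zero():
    freqs = np.linspace(0, 10, 33)
    flat = dsp.PsdEstimate(freqs, np.full(33, 2.0), "welch")
    assert dsp.spectral_decrease(flat) == pytest.approx(0.0, abs=1e-12)


def test_kpca_identical_rows_degenerate():
    q = np.tile(np.arange(15.0), (6, 1))
    assert dsp.kpca_qrs(q) == (0.0, 0.0)


def test_kpca_spectrum_properties():
    rng = np.random.default_rng(9)
    q = rng.standard_normal((30, 15))
    max_dia, rp2 = dsp.kpca_qrs(q)
    assert max_dia > 0
    assert 0.0 <= rp2 <= 1.0


def test_kpca_requires_three_rows():
    with pytest.raises(ValueError):
        dsp.kpca_qrs(np.zeros((2, 15)))
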