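"""Filtering, R-peak detection, segmentation and segment elimination."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from heartprint.preprocess import (
    CYCLE_LEN,
    CardiacCycle,
    FilterSpec,
    bandpass_filter,
    detect_r_peaks,
    minmax_normalize,
    normalize_cycles,
    segment_cycles,
    select_most_similar,
)
from heartprint.synthetic import ConfigurationError

FS = 1000.0


def _tone_gain(freq, fs=FS, dur=20.0):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = bandpass_filter(x, fs)
    core = slice(int(5 * fs), int(15 * fs))  # steady-state region
    tc = t[core]
    # lock-in amplitude estimate at the probe frequency
    s = 2 * np.mean(y[core] * np.sin(2 * np.pi * freq * tc))
    c = 2 * np.mean(y[core] * np.cos(2 * np.pi * freq * tc))
    return float(np.hypot(s, c))


def _oracle_gain(freq, fs=FS):
    # frequency-response oracle: designed filter's |H|, squared for the
    # forward-backward application
    sos = FilterSpec().sos(fs)
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


def test_constant_signal_is_removed():
    out = bandpass_filter(np.full(5000, 7.3), FS)
    core = out[1000:-1000]
    assert np.max(np.abs(core)) < 1e-6 * 7.3


@pytest.mark.parametrize("freq,band", [(10.0, "pass"), (50.0, "stop")])
def test_filter_response_matches_oracle(freq, band):
    measured = _tone_gain(freq)
    oracle = _oracle_gain(freq)
    assert measured == pytest.approx(oracle, rel=0.02)
    if band == "pass":
        assert 0.95 <= measured <= 1.05
    else:
        assert measured <= 10 ** (-20 / 20)  # at least 20 dB down


def test_cutoffs_outside_nyquist_rejected():
    with pytest.raises(ConfigurationError):
        bandpass_filter(np.zeros(1000), FS, FilterSpec(high_hz=600.0))


def test_zero_phase_no_lag(noise_free_cohort):
    rec = noise_free_cohort[0]
    filtered = bandpass_filter(rec.signal, rec.fs)
    xc = np.correlate(filtered - filtered.mean(), rec.signal - rec.signal.mean(), "full")
    lag = int(np.argmax(xc)) - (rec.signal.size - 1)
    assert lag == 0


def test_detector_exact_on_noise_free(noise_free_cohort):
    for rec in noise_free_cohort:
        det = detect_r_peaks(bandpass_filter(rec.signal, rec.fs), rec.fs)
        true = rec.true_r_peaks
        # every true peak matched within 10 ms, and no spurious detections
        tol = int(0.010 * rec.fs)
        assert len(det) == len(true)
        assert np.all(np.abs(det - true) <= tol)


def test_detector_sensitivity_on_noisy_cohort(small_cohort):
    tol = 50  # +/-50 ms at 1 kHz
    for rec in small_cohort:
        det = detect_r_peaks(bandpass_filter(rec.signal, rec.fs), rec.fs)
        true = rec.true_r_peaks
        matched = sum(np.min(np.abs(det - t)) <= tol for t in true)
        sens = matched / len(true)
        ppv = sum(np.min(np.abs(true - d)) <= tol for d in det) / len(det)
        assert sens >= 0.95 and ppv >= 0.95


def test_detector_refractory_and_monotone(small_cohort):
    rec = small_cohort[0]
    det = detect_r_peaks(bandpass_filter(rec.signal, rec.fs), rec.fs)
    assert np.all(np.diff(det) >= int(0.2 * rec.fs))


def test_detector_all_zero_signal():
    assert detect_r_peaks(np.zeros(5000), FS).size == 0


def test_detector_rejects_short_signal():
    with pytest.raises(ConfigurationError):
        detect_r_peaks(np.zeros(500), FS)


def test_segment_margins_and_count():
    x = np.random.default_rng(0).normal(size=5000)
    peaks = [150, 300, 900, 1500, 2100, 2700, 3300, 3900, 4500, 4700]
    cycles = segment_cycles(x, peaks)
    # peak at 150 lacks the 200-sample pre-R margin; 4700 lacks the post margin
    assert len(cycles) == 8
    assert all(c.samples.size == CYCLE_LEN for c in cycles)
    np.testing.assert_array_equal(cycles[0].samples, x[300 - 200 : 300 + 400])


def test_minmax_normalize_ramp_and_idempotence():
    ramp = CardiacCycle(np.arange(600, dtype=float))
    out = minmax_normalize(ramp)
    np.testing.assert_allclose(out.samples, np.arange(600) / 599)
    again = minmax_normalize(out)
    np.testing.assert_allclose(again.samples, out.samples)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(0.01, 100), beta=st.floats(-50, 50))
def test_minmax_normalize_affine_invariance(alpha, beta):
    base = np.sin(np.linspace(0, 7, 600))
    out1 = minmax_normalize(CardiacCycle(base))
    out2 = minmax_normalize(CardiacCycle(alpha * base + beta))
    np.testing.assert_allclose(out1.samples, out2.samples, atol=1e-9)


def test_minmax_normalize_constant_errors_and_batch_drops():
    with pytest.raises(ConfigurationError):
        minmax_normalize(CardiacCycle(np.ones(600)))
    batch = [CardiacCycle(np.ones(600)), CardiacCycle(np.arange(600, dtype=float))]
    assert len(normalize_cycles(batch)) == 1


def _brute_force_selection(arrays, k):
    """Independent oracle: rank by the sum of pairwise Euclidean distances
    computed pair-by-pair, keep the k best (ties to earlier index)."""
    n = len(arrays)
    scores = []
    for i in range(n):
        scores.append(sum(np.linalg.norm(arrays[i] - arrays[j]) for j in range(n)))
    order = sorted(range(n), key=lambda i: (scores[i], i))
    return sorted(order[:k])


@pytest.mark.parametrize("n,k", [(6, 3), (10, 4), (10, 10), (5, 1)])
def test_selection_matches_brute_force(n, k):
    rng = np.random.default_rng(n * 100 + k)
    arrays = [rng.normal(size=600) for _ in range(n)]
    cycles = [CardiacCycle(a) for a in arrays]
    tset = select_most_similar(cycles, k)
    chosen = [id(c) for c in tset.cycles]
    expected = [id(cycles[i]) for i in _brute_force_selection(arrays, k)]
    assert chosen == expected


def test_selection_keeps_cluster_drops_outliers():
    rng = np.random.default_rng(4)
    base = rng.normal(size=600)
    a_copies = [CardiacCycle(base + 0.01 * rng.normal(size=600)) for _ in range(4)]
    far = [CardiacCycle(base + 100.0 + rng.normal(size=600)) for _ in range(2)]
    tset = select_most_similar(a_copies + far, 3)
    assert all(any(c is a for a in a_copies) for c in tset.cycles)


def test_selection_outlier_rejection_scaled():
    # planted outliers at >= 10x the typical intra-set distance never selected
    rng = np.random.default_rng(8)
    base = rng.normal(size=600)
    inliers = [CardiacCycle(base + 0.05 * rng.normal(size=600)) for _ in range(8)]
    typical = np.linalg.norm(inliers[0].samples - inliers[1].samples)
    outliers = [CardiacCycle(base + 20 * typical / np.sqrt(600)) for _ in range(2)]
    tset = select_most_similar(inliers + outliers, 8)
    assert all(any(c is a for a in inliers) for c in tset.cycles)


def test_selection_order_invariant():
    rng = np.random.default_rng(2)
    arrays = [rng.normal(size=600) for _ in range(7)]
    fwd = select_most_similar([CardiacCycle(a) for a in arrays], 4)
    rev = select_most_similar([CardiacCycle(a) for a in arrays[::-1]], 4)
    fwd_set = {tuple(c.samples) for c in fwd.cycles}
    rev_set = {tuple(c.samples) for c in rev.cycles}
    assert fwd_set == rev_set


def test_selection_too_few_cycles_errors():
    with pytest.raises(ConfigurationError, match="S001"):
        select_most_similar([CardiacCycle(np.zeros(600))], 2, subject_id="S001")
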