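import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tactypes as tt
from tactypes._utils import centered_moving_average
from tactypes.preprocessing import (blank_artifacts, detect_spikes,
                                    extract_windows, normalize_window,
                                    qc_check, remove_spikes, smooth_trace)


# ---------------------------------------------------------------------------
# moving average and smoothing
# ---------------------------------------------------------------------------

@given(st.integers(2, 12), st.integers(13, 60))
@settings(max_examples=25, deadline=None)
def test_centered_moving_average_matches_naive_reference(window, n):
    rng = np.random.default_rng(window * 100 + n)
    x = rng.normal(size=n)
    out = centered_moving_average(x, window)
    left = (window - 1) // 2
    right = window - 1 - left
    ref = [x[max(i - left, 0): i + right + 1].mean() for i in range(n)]
    np.testing.assert_allclose(out, ref, atol=1e-12)


def test_smooth_trace_impulse_becomes_plateau():
    x = np.zeros(21)
    x[10] = 1.0
    out = smooth_trace(x, 100_000.0)  # 5-sample boxcar
    assert np.allclose(out[8:13], 0.2)
    assert out[[7, 13]].max() == 0.0


def test_smooth_trace_constant_unchanged():
    out = smooth_trace(np.full(100, -70.0), 100_000.0)
    np.testing.assert_allclose(out, -70.0)


def test_smooth_trace_variance_reduction(rng):
    x = rng.normal(size=200_000)
    out = smooth_trace(x, 100_000.0)
    ratio = out[100:-100].var() / x.var()
    assert abs(ratio - 0.2) < 0.02  # boxcar of 5 on iid noise


# ---------------------------------------------------------------------------
# artifact blanking
# ---------------------------------------------------------------------------

def test_blank_artifact_removes_planted_transient():
    fs = 100_000.0
    vm = np.full(int(0.02 * fs), -70.0)
    i0 = int(0.01 * fs)
    vm[i0: i0 + int(0.001 * fs)] += 30.0
    out = blank_artifacts(vm, np.array([0.01]), fs)
    assert np.abs(out + 70.0).max() < 1.0


def test_blank_empty_pulse_list_is_identity(rng):
    vm = rng.normal(size=1000)
    np.testing.assert_array_equal(blank_artifacts(vm, np.array([]), 100_000.0), vm)


def test_blank_merges_overlapping_windows():
    fs = 100_000.0
    vm = np.arange(int(0.01 * fs), dtype=float)
    out = blank_artifacts(vm, np.array([0.002, 0.0025]), fs, blank_ms=1.0)
    # merged span [2, 3.5] ms is one straight line (input is linear anyway,
    # so check by planting a bump inside the overlap)
    vm2 = vm.copy()
    vm2[int(0.0026 * fs)] += 50
    out2 = blank_artifacts(vm2, np.array([0.002, 0.0025]), fs, blank_ms=1.0)
    assert np.abs(out2 - out).max() < 1e-9


# ---------------------------------------------------------------------------
# spike removal
# ---------------------------------------------------------------------------

def _spike_kernel(fs):
    st_ = np.arange(int(0.003 * fs)) / fs * 1000.0
    return 40.0 * np.where(st_ < 0.5, st_ / 0.5, np.exp(-(st_ - 0.5) / 0.8))


def test_remove_spikes_subtracts_identical_planted_spikes():
    fs = 100_000.0
    vm = np.full(int(1.0 * fs), -70.0)
    kern = _spike_kernel(fs)
    times = np.arange(0.05, 0.95, 0.09)
    for t in times:
        i = int(t * fs)
        vm[i: i + kern.size] += kern
    cleaned, detected = remove_spikes(vm, fs)
    assert detected.size == times.size
    assert np.abs(cleaned + 70.0).max() < 0.05 * 40.0


def test_remove_spikes_noop_without_spikes(rng):
    vm = -70.0 + 0.1 * rng.normal(size=50_000)
    cleaned, times = remove_spikes(vm, 100_000.0)
    assert times.size == 0
    np.testing.assert_array_equal(cleaned, vm)


def test_two_spikes_reported_but_not_subtracted():
    fs = 100_000.0
    vm = np.full(int(0.5 * fs), -70.0)
    kern = _spike_kernel(fs)
    for t in (0.1, 0.3):
        i = int(t * fs)
        vm[i: i + kern.size] += kern
    cleaned, times = remove_spikes(vm, fs)
    assert times.size == 2
    np.testing.assert_array_equal(cleaned, vm)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_constant_trace_fails_peak_to_peak():
    report = qc_check(np.full(100_000, -70.0), 100_000.0)
    assert report.unimodal
    assert report.down_state_mode == pytest.approx(-70.0, abs=0.5)
    assert not report.passes["up_down_p2p"]
    assert not report.overall


def test_qc_depolarized_trace_fails_down_state(small_session):
    _, rec, _ = small_session
    report = qc_check(rec.vm[: 2_000_000] + 20.0, rec.fs_vm)
    assert not report.passes["down_state"]


def test_qc_passes_on_seeded_sessions():
    for seed in range(3):
        cfg = tt.SessionConfig(n_patterns=1, reps_per_pattern=8,
                               single_pulse_chunks_per_channel=1, seed=seed)
        rec, _ = tt.simulate_session(cfg)
        assert qc_check(rec.vm, rec.fs_vm).overall


# ---------------------------------------------------------------------------
# window extraction and normalization
# ---------------------------------------------------------------------------

def test_extract_windows_counts_and_truncation(small_session):
    _, rec, _ = small_session
    wins, meta = extract_windows(rec.vm, rec.fs_vm, rec.events, 350.0)
    n_pat = (rec.events.kind == "pattern").sum()
    assert wins.shape == (n_pat, 35_000)
    # truncate the recording after the 5th onset: later windows are dropped
    cut = int(rec.events[rec.events.kind == "pattern"].onset_s.iloc[5] * rec.fs_vm)
    wins2, meta2 = extract_windows(rec.vm[:cut], rec.fs_vm, rec.events, 350.0)
    assert wins2.shape[0] == 5


def test_extended_windows_do_not_overlap_next_onset(small_session):
    cfg, rec, _ = small_session
    assert cfg.inter_trial_gap_s >= 1.2  # 1200-ms windows fit in the gap


def test_normalize_window_range_and_degenerate():
    rng = np.random.default_rng(1)
    w, degen = normalize_window(-70 + rng.normal(size=3500), 10_000.0)
    assert not degen
    assert w.min() == pytest.approx(0.0, abs=1e-12)
    assert w.max() == pytest.approx(1.0, abs=1e-12)
    assert w.size == 350
    w2, degen2 = normalize_window(np.full(3500, -70.0), 10_000.0)
    assert degen2
    np.testing.assert_array_equal(w2, 0.5)


def test_normalize_window_sinusoid_closed_form():
    """A 5-Hz sinusoid survives the 100-ms offset subtraction attenuated by
    1 - sinc(pi f T) with phase preserved."""
    fs = 10_000.0
    t = np.arange(int(0.35 * fs)) / fs
    raw = -70 + 2.0 * np.sin(2 * np.pi * 5.0 * t)
    w, _ = normalize_window(raw, fs)
    t_ms = np.arange(350) / 1000.0
    expected = np.sin(2 * np.pi * 5.0 * t_ms)
    expected = (expected - expected.min()) / (expected.max() - expected.min())
    # ignore edges where the shrinking moving average distorts the offset
    core = slice(60, 290)
    assert np.corrcoef(w[core], expected[core])[0, 1] > 0.999


def test_normalize_offset_invariance(rng):
    raw = -70 + rng.normal(size=3500)
    a, _ = normalize_window(raw, 10_000.0)
    b, _ = normalize_window(raw + 13.7, 10_000.0)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_normalize_affine_invariance(window_set):
    """A normalized window reconstructed at any positive gain and offset
    renormalizes to exactly the same curve."""
    w = window_set.windows[0]
    a, _ = normalize_window(w, 1000.0)
    b, _ = normalize_window(4.2 * w - 63.0, 1000.0)
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_mean_window_recovers_planted_template(window_set):
    """Mean normalized window of each planted type correlates >= 0.9 with the
    designed template on the same scale."""
    for k in range(4):
        idx = window_set.true_labels == k
        mean_curve = window_set.windows[idx].mean(axis=0)
        target = window_set.template_set.normalized_targets[k]
        assert np.corrcoef(mean_curve, target)[0, 1] >= 0.9
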