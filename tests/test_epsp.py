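import numpy as np
import pandas as pd
import pytest

import tactypes as tt
from tactypes._utils import ou_noise
from tactypes.epsp import (DetectorParams, EpspTemplate, build_epsp_template,
                           fraction_significant_across_pulses, match_template,
                           measure_pulse_response, order_effect_test,
                           pairwise_neuron_tests, response_fraction_and_gate,
                           select_in_pattern_pulses)
from tactypes.simulate import SinglePulseParams, _alpha_kernel

FS = 50_000.0
NEURON = {"amplitude_mv": 7.7, "latency_ms": 11.1, "ttp_ms": 9.8}


def _trace_with_events(rng, dur_s, onsets_s, events=None, noise_sd=0.3):
    n = int(dur_s * FS)
    vm = -70.0 + ou_noise(rng, n, FS, noise_sd, 0.015) + rng.normal(0, 0.08, n)
    kern_t = np.arange(int(0.1 * FS)) / FS * 1000.0
    sp = SinglePulseParams()
    drawn = []
    for j, t0 in enumerate(onsets_s):
        ev = events[j] if events is not None else sp.draw_event(rng, NEURON)
        i = int(t0 * FS)
        k = ev["amplitude_mv"] * _alpha_kernel(kern_t, ev["ttp_ms"])
        vm[i: i + k.size] += k[: max(0, n - i)]
        drawn.append(ev)
    return vm, drawn


@pytest.fixture(scope="module")
def template():
    rng = np.random.default_rng(42)
    onsets = np.arange(1.0, 60.0, 0.4)
    vm, _ = _trace_with_events(rng, 61.0, onsets)
    return build_epsp_template(vm, onsets, FS)


# ---------------------------------------------------------------------------
# automated measurement
# ---------------------------------------------------------------------------

def test_measure_recovers_planted_event_on_flat_baseline():
    vm = np.full(int(0.3 * FS), -70.0)
    kern_t = np.arange(int(0.1 * FS)) / FS * 1000.0
    i = int(0.15 * FS)
    kern = 8.0 * _alpha_kernel(kern_t - 11.0, 9.8)
    vm[i: i + kern.size] += kern
    ev = measure_pulse_response(vm, 0.15, FS)
    assert ev is not None
    assert ev.amplitude_mv == pytest.approx(8.0, rel=0.10)
    assert ev.latency_ms == pytest.approx(11.0, abs=1.0)


def test_measure_flat_trace_returns_none():
    assert measure_pulse_response(np.full(int(0.3 * FS), -70.0), 0.15, FS) is None


def test_measure_truncated_window_returns_none():
    vm = np.full(int(0.12 * FS), -70.0)
    assert measure_pulse_response(vm, 0.115, FS) is None


def test_measured_amplitude_cv_matches_published_value():
    cvs = []
    for seed in range(3):
        traces, t_pulse, truth = tt.simulate_single_pulse_trials(
            n_trials=140, seed=seed, fs=FS)
        amps = [ev.amplitude_mv for tr in traces
                if (ev := measure_pulse_response(tr, t_pulse, FS)) is not None]
        amps = np.asarray(amps)
        if amps.size >= 50:
            cvs.append(amps.std(ddof=1) / amps.mean())
    assert len(cvs) >= 2
    assert np.mean(cvs) == pytest.approx(0.43, abs=0.08)


# ---------------------------------------------------------------------------
# template construction and matching
# ---------------------------------------------------------------------------

def test_template_requires_enough_events():
    with pytest.raises(ValueError):
        build_epsp_template(np.zeros(100_000), np.arange(50) * 0.01, FS)


def test_template_checkpoint_count_clamped():
    rng = np.random.default_rng(0)
    onsets = np.arange(1.0, 50.0, 0.4)
    vm, _ = _trace_with_events(rng, 51.0, onsets)
    assert len(build_epsp_template(vm, onsets, FS, n_checkpoints=3).offsets_ms) == 5
    assert len(build_epsp_template(vm, onsets, FS, n_checkpoints=99).offsets_ms) == 20


def test_identical_events_yield_floor_tolerances_and_match():
    vm = np.full(int(80.0 * FS), -70.0)
    kern_t = np.arange(int(0.1 * FS)) / FS * 1000.0
    kern = 8.0 * _alpha_kernel(kern_t, 9.8)
    onsets = np.arange(1.0, 79.0, 0.5)
    for t0 in onsets:
        i = int(t0 * FS)
        vm[i: i + kern.size] += kern
    tpl = build_epsp_template(vm, onsets, FS)
    assert max(tpl.tolerances_mv) < 0.5   # essentially the 0.2-mV floor
    hits = match_template(vm, tpl, FS)
    d = np.min(np.abs(hits[:, None] - onsets[None, :]), axis=0)
    assert np.mean(d < 0.001) >= 0.99


def test_template_recall_on_held_out_events():
    recalls = []
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        onsets = np.arange(1.0, 89.0, 0.35)
        vm, _ = _trace_with_events(rng, 90.0, onsets)
        train, test = onsets[:150], onsets[150:]
        tpl = build_epsp_template(vm, train, FS)
        hits = match_template(vm, tpl, FS)
        d = np.min(np.abs(hits[:, None] - test[None, :]), axis=0)
        recalls.append(np.mean(d < 0.002))
    assert np.mean(recalls) >= 0.95


def test_false_positive_rate_on_event_free_background(template):
    rng = np.random.default_rng(9)
    vm = -70.0 + ou_noise(rng, int(30 * FS), FS, 0.3, 0.015) \
        + rng.normal(0, 0.08, int(30 * FS))
    fp = match_template(vm, template, FS)
    assert fp.size / 3.0 <= 1.0   # at most one per 10 s


def test_template_invariants():
    with pytest.raises(ValueError):
        EpspTemplate((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        EpspTemplate(tuple(np.arange(5.0)[::-1]), (0.1,) * 5, (1.0,) * 5)


# ---------------------------------------------------------------------------
# response fraction gate
# ---------------------------------------------------------------------------

def test_gate_responsive_pulse_significant(template):
    rng = np.random.default_rng(5)
    pattern_onsets = np.arange(3.0, 60.0, 2.0)
    pulse_times = pattern_onsets + 0.05
    events = [SinglePulseParams().draw_event(rng, NEURON) for _ in pulse_times]
    vm, _ = _trace_with_events(rng, 62.0, pulse_times + np.array(
        [e["latency_ms"] for e in events]) / 1000.0,
        [dict(e, latency_ms=0.0) for e in events])
    out = response_fraction_and_gate(vm, FS, template, pulse_times, pattern_onsets)
    assert out["fraction"] > 0.7
    assert out["significant"]


def test_gate_minimum_event_count(template):
    rng = np.random.default_rng(6)
    pattern_onsets = np.arange(3.0, 60.0, 2.0)
    pulse_times = pattern_onsets[:4] + 0.05  # only 4 occurrences -> < 5 events
    vm, _ = _trace_with_events(
        rng, 62.0, pulse_times + 0.011,
        [dict(NEURON, latency_ms=0.0) for _ in pulse_times])
    out = response_fraction_and_gate(vm, FS, template, pulse_times, pattern_onsets)
    assert out["n_events"] <= 4
    assert not out["significant"]


def test_gate_fails_closed_without_pattern_onsets(template):
    vm = np.full(int(5.0 * FS), -70.0)
    out = response_fraction_and_gate(vm, FS, template, np.array([1.0]),
                                     np.array([]))
    assert not out["significant"]
    assert np.isnan(out["baseline_mean"])


def test_gate_type_one_error_on_baseline_only(template):
    """Spontaneous-only traces pass the gate at most rarely."""
    flagged = 0
    runs = 30
    for seed in range(runs):
        rng = np.random.default_rng(1000 + seed)
        # spontaneous template-like events at 1 Hz, no pulse-locked response
        spont = np.sort(rng.uniform(1.0, 59.0, size=58))
        vm, _ = _trace_with_events(rng, 60.0, spont)
        pattern_onsets = np.arange(3.0, 58.0, 2.0)
        pulse_times = pattern_onsets + 0.05
        out = response_fraction_and_gate(vm, FS, template, pulse_times,
                                         pattern_onsets)
        if out["significant"]:
            flagged += 1
    assert flagged / runs <= 0.05


def test_fraction_bounded_and_baseline_bin_count(template, small_session):
    out = response_fraction_and_gate(
        np.full(int(10.0 * FS), -70.0), FS, template,
        np.array([5.0]), np.array([4.0]))
    assert 0.0 <= out["fraction"] <= 1.0


# ---------------------------------------------------------------------------
# pulse eligibility
# ---------------------------------------------------------------------------

def test_eligibility_hand_checked_example():
    from types import SimpleNamespace
    p = SimpleNamespace(label="X", offsets_ms=(0.0, 5.0, 30.0, 45.0))
    eligible = select_in_pattern_pulses([p])
    assert eligible == [("X", 2), ("X", 3)]


def test_eligibility_uniform_spacings():
    from types import SimpleNamespace
    wide = SimpleNamespace(label="W", offsets_ms=tuple(np.arange(0, 100, 20.0)))
    tight = SimpleNamespace(label="T", offsets_ms=tuple(np.arange(0, 25, 5.0)))
    assert len(select_in_pattern_pulses([wide])) == 5
    assert select_in_pattern_pulses([tight]) == []


def test_eligibility_monotone_in_min_separation():
    patterns = tt.generate_patterns(8, 4, seed=3)
    prev = None
    for sep in (5.0, 10.0, 20.0, 40.0):
        n = len(select_in_pattern_pulses(patterns, min_sep_ms=sep))
        if prev is not None:
            assert n <= prev
        prev = n


# ---------------------------------------------------------------------------
# nonparametric comparisons
# ---------------------------------------------------------------------------

def test_order_effect_identical_ranks_p_one():
    amp = list(np.linspace(5, 10, 20))
    events = pd.DataFrame({"rank": np.repeat([1, 2], 20),
                           "amplitude_mv": amp + amp})
    mat = order_effect_test(events, n_ranks=2)
    assert mat[0, 1] == pytest.approx(1.0)


def test_order_effect_null_calibration():
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(40):
        events = pd.DataFrame({
            "rank": np.tile(np.arange(1, 6), 20),
            "amplitude_mv": rng.normal(7.7, 3.3, size=100)})
        mat = order_effect_test(events)
        iu = np.triu_indices(5, k=1)
        ps.extend(mat[iu])
    ps = np.asarray(ps)
    assert abs(np.mean(ps < 0.05) - 0.05) < 0.04


def test_order_effect_detects_planted_depression():
    rng = np.random.default_rng(1)
    amps = np.concatenate([rng.normal(8, 1, 20)] + [
        rng.normal(4, 1, 20) for _ in range(4)])
    events = pd.DataFrame({"rank": np.repeat(np.arange(1, 6), 20),
                           "amplitude_mv": amps})
    mat = order_effect_test(events)
    assert np.all(mat[0, 1:] < 0.01)


def test_order_effect_skips_tiny_groups():
    events = pd.DataFrame({"rank": [1, 1, 2, 2, 2],
                           "amplitude_mv": [5, 6, 7, 8, 9.0]})
    mat = order_effect_test(events, n_ranks=2)
    assert np.isnan(mat[0, 1])


def test_pairwise_neuron_null_and_power():
    rng = np.random.default_rng(2)
    # identical distributions -> ~5% significant
    fracs = []
    for _ in range(40):
        vals = {n: rng.normal(7.7, 3.3, 25) for n in range(4)}
        _, frac = pairwise_neuron_tests(vals)
        fracs.append(frac)
    assert abs(np.nanmean(fracs) - 0.05) < 0.05
    # a planted 2x amplitude difference is detected
    table, _ = pairwise_neuron_tests({0: rng.normal(4, 1, 25),
                                      1: rng.normal(8, 1, 25)})
    assert table.p.iloc[0] < 0.01


def test_pairwise_single_neuron_empty():
    table, frac = pairwise_neuron_tests({0: np.arange(10.0)})
    assert table.empty
    assert np.isnan(frac)
    assert np.isnan(fraction_significant_across_pulses([table]))
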