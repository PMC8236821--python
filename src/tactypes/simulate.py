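"""Synthetic session generator with planted ground truth.

Emulates the study's recording regime so every downstream stage can be tested
without real data: an Up/Down bistable membrane potential with colored noise
and spontaneous EPSPs, evoked responses drawn from K latent response-type
templates (plus a diffuse "ungrouped" process), single-pulse EPSPs with
published amplitude/latency statistics, biphasic stimulus artifacts,
occasional stereotyped spikes, and an ECoG whose low-frequency (0-12 Hz)
power alternates between synchronized and desynchronized epochs.

Two entry points matter:

``simulate_session``
    Full raw-signal path (Vm at ``vm_rate``, ECoG at ``ecog_rate``, event
    table, ground truth), for end-to-end pipeline runs.

``simulate_window_set``
    Fast path that synthesizes one (neuron, pattern) cell's trial-aligned
    response windows directly at 1 kHz and pushes them through the real
    normalization pipeline.  Used for clustering / statistics work at scale.

The single-pulse EPSP model is hierarchical: per-neuron means are drawn so
that the *pooled* amplitude distribution across neurons has mean 7.7 mV and
SD 4.8 mV while the *within*-neuron coefficient of variation is 0.43 (and
analogously for onset latency and time-to-peak).  Both levels of variability
are published population statistics; a single-level model cannot reproduce
both at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.linalg import hadamard

from ._utils import substream, ou_noise, pink_noise, centered_moving_average
from .patterns import StimulationPattern, generate_patterns

UNGROUPED = -1

WINDOW_MS = 350
EXTENDED_MS = 1200
EDGE_BOUND = 2.0   # max |edge value| of a pre-compensated template, normalized units

# 5-ms onset ramp applied when stamping evoked responses into a raw trace,
# so the response onset does not masquerade as a spike-like fast transient
_ONSET_RAMP = np.ones(EXTENDED_MS)
_ONSET_RAMP[:5] = np.linspace(0.2, 1.0, 5)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinglePulseParams:
    """Population statistics of isolated single-pulse EPSP responses.

    ``*_mean`` / ``*_sd`` describe the pooled distribution across neurons;
    ``*_cv`` is the within-neuron coefficient of variation.  The between-
    neuron spread of the per-neuron means is derived so that the pooled
    moments come out right.
    """

    amplitude_mean_mv: float = 7.7
    amplitude_sd_mv: float = 4.8
    amplitude_cv: float = 0.43
    latency_mean_ms: float = 11.1
    latency_sd_ms: float = 3.1
    latency_cv: float = 0.28
    ttp_mean_ms: float = 9.8
    ttp_sd_ms: float = 5.6
    ttp_cv: float = 0.29

    @staticmethod
    def _between_sd(mean: float, pooled_sd: float, cv: float) -> float:
        # pooled_var = cv^2 * (mean^2 + var_b) + var_b  =>  solve for var_b
        var_b = (pooled_sd**2 - cv**2 * mean**2) / (1.0 + cv**2)
        return float(np.sqrt(max(var_b, 0.0)))

    def draw_neuron(self, rng: np.random.Generator) -> dict[str, float]:
        """Per-neuron mean amplitude/latency/time-to-peak."""
        amp_b = self._between_sd(self.amplitude_mean_mv, self.amplitude_sd_mv, self.amplitude_cv)
        lat_b = self._between_sd(self.latency_mean_ms, self.latency_sd_ms, self.latency_cv)
        ttp_b = self._between_sd(self.ttp_mean_ms, self.ttp_sd_ms, self.ttp_cv)
        return {
            "amplitude_mv": max(1.0, rng.normal(self.amplitude_mean_mv, amp_b)),
            "latency_ms": max(3.0, rng.normal(self.latency_mean_ms, lat_b)),
            "ttp_ms": max(3.0, rng.normal(self.ttp_mean_ms, ttp_b)),
        }

    def draw_event(self, rng: np.random.Generator, neuron: dict[str, float]) -> dict[str, float]:
        """One EPSP event for a given neuron (within-neuron scatter)."""
        return {
            "amplitude_mv": max(0.3, rng.normal(neuron["amplitude_mv"],
                                                self.amplitude_cv * neuron["amplitude_mv"])),
            "latency_ms": max(1.0, rng.normal(neuron["latency_ms"],
                                              self.latency_cv * neuron["latency_ms"])),
            "ttp_ms": max(4.0, rng.normal(neuron["ttp_ms"],
                                          self.ttp_cv * neuron["ttp_ms"])),
        }


@dataclass(frozen=True)
class SessionConfig:
    """All tunables of one simulated session.  Defaults are the study's
    stated conditions; signal/kinetic constants are documented choices."""

    n_patterns: int = 8
    n_channels: int = 4
    reps_per_pattern: int = 100
    reps_overrides: dict = field(default_factory=dict)  # label -> reps (truncated recordings)
    inter_trial_gap_s: float = 1.8
    k_types_min: int = 3
    k_types_max: int = 6
    ungrouped_fraction: float = 0.2
    single_pulse_chunks_per_channel: int = 20
    pulses_per_chunk: int = 5
    chunk_ipi_s: float = 0.3
    vm_rate: float = 100_000.0
    ecog_rate: float = 1_000.0
    # Up/Down background
    down_level_mv: float = -72.0
    up_level_mv: float = -58.0
    up_dwell_mean_s: float = 0.45
    down_dwell_mean_s: float = 0.7
    ou_sd_mv: float = 0.5
    ou_tau_s: float = 0.015
    white_sd_mv: float = 0.1
    # spontaneous EPSP shot noise
    spont_epsp_rate_hz: float = 1.0
    spont_epsp_amp_mv: float = 2.5
    spont_epsp_amp_sd_mv: float = 1.0
    # evoked responses
    evoked_gain_mv: float = 12.0
    within_type_noise_sd: float = 0.03   # normalized units
    template_separation: float = 0.42    # min pairwise mean |difference|, normalized units
    state_suppression: float = 0.9       # how strongly stimulation overrides Up/Down flips
    pulse_response_prob: float = 0.75
    # artifacts and spikes
    artifact_amp_mv: float = 30.0
    spike_rate_hz: float = 0.05
    spike_amp_mv: float = 40.0
    include_spikes: bool = True
    include_ecog: bool = True
    # ECoG state process
    desync_fraction: float = 0.2
    sync_dwell_mean_s: float = 8.0
    single_pulse: SinglePulseParams = field(default_factory=SinglePulseParams)
    neuron_id: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.vm_rate <= 0 or self.ecog_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.reps_per_pattern < 1:
            raise ValueError("reps_per_pattern must be >= 1")
        if not self.down_level_mv < -55.0:
            raise ValueError("Down level must be < -55 mV (QC criterion)")
        if not (self.up_level_mv - self.down_level_mv) > 10.0:
            raise ValueError("Up-Down separation must exceed 10 mV (QC criterion)")
        if not (0.0 <= self.ungrouped_fraction < 1.0):
            raise ValueError("ungrouped_fraction must be in [0, 1)")
        if self.k_types_min < 1 or self.k_types_max < self.k_types_min:
            raise ValueError("invalid k_types range")


# ---------------------------------------------------------------------------
# response-type templates
# ---------------------------------------------------------------------------

def _alpha_kernel(t_ms: np.ndarray, tau_ms: float) -> np.ndarray:
    """Alpha-function EPSP kernel peaking at tau with unit amplitude."""
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    x = t_ms[pos] / tau_ms
    out[pos] = x * np.exp(1.0 - x)
    return out


def _activity_envelope(t_ms: np.ndarray, t_on: float, t_off: float, decay_ms: float) -> np.ndarray:
    env = np.clip((t_ms - t_on) / 5.0, 0.0, 1.0)
    late = t_ms > t_off
    env[late] *= np.exp(-(t_ms[late] - t_off) / decay_ms)
    return env


@dataclass
class TypeTemplateSet:
    """K planted response-type templates for one stimulation pattern.

    ``templates`` holds raw-scale curves of length EXTENDED_MS: they are
    constructed so that, after the analysis pipeline's own normalization
    (100-ms offset subtraction and per-window min-max scaling), the 350-ms
    stimulation window reproduces the designed target shapes in
    ``normalized_targets`` and the requested pairwise separation holds on
    the scale the clustering actually sees.  After stimulus offset every
    template decays to baseline and carries the same stereotyped off-
    response (rebound), so full-extent normalization constants are
    trial-invariant.  ``draw_ungrouped`` produces a fresh diffuse curve per
    call, emulating rare latent types that do not recur.
    """

    pattern: StimulationPattern
    templates: np.ndarray          # (k, EXTENDED_MS), raw scale
    normalized_targets: np.ndarray  # (k, WINDOW_MS), post-pipeline scale
    separation: float
    _region_bounds: np.ndarray
    _pulse_component: np.ndarray
    _rebound: np.ndarray

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    def min_pairwise_separation(self) -> float:
        """Min pairwise mean |difference| on the post-normalization scale."""
        from .preprocessing import normalize_window

        norm = [normalize_window(-70.0 + 12.0 * tp[:WINDOW_MS], 1000.0)[0]
                for tp in self.templates]
        return min_pairwise_separation(np.asarray(norm))

    def draw_ungrouped(self, rng: np.random.Generator) -> np.ndarray:
        """A fresh rare latent type: a random binary region code.

        Diffuse responses are modeled as response types too rare to recur:
        two draws share a code only with vanishing probability, so they
        almost never pair-match under the clustering rule.
        """
        m = self._region_bounds.size - 1
        for _ in range(100):
            bounds = self._region_bounds.copy()
            bounds[1:-1] += rng.uniform(-6.0, 6.0, size=m - 1)
            # random code with runs of at most two regions (same constraint as
            # the planted types, so the pre-compensated amplitude stays bounded)
            code = np.empty(m)
            code[0] = rng.integers(0, 2)
            run = 1
            for j in range(1, m):
                if run >= 2 or rng.random() < 0.5:
                    code[j] = 1.0 - code[j - 1]
                    run = 1
                else:
                    code[j] = code[j - 1]
                    run += 1
            target = _code_target(code, bounds, self._pulse_component)
            pre = _precompensate(target)
            if abs(pre[-1]) <= EDGE_BOUND:
                break
        return _extend_template(pre, self._rebound)


def _code_target(code: np.ndarray, bounds: np.ndarray,
                 pulse_comp: np.ndarray) -> np.ndarray:
    """Post-pipeline target curve for one binary region code (350 samples)."""
    t = np.arange(WINDOW_MS, dtype=float)
    profile = np.zeros(WINDOW_MS)
    m = bounds.size - 1
    for j in range(m):
        profile[(t >= bounds[j]) & (t < bounds[j + 1])] = code[j]
    profile[t < bounds[0]] = code[0]
    profile[t >= bounds[-1]] = code[-1]
    profile = gaussian_filter1d(profile, 0.75)
    target = 0.97 * profile + 0.03 * pulse_comp[:WINDOW_MS]
    lo, hi = target.min(), target.max()
    target = (target - lo) / (hi - lo)
    # common terminal ramp to mid-level, so every type's curve leaves the
    # window at the same value (keeps the post-window bridge type-invariant)
    ramp_len = 8
    w = 0.5 * (1.0 + np.cos(np.pi * np.arange(ramp_len) / (ramp_len - 1)))
    target[-ramp_len:] = w * target[-ramp_len] + (1.0 - w) * 0.5
    return target


@lru_cache(maxsize=4)
def _offset_removal_pinv(n: int, window: int = 100) -> np.ndarray:
    """Pseudoinverse of the offset-subtraction operator x -> x - MA(x).

    The operator is singular on constants (an offset is removed entirely);
    the pseudoinverse returns the minimum-norm (zero-mean) pre-image.
    """
    m = np.zeros((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        m[:, i] = e - centered_moving_average(e, window)
    return np.linalg.pinv(m, rcond=1e-8)


def _precompensate(target: np.ndarray) -> np.ndarray:
    """Pre-image of the designed post-pipeline shape under offset removal.

    The analysis pipeline subtracts a centered 100-ms moving average before
    scaling; planting the pre-image of the desired shape makes the post-
    pipeline 350-ms curve equal the designed target.  Targets are built from
    short-run region codes, so their low-frequency content (which the
    inversion amplifies) stays moderate and the template amplitude bounded.
    """
    y0 = target - target.mean()
    return _offset_removal_pinv(target.size) @ y0


def _extend_template(r350: np.ndarray, rebound: np.ndarray) -> np.ndarray:
    """Bridge quickly to baseline, then add the common off-response.

    The bridge time constant (5 ms) is short enough that the moving-average
    windows of the off-response extremes see only type-invariant content,
    keeping full-extent normalization constants trial-invariant.
    """
    ext = np.zeros(EXTENDED_MS)
    ext[:WINDOW_MS] = r350
    tail_t = np.arange(EXTENDED_MS - WINDOW_MS, dtype=float)
    ext[WINDOW_MS:] = r350[-1] * np.exp(-tail_t / 2.0)
    return ext + rebound


def min_pairwise_separation(templates: np.ndarray) -> float:
    k = templates.shape[0]
    if k < 2:
        return np.inf
    vals = [np.mean(np.abs(templates[i] - templates[j]))
            for i in range(k) for j in range(i + 1, k)]
    return float(min(vals))


def generate_type_templates(
    pattern: StimulationPattern,
    k_types: int,
    seed: int = 0,
    separation: float = 0.42,
    max_attempts: int = 1000,
) -> TypeTemplateSet:
    """Build K smooth response-type templates with guaranteed separation.

    Each type is a smoothed binary level code over ~21-ms regions of the
    stimulation window (codes are mutually balanced Hadamard rows, so any
    two types disagree over half the window) combined with pulse-triggered
    alpha kernels.  The separation contract is enforced on the scale the
    clustering consumes: the designed code curve is the *post-pipeline*
    target, and the planted raw template is its pre-image under the offset-
    subtraction step.  Raises if the requested pairwise separation is not
    achieved within ``max_attempts``.
    """
    if k_types < 1:
        raise ValueError("k_types must be >= 1")
    if k_types > 15:
        raise ValueError("at most 15 planted types are supported")
    rng = substream(seed, "templates")
    t = np.arange(EXTENDED_MS, dtype=float)

    # Stereotyped off-response shared by every trial: a brief hyperpolarizing
    # dip followed by a rebound depolarization after stimulus offset.  Being
    # type-unspecific and large, it pins the extremes (hence the
    # normalization constants) of full-extent windows to trial-invariant
    # features, the way stimulus-locked but state-independent off-responses do.
    rebound = (-2.5 * np.exp(-0.5 * ((t - 410.0) / 12.0) ** 2)
               + 4.0 * np.exp(-0.5 * ((t - 455.0) / 18.0) ** 2))
    pulse_comp = np.zeros(EXTENDED_MS)
    for off, _ch in pattern.pulses():
        pulse_comp += _alpha_kernel(t - off - 8.0, tau_ms=9.0)
    if pulse_comp.max() > 0:
        pulse_comp = pulse_comp / pulse_comp.max()

    m = 16
    H = (hadamard(m) > 0).astype(float)
    # rows whose codes flip level at least every two regions: their slow
    # spectral content is small, keeping the pre-compensated template bounded
    short_run_rows = np.array([1, 2, 3, 5, 7, 9, 11, 13, 15])
    t_off = min(max(pattern.duration_ms + 4.0, 330.0), WINDOW_MS - 4.0)

    best = None
    for _ in range(max_attempts):
        # complement pairs of Hadamard rows: pairwise Hamming >= m/2, and every
        # region carries both levels, so each type differs from the "rest" of
        # its cell throughout the stimulation window
        rows = rng.choice(short_run_rows, size=(k_types + 1) // 2, replace=False)
        codes = []
        for r in rows:
            codes += [H[r], 1.0 - H[r]]
        codes = np.stack(codes[:k_types])
        bounds = np.linspace(0.0, t_off, m + 1)
        bounds[1:-1] += rng.uniform(-1.5, 1.5, size=m - 1)
        # stagger boundaries per type, so no two types cross between levels
        # at the same instant (at a shared crossing both would momentarily be
        # indistinguishable from the cell's pooled "rest")
        targets = []
        for i, c in enumerate(codes):
            b = bounds.copy()
            b[1:-1] += 3.5 * (i - (k_types - 1) / 2.0)
            targets.append(_code_target(c, b, pulse_comp))
        targets = np.stack(targets)
        achieved = min_pairwise_separation(targets)
        if best is None or achieved > best[0]:
            best = (achieved, None)
        if achieved < separation:
            continue
        pre = [_precompensate(y) for y in targets]
        # the step from the template's edge value down to baseline must stay
        # well below the off-response extremes, or the full-extent scaling
        # constants become type-specific
        if max(abs(r[-1]) for r in pre) > EDGE_BOUND:
            continue
        templates = np.stack([_extend_template(r, rebound) for r in pre])
        tset = TypeTemplateSet(pattern, templates, targets, separation,
                               bounds, pulse_comp, rebound)
        if tset.min_pairwise_separation() >= separation:
            return tset
        best = (max(best[0], tset.min_pairwise_separation()), None)
    raise RuntimeError(
        f"could not achieve template separation {separation:.3f} "
        f"(best {best[0]:.3f}) in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# fast path: trial-aligned response windows for one (neuron, pattern) cell
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Normalized response windows of one (neuron, pattern) cell plus truth."""

    windows: np.ndarray        # (n, 350) normalized to [0, 1]
    windows_ext: np.ndarray    # (n, 1200) normalized over the full extent
    true_labels: np.ndarray    # planted type id, UNGROUPED == -1
    template_set: TypeTemplateSet
    neuron_id: int = 0
    pattern_label: str = ""


def simulate_window_set(
    k_types: int = 4,
    reps_per_type: int = 80,
    ungrouped_fraction: float = 0.2,
    noise_sd: float = 0.03,
    separation: float = 0.42,
    seed: int = 0,
    pattern: StimulationPattern | None = None,
    neuron_id: int = 0,
) -> WindowSet:
    """Generate one cell's worth of planted response windows at 1 kHz.

    Raw mV-scale windows (template x gain + noise on a resting baseline) are
    pushed through the actual normalization pipeline, so the returned windows
    carry the same per-window min-max scaling and 100-ms offset removal as
    windows extracted from a full recording.
    """
    from .preprocessing import normalize_window

    if pattern is None:
        pattern = generate_patterns(1, 4, seed=seed)[0]
    tset = generate_type_templates(pattern, k_types, seed=seed, separation=separation)
    rng = substream(seed, "evoked")

    n_grouped = k_types * reps_per_type
    n_ungrouped = int(round(ungrouped_fraction / (1.0 - ungrouped_fraction) * n_grouped)) \
        if ungrouped_fraction > 0 else 0
    labels = np.concatenate([
        np.repeat(np.arange(k_types), reps_per_type),
        np.full(n_ungrouped, UNGROUPED),
    ])
    rng.shuffle(labels)

    gain = 12.0
    spont_rate_hz = 1.5
    t_ms = np.arange(EXTENDED_MS, dtype=float)
    n = labels.size
    windows = np.empty((n, WINDOW_MS))
    windows_ext = np.empty((n, EXTENDED_MS))
    for i, lab in enumerate(labels):
        curve = tset.templates[lab] if lab != UNGROUPED else tset.draw_ungrouped(rng)
        raw = -70.0 + gain * (curve + rng.normal(0.0, noise_sd, size=EXTENDED_MS))
        # spontaneous EPSP shot noise riding on the window
        for t_ev in rng.uniform(0, EXTENDED_MS, size=rng.poisson(
                spont_rate_hz * EXTENDED_MS / 1000.0)):
            amp = max(0.3, rng.normal(2.5, 1.0))
            raw += amp * _alpha_kernel(t_ms - t_ev, 10.0)
        w350, _ = normalize_window(raw[:WINDOW_MS], fs=1000.0)
        wext, _ = normalize_window(raw, fs=1000.0)
        windows[i] = w350
        windows_ext[i] = wext
    return WindowSet(windows, windows_ext, labels, tset, neuron_id, pattern.label)


# ---------------------------------------------------------------------------
# full raw-signal session
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One session: Vm trace, ECoG trace, stimulus event table, metadata."""

    vm: np.ndarray
    ecog: np.ndarray
    events: pd.DataFrame
    neuron_id: int
    fs_vm: float
    fs_ecog: float

    @property
    def duration_s(self) -> float:
        return self.vm.size / self.fs_vm


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-style testing."""

    type_labels: pd.DataFrame      # label, repetition, type_id (-1 == ungrouped)
    epsp_events: pd.DataFrame      # time_s, amplitude_mv, latency_ms, ttp_ms, channel, kind
    state_intervals: pd.DataFrame  # start_s, stop_s, state
    spike_times: np.ndarray
    template_sets: dict
    neuron_params: dict
    patterns: list


def _build_event_table(cfg: SessionConfig, patterns, rng) -> tuple[pd.DataFrame, float]:
    """Randomly interleave pattern presentations and single-pulse chunks."""
    trials: list[tuple[str, object]] = []
    for p in patterns:
        reps = cfg.reps_overrides.get(p.label, cfg.reps_per_pattern)
        trials += [("pattern", p)] * reps
    for ch in range(1, cfg.n_channels + 1):
        trials += [("chunk", ch)] * cfg.single_pulse_chunks_per_channel
    order = rng.permutation(len(trials))

    rows = []
    t = 1.0
    rep_count: dict[str, int] = {}
    sp_count: dict[int, int] = {}
    for idx in order:
        kind, obj = trials[idx]
        if kind == "pattern":
            p: StimulationPattern = obj
            rep = rep_count.get(p.label, 0)
            rep_count[p.label] = rep + 1
            rows.append((t, "pattern", p.label, 0, rep))
            t += p.duration_ms / 1000.0 + cfg.inter_trial_gap_s
        else:
            ch = obj
            for j in range(cfg.pulses_per_chunk):
                rep = sp_count.get(ch, 0)
                sp_count[ch] = rep + 1
                rows.append((t + j * cfg.chunk_ipi_s, "single", f"ch{ch}", ch, rep))
            t += (cfg.pulses_per_chunk - 1) * cfg.chunk_ipi_s + cfg.inter_trial_gap_s
    events = pd.DataFrame(rows, columns=["onset_s", "kind", "label", "channel", "repetition"])
    events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return events, t + 1.0


def _dwell_intervals(rng, total_s: float, mean_a: float, mean_b: float,
                     state_a: str, state_b: str) -> pd.DataFrame:
    """Alternating exponential dwell times tiling [0, total_s)."""
    rows = []
    t = 0.0
    state, mean = state_a, mean_a
    while t < total_s:
        dwell = rng.exponential(mean)
        rows.append((t, min(t + dwell, total_s), state))
        t += dwell
        state, mean = (state_b, mean_b) if state == state_a else (state_a, mean_a)
    return pd.DataFrame(rows, columns=["start_s", "stop_s", "state"])


def _stamp(trace: np.ndarray, start: int, kernel: np.ndarray) -> None:
    if start >= trace.size:
        return
    stop = min(start + kernel.size, trace.size)
    if start < 0:
        kernel = kernel[-start:]
        start = 0
    trace[start:stop] += kernel[: stop - start]


def simulate_session(config: SessionConfig | None = None) -> tuple[Recording, GroundTruth]:
    """Simulate one full session (Vm + ECoG + events) with ground truth."""
    cfg = config or SessionConfig()
    cfg.validate()
    seed = cfg.seed

    patterns = generate_patterns(cfg.n_patterns, cfg.n_channels, seed=seed)
    rng_tl = substream(seed, "timeline", cfg.neuron_id)
    events, total_s = _build_event_table(cfg, patterns, rng_tl)

    fs = cfg.vm_rate
    n = int(round(total_s * fs))
    t_axis = None  # not materialized; indices computed directly

    # --- Up/Down background -------------------------------------------------
    rng_bg = substream(seed, "background", cfg.neuron_id)
    updown = _dwell_intervals(rng_bg, total_s, cfg.up_dwell_mean_s, cfg.down_dwell_mean_s,
                              "up", "down")
    state_sig = np.zeros(n, dtype=float)
    for _, row in updown.iterrows():
        if row.state == "up":
            i0, i1 = int(row.start_s * fs), int(row.stop_s * fs)
            state_sig[i0:i1] = 1.0
    # smooth 20-ms state transitions
    state_sig = centered_moving_average(state_sig, int(0.02 * fs))

    # --- evoked responses ---------------------------------------------------
    rng_ev = substream(seed, "evoked", cfg.neuron_id)
    template_sets = {}
    k_per_pattern = {}
    for p in patterns:
        k = int(rng_ev.integers(cfg.k_types_min, cfg.k_types_max + 1))
        k_per_pattern[p.label] = k
        template_sets[p.label] = generate_type_templates(
            p, k, seed=int(rng_ev.integers(2**31)), separation=cfg.template_separation)

    evoked = np.zeros(n, dtype=float)
    suppression = np.zeros(n, dtype=float)
    truth_rows = []
    ext_n = int(EXTENDED_MS / 1000.0 * fs)
    t_hi = np.arange(ext_n) / fs * 1000.0
    t_lo = np.arange(EXTENDED_MS, dtype=float)
    env_decay = _activity_envelope(t_lo, 0.0, 400.0, 60.0)
    env_decay_hi = np.interp(t_hi, t_lo, env_decay)
    pat_events = events[events.kind == "pattern"]
    for _, row in pat_events.iterrows():
        tset = template_sets[row.label]
        if rng_ev.random() < cfg.ungrouped_fraction:
            type_id = UNGROUPED
            curve = tset.draw_ungrouped(rng_ev)
        else:
            type_id = int(rng_ev.integers(tset.k))
            curve = tset.templates[type_id]
        truth_rows.append((row.label, int(row.repetition), type_id))
        jitter = rng_ev.normal(0.0, cfg.within_type_noise_sd, size=EXTENDED_MS)
        curve = (curve + jitter) * _ONSET_RAMP
        curve_hi = np.interp(t_hi, t_lo, curve)
        i0 = int(row.onset_s * fs)
        _stamp(evoked, i0, cfg.evoked_gain_mv * rng_ev.normal(1.0, 0.03) * curve_hi)
        _stamp(suppression, i0, cfg.state_suppression * env_decay_hi)
    type_labels = pd.DataFrame(truth_rows, columns=["label", "repetition", "type_id"])
    np.clip(suppression, 0.0, 1.0, out=suppression)

    # --- EPSPs: single-pulse, in-pattern, spontaneous ----------------------
    rng_ep = substream(seed, "epsp", cfg.neuron_id)
    sp = cfg.single_pulse
    neuron_params = {ch: sp.draw_neuron(rng_ep) for ch in range(1, cfg.n_channels + 1)}
    # planted per-(pattern, pulse) modulation of in-pattern responses
    pulse_modulation = {
        p.label: np.exp(rng_ep.normal(0.0, 0.4, size=p.n_pulses)) for p in patterns
    }
    epsp_rows = []
    epsp_trace = np.zeros(n, dtype=float)
    kern_t = np.arange(int(0.12 * fs)) / fs * 1000.0  # 120-ms kernel support

    def add_epsp(t_pulse_s, ch, kind, amp_scale=1.0):
        ev = sp.draw_event(rng_ep, neuron_params[ch])
        amp = ev["amplitude_mv"] * amp_scale
        kern = amp * _alpha_kernel(kern_t - ev["latency_ms"], ev["ttp_ms"])
        _stamp(epsp_trace, int(t_pulse_s * fs), kern)
        epsp_rows.append((t_pulse_s, amp, ev["latency_ms"], ev["ttp_ms"], ch, kind))

    for _, row in events[events.kind == "single"].iterrows():
        add_epsp(row.onset_s, int(row.channel), "single")
    for _, row in pat_events.iterrows():
        p = next(q for q in patterns if q.label == row.label)
        mod = pulse_modulation[row.label]
        for j, (off, ch) in enumerate(p.pulses()):
            if rng_ep.random() < cfg.pulse_response_prob:
                add_epsp(row.onset_s + off / 1000.0, ch, "pattern", amp_scale=mod[j])
    # spontaneous EPSP shot noise
    n_spont = rng_ep.poisson(cfg.spont_epsp_rate_hz * total_s)
    for t_sp in np.sort(rng_ep.uniform(0, total_s, size=n_spont)):
        amp = max(0.3, rng_ep.normal(cfg.spont_epsp_amp_mv, cfg.spont_epsp_amp_sd_mv))
        kern = amp * _alpha_kernel(kern_t - 2.0, 10.0)
        _stamp(epsp_trace, int(t_sp * fs), kern)
        epsp_rows.append((t_sp, amp, 2.0, 10.0, 0, "spont"))
    epsp_events = pd.DataFrame(
        epsp_rows, columns=["time_s", "amplitude_mv", "latency_ms", "ttp_ms", "channel", "kind"]
    ).sort_values("time_s").reset_index(drop=True)

    # --- artifacts ----------------------------------------------------------
    artifact = np.zeros(n, dtype=float)
    half = max(int(0.0005 * fs), 1)
    art_kern = cfg.artifact_amp_mv * np.concatenate([np.ones(half), -np.ones(half)])
    pulse_times = []
    for _, row in events.iterrows():
        if row.kind == "single":
            pulse_times.append(row.onset_s)
        else:
            p = next(q for q in patterns if q.label == row.label)
            pulse_times += [row.onset_s + off / 1000.0 for off, _ in p.pulses()]
    pulse_times = np.sort(np.asarray(pulse_times))
    if cfg.artifact_amp_mv > 0:
        for tp in pulse_times:
            _stamp(artifact, int(tp * fs), art_kern)

    # --- spikes -------------------------------------------------------------
    rng_sp = substream(seed, "spikes", cfg.neuron_id)
    spike_times = np.array([])
    spikes_trace = np.zeros(n, dtype=float)
    if cfg.include_spikes and cfg.spike_rate_hz > 0:
        n_spikes = rng_sp.poisson(cfg.spike_rate_hz * total_s)
        spike_times = np.sort(rng_sp.uniform(0, total_s, size=n_spikes))
        st = np.arange(int(0.003 * fs)) / fs * 1000.0
        spike_kern = cfg.spike_amp_mv * np.where(
            st < 0.5, st / 0.5, np.exp(-(st - 0.5) / 0.8))
        for ts in spike_times:
            _stamp(spikes_trace, int(ts * fs), spike_kern)

    # --- noise and assembly -------------------------------------------------
    rng_noise = substream(seed, "noise", cfg.neuron_id)
    noise = ou_noise(rng_noise, n, fs, cfg.ou_sd_mv, cfg.ou_tau_s)
    noise += rng_noise.normal(0.0, cfg.white_sd_mv, size=n)
    background = cfg.down_level_mv + (cfg.up_level_mv - cfg.down_level_mv) \
        * state_sig * (1.0 - suppression)
    vm = (background + evoked + epsp_trace + artifact + spikes_trace + noise).astype(np.float32)

    # --- ECoG ---------------------------------------------------------------
    rng_ecog = substream(seed, "ecog", cfg.neuron_id)
    f_desync = cfg.desync_fraction
    desync_dwell = cfg.sync_dwell_mean_s * f_desync / max(1.0 - f_desync, 1e-9)
    states = _dwell_intervals(rng_ecog, total_s, cfg.sync_dwell_mean_s, desync_dwell,
                              "synchronized", "desynchronized")
    n_ecog = int(round(total_s * cfg.ecog_rate))
    ecog = np.zeros(n_ecog, dtype=float)
    if cfg.include_ecog:
        base = pink_noise(rng_ecog, n_ecog)
        tt = np.arange(n_ecog) / cfg.ecog_rate
        freq = 2.5 + 1.0 * np.sin(2 * np.pi * 0.05 * tt + rng_ecog.uniform(0, 2 * np.pi))
        slow = np.sin(2 * np.pi * np.cumsum(freq) / cfg.ecog_rate)
        mask = np.zeros(n_ecog)
        for _, row in states[states.state == "synchronized"].iterrows():
            i0, i1 = int(row.start_s * cfg.ecog_rate), int(row.stop_s * cfg.ecog_rate)
            mask[i0:i1] = 1.0
        mask = centered_moving_average(mask, int(0.2 * cfg.ecog_rate))
        ecog = (0.4 + 0.6 * mask) * base + 3.0 * mask * slow
    ecog = ecog.astype(np.float32)

    rec = Recording(vm=vm, ecog=ecog, events=events, neuron_id=cfg.neuron_id,
                    fs_vm=fs, fs_ecog=cfg.ecog_rate)
    truth = GroundTruth(type_labels=type_labels, epsp_events=epsp_events,
                        state_intervals=states, spike_times=spike_times,
                        template_sets=template_sets, neuron_params=neuron_params,
                        patterns=patterns)
    return rec, truth


# ---------------------------------------------------------------------------
# isolated single-pulse trials (short traces, for EPSP measurement loops)
# ---------------------------------------------------------------------------

def simulate_single_pulse_trials(
    n_trials: int = 100,
    seed: int = 0,
    params: SinglePulseParams | None = None,
    neuron: dict[str, float] | None = None,
    fs: float = 100_000.0,
    pre_s: float = 0.12,
    post_s: float = 0.06,
    noise_sd_mv: float = 0.3,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Short quiescent-baseline traces each containing one planted EPSP.

    Returns (traces, pulse_time_s, truth table).  If ``neuron`` is None, one
    neuron's per-channel means are drawn from the population distributions.
    """
    sp = params or SinglePulseParams()
    rng = substream(seed, "epsp", 1)
    if neuron is None:
        neuron = sp.draw_neuron(rng)
    n = int(round((pre_s + post_s) * fs))
    pulse_idx = int(pre_s * fs)
    kern_t = np.arange(n - pulse_idx) / fs * 1000.0
    traces = np.empty((n_trials, n), dtype=float)
    rows = []
    for i in range(n_trials):
        ev = sp.draw_event(rng, neuron)
        trace = -70.0 + ou_noise(rng, n, fs, noise_sd_mv, 0.015) \
            + rng.normal(0.0, 0.08, size=n)
        trace[pulse_idx:] += ev["amplitude_mv"] * _alpha_kernel(
            kern_t - ev["latency_ms"], ev["ttp_ms"])
        traces[i] = trace
        rows.append((ev["amplitude_mv"], ev["latency_ms"], ev["ttp_ms"]))
    truth = pd.DataFrame(rows, columns=["amplitude_mv", "latency_ms", "ttp_ms"])
    return traces, pre_s, truth
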