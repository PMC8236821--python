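"""Raw-trace conditioning: QC, smoothing, artifact blanking, spike removal,
window extraction and normalization.

The normalization pipeline mirrors the published post-processing order:
1-ms moving average, resampling to 1 kHz, subtraction of a centered 100-ms
moving average (offset removal), then per-window min-max scaling to [0, 1]
based on the highest peak and deepest trough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from ._utils import centered_moving_average, merge_intervals

NORM_EPS = 1e-9


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Recording-inclusion criteria: Down-state mode < -55 mV, spike
    amplitude > 25 mV when spikes are present, Up-Down peak-to-peak > 10 mV."""

    down_state_mode: float
    up_state_mode: float
    up_down_peak_to_peak: float
    spike_amplitude: float | None
    unimodal: bool
    passes: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.passes.values())


def _vm_modes(vm: np.ndarray) -> tuple[float, float, bool]:
    """Lower and upper mode of the Vm amplitude histogram (0.25-mV bins)."""
    lo, hi = np.percentile(vm, [0.5, 99.5])
    edges = np.arange(lo, hi + 0.25, 0.25)
    if edges.size < 4:
        med = float(np.median(vm))
        return med, med, True
    counts, edges = np.histogram(vm, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), 3.0)
    peaks, props = find_peaks(smooth, prominence=0.03 * smooth.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    if peaks.size == 0:
        idx = int(np.argmax(smooth))
        return float(centers[idx]), float(centers[idx]), True
    if peaks.size == 1:
        return float(centers[peaks[0]]), float(centers[peaks[0]]), True
    # keep the two most prominent peaks; lower is Down, upper is Up
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo_pk, hi_pk = sorted(centers[top2])
    return float(lo_pk), float(hi_pk), False


def qc_check(vm: np.ndarray, fs: float) -> QCReport:
    """Evaluate the inclusion criteria on a membrane-potential trace.

    For unimodal amplitude distributions the peak-to-peak criterion falls
    back to the 5th-95th percentile span (noted via ``unimodal``).
    """
    vm = np.asarray(vm, dtype=float)
    if vm.size == 0:
        raise ValueError("vm is empty")
    down_mode, up_mode, unimodal = _vm_modes(vm)
    if unimodal:
        p5, p95 = np.percentile(vm, [5, 95])
        p2p = float(p95 - p5)
    else:
        p2p = up_mode - down_mode
    spike_idx = detect_spikes(vm, fs)
    spike_amp = None
    if spike_idx.size:
        heights = []
        w = max(int(0.003 * fs), 2)
        for i in spike_idx:
            seg = vm[i: i + w]
            base = vm[max(i - int(0.001 * fs), 0): i + 1]
            if seg.size and base.size:
                heights.append(seg.max() - np.median(base))
        spike_amp = float(np.median(heights)) if heights else None
    passes = {
        "down_state": down_mode < -55.0,
        "spike_amplitude": (spike_amp is None) or (spike_amp > 25.0),
        "up_down_p2p": p2p > 10.0,
    }
    return QCReport(down_mode, up_mode, p2p, spike_amp, unimodal, passes)


# ---------------------------------------------------------------------------
# trace conditioning
# ---------------------------------------------------------------------------

def smooth_trace(vm: np.ndarray, fs: float) -> np.ndarray:
    """50-us centered moving average (5 samples at 100 kHz)."""
    window = max(int(round(50e-6 * fs)), 1)
    return centered_moving_average(np.asarray(vm, dtype=float), window)


def blank_artifacts(
    vm: np.ndarray, pulse_times_s: np.ndarray, fs: float, blank_ms: float = 1.0,
    pre_ms: float = 0.1,
) -> np.ndarray:
    """Replace [t - pre_ms, t + blank_ms) around each pulse by linear
    interpolation.

    The small pre-margin absorbs artifact energy smeared backwards by the
    50-us smoothing.  Overlapping blank windows are merged before
    interpolation.
    """
    vm = np.asarray(vm, dtype=float).copy()
    n = vm.size
    spans = []
    for t in np.atleast_1d(pulse_times_s):
        i0 = int(round((t - pre_ms / 1000.0) * fs))
        i1 = int(round(t * fs)) + int(round(blank_ms / 1000.0 * fs))
        if i0 >= n or i1 <= 0:
            continue
        spans.append((max(i0, 0), min(i1, n)))
    for i0, i1 in merge_intervals(spans):
        i0, i1 = int(i0), int(i1)
        left = vm[i0 - 1] if i0 > 0 else vm[i1 - 1] if i1 <= n else vm[0]
        right = vm[i1] if i1 < n else left
        vm[i0:i1] = np.linspace(left, right, i1 - i0 + 2)[1:-1]
    return vm


# ---------------------------------------------------------------------------
# spike removal
# ---------------------------------------------------------------------------

def slope_mv_per_ms(vm: np.ndarray, fs: float, span_ms: float = 0.2) -> np.ndarray:
    """Forward-difference slope over ``span_ms``, in mV/ms.

    Computing the slope over a finite span (rather than adjacent samples)
    keeps sample-to-sample noise from dominating at high sampling rates.
    """
    vm = np.asarray(vm, dtype=float)
    k = max(int(round(span_ms / 1000.0 * fs)), 1)
    dv = np.empty_like(vm)
    dv[:-k] = (vm[k:] - vm[:-k]) / (k / fs * 1000.0)
    dv[-k:] = dv[-k - 1] if vm.size > k else 0.0
    return dv


def detect_spikes(vm: np.ndarray, fs: float, slope_thresh_mv_per_ms: float = 35.0,
                  min_height_mv: float = 15.0) -> np.ndarray:
    """Onset indices of fast upward transients (candidate spikes).

    Spikes rise an order of magnitude faster than synaptic events (tens of
    mV within ~0.5 ms), so a steep slope threshold separates them from even
    the sharpest evoked-response transitions.
    """
    vm = np.asarray(vm, dtype=float)
    w = max(int(round(0.5e-3 * fs)), 1)
    sm = centered_moving_average(vm, w)
    dv = slope_mv_per_ms(sm, fs, 0.2)
    above = dv > slope_thresh_mv_per_ms
    if not above.any():
        return np.array([], dtype=int)
    idx = np.flatnonzero(above)
    # group threshold crossings closer than 5 ms, keep the first of each group
    gap = int(0.005 * fs)
    starts = [idx[0]]
    for i in idx[1:]:
        if i - starts[-1] > gap:
            starts.append(i)
    starts = np.asarray(starts)
    # require the excursion to actually reach min_height above the local base
    keep = []
    w_post = int(0.003 * fs)
    for i in starts:
        base = sm[max(i - int(0.001 * fs), 0): i + 1].min()
        if sm[i: i + w_post].max() - base >= min_height_mv:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def remove_spikes(
    vm: np.ndarray, fs: float, tol: float = 1e-4, max_iter: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract a recursively fitted generic spike shape at each occurrence.

    A generic waveform is estimated by iterative align-and-average over the
    detections (re-aligning each snippet to the current average by cross-
    correlation) until the average stabilizes, then subtracted at every
    occurrence.  With fewer than three detections the spikes are reported
    but left in place.
    """
    vm = np.asarray(vm, dtype=float)
    onsets = detect_spikes(vm, fs)
    times = onsets / fs
    if onsets.size < 3:
        return vm.copy(), times

    pre = int(0.001 * fs)
    post = int(0.005 * fs)
    length = pre + post
    max_lag = int(0.0005 * fs)

    def snippet(i, lag=0):
        a = i - pre + lag
        if a < 0 or a + length > vm.size:
            return None
        seg = vm[a: a + length].copy()
        return seg - seg[0]

    snips = [s for i in onsets if (s := snippet(i)) is not None]
    if len(snips) < 3:
        return vm.copy(), times
    template = np.mean(snips, axis=0)
    lags = np.zeros(len(onsets), dtype=int)
    for _ in range(max_iter):
        new_snips = []
        for j, i in enumerate(onsets):
            best, best_val = lags[j], -np.inf
            for lag in range(-max_lag, max_lag + 1):
                s = snippet(i, lag)
                if s is None:
                    continue
                val = float(np.dot(s, template))
                if val > best_val:
                    best_val, best = val, lag
            lags[j] = best
        new_snips = [s for j, i in enumerate(onsets)
                     if (s := snippet(i, lags[j])) is not None]
        new_template = np.mean(new_snips, axis=0)
        change = np.max(np.abs(new_template - template)) / max(np.max(np.abs(new_template)), 1e-12)
        template = new_template
        if change < tol:
            break
    cleaned = vm.copy()
    for j, i in enumerate(onsets):
        a = i - pre + lags[j]
        if a < 0 or a + length > vm.size:
            continue
        cleaned[a: a + length] -= template
    return cleaned, times


# ---------------------------------------------------------------------------
# window extraction and normalization
# ---------------------------------------------------------------------------

def extract_windows(
    vm: np.ndarray,
    fs: float,
    events: pd.DataFrame,
    duration_ms: float = 350.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-repetition raw segments aligned to pattern onset, [onset, onset+D).

    Windows truncated by the end of the recording are dropped (listed in the
    returned metadata under ``dropped``).  Returns (windows, meta) where
    ``meta`` has columns label, repetition, onset_s.
    """
    vm = np.asarray(vm)
    n_samp = int(round(duration_ms / 1000.0 * fs))
    rows, wins = [], []
    pat = events[events.kind == "pattern"] if "kind" in events.columns else events
    for _, row in pat.iterrows():
        i0 = int(round(row.onset_s * fs))
        if i0 + n_samp > vm.size or i0 < 0:
            continue
        wins.append(vm[i0: i0 + n_samp])
        rows.append((row.label, int(row.repetition), float(row.onset_s)))
    meta = pd.DataFrame(rows, columns=["label", "repetition", "onset_s"])
    windows = np.asarray(wins, dtype=float) if wins else np.empty((0, n_samp))
    return windows, meta


def normalize_window(raw: np.ndarray, fs: float) -> tuple[np.ndarray, bool]:
    """Normalize one raw window: 1-ms average, resample to 1 kHz, subtract a
    centered 100-ms moving average, min-max scale to [0, 1].

    Returns (normalized, degenerate).  A flat window (range < 1e-9 after
    offset removal) is flagged degenerate and filled with 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    step = int(round(fs / 1000.0))
    if step < 1:
        raise ValueError("window must be sampled at >= 1 kHz")
    w1 = max(int(round(0.001 * fs)), 1)
    sm = centered_moving_average(raw, w1)
    resampled = sm[::step]
    offset = centered_moving_average(resampled, 100)
    centered = resampled - offset
    lo, hi = centered.min(), centered.max()
    if hi - lo < NORM_EPS:
        return np.full(centered.size, 0.5), True
    return (centered - lo) / (hi - lo), False


def normalize_windows(raw_windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized convenience over ``normalize_window``."""
    out = []
    degen = []
    for w in raw_windows:
        nw, d = normalize_window(w, fs)
        out.append(nw)
        degen.append(d)
    return np.asarray(out), np.asarray(degen, dtype=bool)
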