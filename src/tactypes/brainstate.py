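"""ECoG brain-state segmentation and response-type/state association.

The surface ECoG is segmented into 1000-ms windows with 125-ms overlap
(hop = 875 ms); per segment the mean-detrended periodogram is summed over
the delta/theta/alpha bands (0-12 Hz).  Segments whose compound power drops
below the recording's median for at least two segments in a row are
desynchronized; everything else is synchronized.  Ties at the median count
as synchronized (the rule is a strict "dropped below").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from scipy.stats import ttest_rel

from .clustering import ResponseTypeResults

SYNCHRONIZED = "synchronized"
DESYNCHRONIZED = "desynchronized"


@dataclass
class EcogStateTrack:
    start_s: np.ndarray
    power: np.ndarray           # compound 0-12 Hz spectral density per segment
    median_power: float
    desynchronized: np.ndarray  # boolean per segment (run-filtered)
    segment_s: float
    hop_s: float

    @property
    def states(self) -> np.ndarray:
        return np.where(self.desynchronized, DESYNCHRONIZED, SYNCHRONIZED)

    @property
    def desync_fraction(self) -> float:
        return float(self.desynchronized.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment_start_s": self.start_s,
            "power": self.power,
            "state": self.states,
        })


def segment_ecog(
    ecog: np.ndarray,
    fs: float = 1000.0,
    segment_s: float = 1.0,
    hop_s: float = 0.875,
    band_hz: tuple[float, float] = (0.0, 12.0),
) -> EcogStateTrack:
    """Segment the ECoG into synchronized/desynchronized states."""
    ecog = np.asarray(ecog, dtype=float)
    n_seg_samp = int(round(segment_s * fs))
    hop = int(round(hop_s * fs))
    if ecog.size < n_seg_samp + hop:
        raise ValueError("ECoG shorter than two segments")
    starts = np.arange(0, ecog.size - n_seg_samp + 1, hop)
    power = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = ecog[s: s + n_seg_samp]
        f, pxx = periodogram(seg, fs=fs, detrend="constant")
        sel = (f > band_hz[0]) & (f <= band_hz[1])
        power[i] = float(pxx[sel].sum())
    median = float(np.median(power))
    below = power < median  # strictly below; median ties stay synchronized
    desync = run_filter(below, min_run=2)
    return EcogStateTrack(starts / fs, power, median, desync, segment_s, hop_s)


def run_filter(below: np.ndarray, min_run: int = 2) -> np.ndarray:
    """Keep only runs of at least ``min_run`` consecutive True segments."""
    below = np.asarray(below, dtype=bool)
    out = np.zeros_like(below)
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j < below.size and below[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def state_at_times(track: EcogStateTrack, times_s: np.ndarray) -> np.ndarray:
    """State of the latest segment starting at or before each time."""
    times = np.atleast_1d(np.asarray(times_s, dtype=float))
    idx = np.searchsorted(track.start_s, times, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("times before the first segment")
    idx = np.clip(idx, 0, track.start_s.size - 1)
    return track.desynchronized[idx]


@dataclass
class StateAssociation:
    """Paired comparison of per-type vs per-cell desynchronized fractions."""

    table: pd.DataFrame
    p_all: float
    p_large: float              # restricted to types with > 9 members
    n_pairs: int
    n_pairs_large: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "comparison": ["all types", "types with > 9 members"],
            "n_pairs": [self.n_pairs, self.n_pairs_large],
            "paired_t_p": [self.p_all, self.p_large],
        })


def type_state_association(
    cells: list[tuple[ResponseTypeResults, np.ndarray]],
    large_min_members: int = 10,
) -> StateAssociation:
    """Do response types preferentially occur in one ECoG state?

    ``cells`` holds, per (neuron, pattern), the clustering result and the
    boolean desynchronized flag at each presentation onset.  Each type
    contributes one pair (its desynchronized fraction, its own cell's
    overall fraction); the two-sided paired t-test is run over all pairs and
    again restricted to types with more than nine members.
    """
    rows = []
    for ts, desync in cells:
        desync = np.asarray(desync, dtype=bool)
        if desync.size != ts.n_windows:
            raise ValueError("onset states and typeset disagree in length")
        cell_frac = float(desync.mean())
        for k in range(ts.n_types):
            idx = ts.members(k)
            rows.append((ts.neuron_id, ts.pattern_label, k, idx.size,
                         float(desync[idx].mean()), cell_frac))
    table = pd.DataFrame(rows, columns=[
        "neuron", "pattern", "type", "n_members", "type_fraction", "cell_fraction"])
    if len(table) < 2:
        raise ValueError("need at least two (type, cell) pairs")

    def paired_p(df: pd.DataFrame) -> tuple[float, int]:
        if len(df) < 2 or np.allclose(df.type_fraction, df.cell_fraction):
            return np.nan, len(df)
        stat = ttest_rel(df.type_fraction, df.cell_fraction)
        return float(stat.pvalue), len(df)

    p_all, n_all = paired_p(table)
    large = table[table.n_members >= large_min_members]
    p_large, n_large = paired_p(large)
    return StateAssociation(table, p_all, p_large, n_all, n_large)
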