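"""Spatiotemporal stimulation patterns.

Each pattern is an ordered train of brief intracutaneous pulses over up to
four skin channels, lasting less than 340 ms.  Eight such patterns (labels
F/S x {5, 10, 20, inf}) are used per session; individual patterns carry 5-33
pulses with inter-pulse intervals in the 1-123 ms span.  The published pulse
times are not available, so patterns are generated statistically under those
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import substream

PATTERN_LABELS = ("F5", "S5", "F10", "S10", "F20", "S20", "Finf", "Sinf")

MIN_PULSES = 5
MAX_PULSES = 33
MAX_DURATION_MS = 340.0
MIN_IPI_MS = 1.0
MAX_IPI_MS = 123.0


@dataclass(frozen=True)
class StimulationPattern:
    """One labeled spatiotemporal input: (offset_ms, channel) pulse pairs."""

    label: str
    offsets_ms: tuple[float, ...]
    channels: tuple[int, ...]

    def __post_init__(self):
        n = len(self.offsets_ms)
        if n != len(self.channels):
            raise ValueError("offsets and channels must have equal length")
        if not (MIN_PULSES <= n <= MAX_PULSES):
            raise ValueError(f"pattern {self.label}: pulse count {n} outside [5, 33]")
        off = np.asarray(self.offsets_ms)
        if np.any(np.diff(off) < 0):
            raise ValueError("pulse offsets must be nondecreasing")
        if off[-1] >= MAX_DURATION_MS:
            raise ValueError("last pulse offset must be < 340 ms")
        ipi = np.diff(off)
        if ipi.size and (ipi.min() < MIN_IPI_MS - 1e-9 or ipi.max() > MAX_IPI_MS + 1e-9):
            raise ValueError("inter-pulse intervals must lie within 1-123 ms")
        if any(c < 1 for c in self.channels):
            raise ValueError("channels are 1-based positive integers")

    @property
    def n_pulses(self) -> int:
        return len(self.offsets_ms)

    @property
    def duration_ms(self) -> float:
        return float(self.offsets_ms[-1])

    def pulses(self) -> list[tuple[float, int]]:
        return list(zip(self.offsets_ms, self.channels))


def _draw_counts(rng: np.random.Generator, n_patterns: int, total: int) -> np.ndarray:
    """Per-pattern pulse counts in [5, 33] summing to ``total`` (rejection)."""
    lo, hi = n_patterns * MIN_PULSES, n_patterns * MAX_PULSES
    if not (lo <= total <= hi):
        raise ValueError(f"total pulse count {total} unattainable with {n_patterns} patterns")
    for _ in range(20000):
        counts = rng.integers(MIN_PULSES, MAX_PULSES + 1, size=n_patterns)
        diff = total - counts.sum()
        # nudge random entries toward the target instead of rejecting outright
        for _ in range(200):
            if diff == 0:
                break
            i = rng.integers(n_patterns)
            step = int(np.sign(diff))
            if MIN_PULSES <= counts[i] + step <= MAX_PULSES:
                counts[i] += step
                diff -= step
        if diff == 0:
            return counts
    raise RuntimeError("could not allocate pulse counts")


def _draw_offsets(rng: np.random.Generator, n_pulses: int) -> np.ndarray:
    """Log-uniform IPIs on [1, 123] ms, rescaled to keep the train < 340 ms."""
    if n_pulses == 1:
        return np.zeros(1)
    ipi = np.exp(rng.uniform(np.log(MIN_IPI_MS), np.log(MAX_IPI_MS), size=n_pulses - 1))
    limit = MAX_DURATION_MS - 1.0
    # shrink the free (>1 ms) intervals until the train fits; intervals pinned
    # at the 1-ms floor keep their value
    for _ in range(100):
        total = ipi.sum()
        if total <= limit:
            break
        free = ipi > MIN_IPI_MS
        if not free.any():
            raise RuntimeError("pulse train does not fit below 340 ms")
        budget = limit - ipi[~free].sum()
        if budget <= 0:
            raise RuntimeError("pulse train does not fit below 340 ms")
        ipi[free] = np.clip(ipi[free] * budget / ipi[free].sum(), MIN_IPI_MS, MAX_IPI_MS)
    offsets = np.concatenate(([0.0], np.cumsum(ipi)))
    if offsets[-1] >= MAX_DURATION_MS:
        raise RuntimeError("pulse train does not fit below 340 ms")
    return offsets


def generate_patterns(
    n_patterns: int = 8,
    n_channels: int = 4,
    seed: int = 0,
    total_pulses: int | None = None,
) -> list[StimulationPattern]:
    """Generate labeled stimulation patterns under the published constraints.

    With the default eight patterns the total pulse count defaults to 152.
    For other pattern counts the default total scales as 19 pulses/pattern.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if total_pulses is None:
        total_pulses = 152 if n_patterns == 8 else 19 * n_patterns
    rng = substream(seed, "patterns")
    labels = [PATTERN_LABELS[i] if i < len(PATTERN_LABELS) else f"P{i}" for i in range(n_patterns)]
    for _ in range(100):
        counts = _draw_counts(rng, n_patterns, total_pulses)
        patterns = []
        for label, count in zip(labels, counts):
            offsets = _draw_offsets(rng, int(count))
            channels = tuple(int(c) for c in rng.integers(1, n_channels + 1, size=int(count)))
            patterns.append(StimulationPattern(label, tuple(map(float, offsets)), channels))
        # the within-pattern pulse analysis needs some temporally isolated pulses
        if any(_n_isolated(p) > 0 for p in patterns):
            return patterns
    raise RuntimeError("failed to generate patterns with isolated pulses")


def _n_isolated(pattern: StimulationPattern, min_sep_ms: float = 10.0) -> int:
    off = np.asarray(pattern.offsets_ms)
    gaps_prev = np.concatenate(([np.inf], np.diff(off)))
    gaps_next = np.concatenate((np.diff(off), [np.inf]))
    return int(np.sum((gaps_prev >= min_sep_ms) & (gaps_next >= min_sep_ms)))
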