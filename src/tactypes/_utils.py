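"""Shared numeric helpers: shrinking-window moving averages and seeded sub-streams."""

from __future__ import annotations

import numpy as np

# Fixed tags so each simulator component draws from its own reproducible stream.
_STREAM_TAGS = {
    "patterns": 11,
    "templates": 12,
    "timeline": 13,
    "background": 14,
    "evoked": 15,
    "epsp": 16,
    "ecog": 17,
    "spikes": 18,
    "noise": 19,
    "misc": 20,
}


def substream(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Independent generator for one simulator component.

    Keyed on (seed, component tag, extra) so partial reconfiguration of one
    component does not perturb the draws of the others.
    """
    tag = _STREAM_TAGS.get(name)
    if tag is None:
        raise KeyError(f"unknown stream name: {name!r}")
    return np.random.default_rng([int(seed), tag, int(extra)])


def centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered boxcar average with shrinking (partial) windows at the edges.

    Output length equals input length; interior samples average exactly
    ``window`` points, edge samples average the points that exist.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window <= 1 or n == 0:
        return x.copy()
    left = (window - 1) // 2
    right = window - 1 - left
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching [start, stop) intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for start, stop in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [(a, b) for a, b in merged]


def ou_noise(rng: np.random.Generator, n: int, fs: float, sd: float, tau_s: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck (one-pole low-pass) noise.

    sd is the stationary standard deviation; tau_s the correlation time.
    Used as a stand-in for the slow membrane-potential fluctuations that ride
    on top of the Up/Down background.
    """
    from scipy.signal import lfilter

    if n == 0:
        return np.zeros(0)
    a = np.exp(-1.0 / (fs * tau_s))
    w = rng.standard_normal(n)
    x = lfilter([np.sqrt(1.0 - a * a)], [1.0, -a], w)
    # start from stationary distribution
    x[0] = rng.standard_normal()
    return sd * x


def pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance approximately 1/f noise via spectral shaping."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x / s if s > 0 else x
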