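"""Response-type clustering of normalized evoked windows.

The similarity rule is a per-sample hinge: two 350-sample curves are "the
same response type" when the mean over samples of max(0, |a_t - b_t| - D)
falls below O, with D = 0.13 and O = 0.08 normalized units by default.
Types are extracted greedily: every remaining window defines a candidate
group (itself plus its direct matches); the largest group is removed as a
type, and the sweep repeats until nothing is left.  Types with fewer than
five members dissolve into "ungrouped".

The core is exposed as a model/results pair: ``ResponseTypeModel(windows,
params).fit()`` returns a ``ResponseTypeResults`` carrying the partition,
per-type mean curves, and a summary table.  ``sensitivity_grid`` and
``cluster_agreement`` explore the (D, O) parameter plane and the membership
consistency between neighboring grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNGROUPED = -1


@dataclass(frozen=True)
class ClusterParams:
    threshold_diff: float = 0.13   # per-sample tolerance, normalized units
    overshoot_thresh: float = 0.08  # mean-overshoot criterion, normalized units
    min_members: int = 5

    def __post_init__(self):
        if self.threshold_diff <= 0 or self.overshoot_thresh <= 0 or self.min_members <= 0:
            raise ValueError("all clustering parameters must be positive")


def pair_same_type(a: np.ndarray, b: np.ndarray,
                   params: ClusterParams | None = None) -> tuple[bool, float]:
    """Hinge similarity of two equal-length normalized curves.

    Returns (same, mean_overshoot); symmetric in its arguments.
    """
    params = params or ClusterParams()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have equal length")
    overshoot = np.maximum(np.abs(a - b) - params.threshold_diff, 0.0)
    mean_overshoot = float(overshoot.mean())
    return mean_overshoot < params.overshoot_thresh, mean_overshoot


def overshoot_matrix(windows: np.ndarray, threshold_diff: float) -> np.ndarray:
    """All-pairs mean hinge overshoot, vectorized."""
    x = np.asarray(windows, dtype=float)
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        out[i] = np.maximum(d - threshold_diff, 0.0).mean(axis=1)
    return out


@dataclass
class ResponseTypeResults:
    """Partition of one cell's repetitions into response types.

    ``labels[i]`` is the type id of repetition i (ids in extraction order,
    0 = largest) or UNGROUPED (-1).
    """

    labels: np.ndarray
    params: ClusterParams
    windows: np.ndarray | None = None
    neuron_id: int = 0
    pattern_label: str = ""

    @property
    def n_types(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    @property
    def n_windows(self) -> int:
        return int(self.labels.size)

    @property
    def ungrouped_fraction(self) -> float:
        return float(np.mean(self.labels == UNGROUPED)) if self.labels.size else 0.0

    def members(self, type_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == type_id)

    def clusters(self) -> list[np.ndarray]:
        """Member-index sets of the non-ungrouped types, in id order."""
        return [self.members(k) for k in range(self.n_types)]

    def type_means(self) -> np.ndarray:
        if self.windows is None:
            raise ValueError("results were built without windows")
        return np.stack([self.windows[self.members(k)].mean(axis=0)
                         for k in range(self.n_types)]) \
            if self.n_types else np.empty((0, self.windows.shape[1]))

    def summary(self) -> pd.DataFrame:
        rows = [(k, self.members(k).size,
                 self.members(k).size / max(self.n_windows, 1))
                for k in range(self.n_types)]
        rows.append(("ungrouped", int(np.sum(self.labels == UNGROUPED)),
                     self.ungrouped_fraction))
        return pd.DataFrame(rows, columns=["type", "n_members", "fraction"])


class ResponseTypeModel:
    """Greedy leader-extraction clustering of one (neuron, pattern) cell.

    Parameters
    ----------
    windows : (n, 350) array of normalized response curves.
    params : ClusterParams, thresholds of the similarity rule.
    degenerate : optional boolean mask; flagged windows never cluster and are
        forced to UNGROUPED.
    """

    def __init__(self, windows: np.ndarray, params: ClusterParams | None = None,
                 degenerate: np.ndarray | None = None,
                 neuron_id: int = 0, pattern_label: str = ""):
        self.windows = np.asarray(windows, dtype=float)
        if self.windows.ndim != 2 or self.windows.shape[0] < 1:
            raise ValueError("windows must be a nonempty (n, T) array")
        self.params = params or ClusterParams()
        self.degenerate = (np.zeros(self.windows.shape[0], dtype=bool)
                           if degenerate is None else np.asarray(degenerate, dtype=bool))
        self.neuron_id = neuron_id
        self.pattern_label = pattern_label

    def fit(self) -> ResponseTypeResults:
        n = self.windows.shape[0]
        labels = np.full(n, UNGROUPED, dtype=int)
        valid = ~self.degenerate
        if valid.sum() == 0:
            return ResponseTypeResults(labels, self.params, self.windows,
                                       self.neuron_id, self.pattern_label)
        over = overshoot_matrix(self.windows, self.params.threshold_diff)
        same = over < self.params.overshoot_thresh
        same[~valid, :] = False
        same[:, ~valid] = False
        np.fill_diagonal(same, True)
        same &= valid[:, None] & valid[None, :]

        remaining = valid.copy()
        groups: list[np.ndarray] = []
        while remaining.any():
            counts = (same & remaining[None, :]).sum(axis=1)
            counts[~remaining] = -1
            leader = int(np.argmax(counts))  # argmax ties -> lowest index
            group = np.flatnonzero(same[leader] & remaining)
            groups.append(group)
            remaining[group] = False
        # dissolve small types; ids in extraction order among survivors
        next_id = 0
        for group in groups:
            if group.size >= self.params.min_members:
                labels[group] = next_id
                next_id += 1
        return ResponseTypeResults(labels, self.params, self.windows,
                                   self.neuron_id, self.pattern_label)


def cluster_responses(windows: np.ndarray, params: ClusterParams | None = None,
                      degenerate: np.ndarray | None = None,
                      neuron_id: int = 0, pattern_label: str = "") -> ResponseTypeResults:
    """Functional wrapper around ``ResponseTypeModel(...).fit()``."""
    return ResponseTypeModel(windows, params, degenerate, neuron_id, pattern_label).fit()


# ---------------------------------------------------------------------------
# sensitivity analysis over the (threshold, overshoot) plane
# ---------------------------------------------------------------------------

@dataclass
class SensitivityGrid:
    threshold_values: np.ndarray
    overshoot_values: np.ndarray
    n_types: np.ndarray            # (nt, no)
    proportion_ungrouped: np.ndarray
    proportion_grouped: np.ndarray  # n_types / max over grid
    mean_agreement: np.ndarray
    max_agreement: np.ndarray
    typesets: list                 # nested [i][j] -> ResponseTypeResults


def sensitivity_grid(windows: np.ndarray,
                     threshold_values, overshoot_values,
                     min_members: int = 5,
                     degenerate: np.ndarray | None = None) -> SensitivityGrid:
    """Re-cluster one cell at every (threshold, overshoot) grid point."""
    tvals = np.atleast_1d(np.asarray(threshold_values, dtype=float))
    ovals = np.atleast_1d(np.asarray(overshoot_values, dtype=float))
    if tvals.size == 0 or ovals.size == 0:
        raise ValueError("grid axes must be nonempty")
    nt, no = tvals.size, ovals.size
    n_types = np.zeros((nt, no), dtype=int)
    prop_un = np.zeros((nt, no))
    typesets = [[None] * no for _ in range(nt)]
    for i, tv in enumerate(tvals):
        for j, ov in enumerate(ovals):
            res = cluster_responses(
                windows, ClusterParams(tv, ov, min_members), degenerate)
            typesets[i][j] = res
            n_types[i, j] = res.n_types
            prop_un[i, j] = res.ungrouped_fraction
    max_types = max(n_types.max(), 1)
    prop_grouped = n_types / max_types
    if nt >= 2 and no >= 2:
        mean_ag, max_ag = cluster_agreement(typesets)
    else:
        mean_ag = np.full((nt, no), np.nan)
        max_ag = np.full((nt, no), np.nan)
    return SensitivityGrid(tvals, ovals, n_types, prop_un, prop_grouped,
                           mean_ag, max_ag, typesets)


def agreement_between(center_clusters: list, neighbor_clusters: list) -> tuple[float, float]:
    """One directed comparison between two clusterings.

    For each cluster of the center, the agreement is the largest proportion
    of its members contained in a single cluster of the neighbor.  Returns
    (mean over center clusters, best over center clusters).
    """
    if not center_clusters:
        return np.nan, np.nan
    per_cluster = []
    for k in center_clusters:
        kset = set(np.asarray(k).tolist())
        if not kset:
            continue
        best = 0.0
        for d in neighbor_clusters:
            ov = len(kset.intersection(np.asarray(d).tolist())) / len(kset)
            best = max(best, ov)
        per_cluster.append(best)
    if not per_cluster:
        return np.nan, np.nan
    return float(np.mean(per_cluster)), float(np.max(per_cluster))


def cluster_agreement(typesets: list) -> tuple[np.ndarray, np.ndarray]:
    """Membership consistency between 8-neighboring parameter-grid cells.

    For each grid cell, every available neighbor contributes one directed
    comparison (``agreement_between`` with the cell as center).  The mean
    map averages the comparisons' mean per-cluster values, the max map the
    comparisons' best per-cluster values.  Ungrouped responses are excluded
    on both sides; neighbors with zero types contribute no comparison.
    """
    nt = len(typesets)
    no = len(typesets[0])
    if nt < 2 or no < 2:
        raise ValueError("agreement needs a grid of at least 2x2")
    mean_map = np.full((nt, no), np.nan)
    max_map = np.full((nt, no), np.nan)
    for i in range(nt):
        for j in range(no):
            center = typesets[i][j].clusters()
            if not center:
                continue
            means, bests = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if not (0 <= a < nt and 0 <= b < no):
                        continue
                    neighbor = typesets[a][b].clusters()
                    if not neighbor:
                        continue
                    m, mx = agreement_between(center, neighbor)
                    if np.isfinite(m):
                        means.append(m)
                        bests.append(mx)
            if means:
                mean_map[i, j] = float(np.mean(means))
                max_map[i, j] = float(np.mean(bests))
    return mean_map, max_map
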