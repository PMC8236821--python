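"""Per-timepoint Kruskal-Wallis specificity of response types.

For each response type of a (neuron, pattern) cell, the members' normalized
amplitudes at every 1-ms sample over 0-1200 ms are compared against all
other responses of the same cell (two-group Kruskal-Wallis with tie
correction).  The headline summaries are the fraction of types significant
at alpha per timepoint and the label-shuffle null of that fraction, which
doubles as the multiple-comparisons control.

Ranks are computed once per cell and reused across types and label shuffles,
which makes large shuffle counts cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, rankdata

from .clustering import UNGROUPED, ResponseTypeResults


@dataclass
class KwTimecourse:
    """p/H time curves for the valid types of one (neuron, pattern) cell."""

    p: np.ndarray        # (n_valid_types, T)
    h: np.ndarray
    type_ids: np.ndarray
    alpha: float = 0.05

    @property
    def n_types(self) -> int:
        return int(self.type_ids.size)


class _CellRanks:
    """Columnwise ranks and tie terms of one cell's window matrix."""

    def __init__(self, windows: np.ndarray):
        data = np.asarray(windows, dtype=float)
        self.n, self.T = data.shape
        self.ranks = rankdata(data, axis=0)
        self.tie_term = np.zeros(self.T)
        for t in range(self.T):
            col = np.sort(data[:, t])
            # run lengths of tied values
            change = np.concatenate(([True], np.diff(col) != 0))
            counts = np.diff(np.concatenate((np.flatnonzero(change), [self.n])))
            self.tie_term[t] = float(np.sum(counts**3 - counts))

    def two_group(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized two-group Kruskal-Wallis across all timepoints."""
        n1 = int(mask.sum())
        n2 = self.n - n1
        if n1 < 2 or n2 < 2:
            raise ValueError("both groups need >= 2 members")
        N = self.n
        r1 = self.ranks[mask].sum(axis=0)
        r2 = N * (N + 1) / 2.0 - r1
        h = 12.0 / (N * (N + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (N + 1)
        corr = 1.0 - self.tie_term / (N**3 - N)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(corr > 0, h / corr, 0.0)
        h = np.maximum(h, 0.0)
        p = chi2.sf(h, df=1)
        return np.clip(p, np.finfo(float).tiny, 1.0), h


def _timecourse_from_ranks(cell: _CellRanks, labels: np.ndarray,
                           alpha: float) -> KwTimecourse:
    labels = np.asarray(labels)
    valid_ids = []
    p_rows, h_rows = [], []
    for k in np.unique(labels[labels != UNGROUPED]):
        mask = labels == k
        if mask.sum() < 2 or (cell.n - mask.sum()) < 2:
            continue
        p, h = cell.two_group(mask)
        valid_ids.append(int(k))
        p_rows.append(p)
        h_rows.append(h)
    if not p_rows:
        return KwTimecourse(np.empty((0, cell.T)), np.empty((0, cell.T)),
                            np.array([], dtype=int), alpha)
    return KwTimecourse(np.stack(p_rows), np.stack(h_rows),
                        np.asarray(valid_ids), alpha)


def type_specificity_timecourse(
    windows_ext: np.ndarray,
    typeset: ResponseTypeResults | np.ndarray,
    alpha: float = 0.05,
) -> KwTimecourse:
    """KW time curves of each type vs. the rest of its cell.

    ``typeset`` may be a clustering result or a plain label vector; ungrouped
    responses count toward "the rest".  Types with fewer than two members
    are skipped; single-type cells yield empty curves.
    """
    labels = typeset.labels if isinstance(typeset, ResponseTypeResults) else np.asarray(typeset)
    windows_ext = np.asarray(windows_ext, dtype=float)
    if windows_ext.shape[0] != labels.size:
        raise ValueError("windows and labels disagree in length")
    return _timecourse_from_ranks(_CellRanks(windows_ext), labels, alpha)


def significant_fraction(timecourses: list[KwTimecourse], alpha: float = 0.05) -> np.ndarray:
    """Per-sample fraction of all types (across cells) with p < alpha."""
    rows = [tc.p for tc in timecourses if tc.p.size]
    if not rows:
        raise ValueError("no defined types in any timecourse")
    p = np.concatenate(rows, axis=0)
    return (p < alpha).mean(axis=0)


def shuffle_control(
    cells: list[tuple[np.ndarray, np.ndarray]],
    n_shuffles: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-shuffle null of the significant-fraction curve.

    ``cells`` is a list of (windows_ext, labels) per (neuron, pattern);
    labels are permuted independently within each cell, the fraction curve
    recomputed per shuffle, and the curves averaged.  Returns
    (mean_curve, per_shuffle_curves).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng([int(seed), 77])
    ranked = [( _CellRanks(np.asarray(w, dtype=float)), np.asarray(l) )
              for w, l in cells]
    curves = []
    for _ in range(n_shuffles):
        tcs = []
        for cell, labels in ranked:
            perm = rng.permutation(labels.size)
            tcs.append(_timecourse_from_ranks(cell, labels[perm], alpha))
        curves.append(significant_fraction(tcs, alpha))
    curves = np.asarray(curves)
    return curves.mean(axis=0), curves
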