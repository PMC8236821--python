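"""PCA + kNN verification of response-type separability.

The principal components are fitted on the *mean* curve of each class only;
individual responses are then projected onto the smallest number of
components explaining at least 95% of the mean-curve variance, and decoded
with a repeated half-split k-nearest-neighbor classifier (Euclidean metric,
relative-majority vote, ties resolved by the single nearest neighbor).

Three scopes are supported: within one (neuron, pattern) cell (classes =
types + ungrouped, k = 4), across all patterns of one neuron and across all
neurons for one pattern (ungrouped excluded, k = 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .clustering import UNGROUPED, ResponseTypeResults


@dataclass
class PcBasis:
    center: np.ndarray
    components: np.ndarray          # (n_components, T), orthonormal rows
    explained_variance_fraction: float
    var_frac: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pc_basis(type_mean_curves: np.ndarray, var_frac: float = 0.95) -> PcBasis:
    """PCA on class-mean curves; keep the fewest PCs reaching ``var_frac``."""
    means = np.asarray(type_mean_curves, dtype=float)
    if means.ndim != 2 or means.shape[0] < 2:
        raise ValueError("need at least two mean curves")
    pca = PCA()
    pca.fit(means)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    n = min(n, pca.components_.shape[0])
    return PcBasis(pca.mean_, pca.components_[:n], float(cum[n - 1]), var_frac)


def project_responses(windows: np.ndarray, basis: PcBasis) -> np.ndarray:
    """Transform responses from the time domain to PC coordinates."""
    x = np.asarray(windows, dtype=float)
    if x.shape[-1] != basis.center.size:
        raise ValueError("window length does not match the basis")
    return (x - basis.center) @ basis.components.T


def reconstruct(coords: np.ndarray, basis: PcBasis) -> np.ndarray:
    return np.asarray(coords) @ basis.components + basis.center


def chance_level(n_classes: int) -> float:
    """Uniform-classifier reference accuracy, 1 / number of classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


@dataclass
class DecodingResult:
    confusion: np.ndarray       # row-normalized over true classes
    counts: np.ndarray          # pooled (true, predicted) counts
    accuracy: float             # mean of the confusion diagonal
    f1: np.ndarray              # per class, from pooled counts
    classes: list
    chance: float
    k: int
    n_iterations: int
    n_resampled_splits: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.classes,
            "recall": np.diag(self.confusion),
            "f1": self.f1,
        })


def _vote(dist_row: np.ndarray, train_labels: np.ndarray, k: int) -> int:
    order = np.argsort(dist_row, kind="stable")
    nearest = order[: min(k, order.size)]
    votes = train_labels[nearest]
    classes, counts = np.unique(votes, return_counts=True)
    winners = classes[counts == counts.max()]
    if winners.size == 1:
        return int(winners[0])
    return int(train_labels[order[0]])  # tie -> single nearest neighbor


def knn_decode(
    coords: np.ndarray,
    labels: np.ndarray,
    k: int = 4,
    n_iter: int = 40,
    split: float = 0.5,
    seed: int = 0,
) -> DecodingResult:
    """Repeated random half-split kNN decoding in PC space.

    Splits that leave a class without training examples are resampled.  The
    confusion matrix is built from counts pooled over iterations and
    row-normalized, so each row sums to one.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    classes, y = np.unique(labels, return_inverse=True)
    c = classes.size
    binc = np.bincount(y, minlength=c)
    if binc.min() < 2:
        raise ValueError("every class needs at least two members")
    n = y.size
    n_train = int(round(split * n))
    rng = np.random.default_rng([int(seed), 101])
    counts = np.zeros((c, c), dtype=float)
    resampled = 0
    for _ in range(n_iter):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if np.unique(y[train]).size == c:
                break
            resampled += 1
        else:
            raise RuntimeError("could not draw a split covering every class")
        d = cdist(coords[test], coords[train])
        for row, i in enumerate(test):
            pred = _vote(d[row], y[train], k)
            counts[y[i], pred] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, counts / row_sums, 0.0)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    return DecodingResult(
        confusion=confusion, counts=counts,
        accuracy=float(np.diag(confusion).mean()), f1=f1,
        classes=list(classes), chance=chance_level(c), k=k,
        n_iterations=n_iter, n_resampled_splits=resampled,
    )


# ---------------------------------------------------------------------------
# task assembly across scopes
# ---------------------------------------------------------------------------

SCOPES = ("within_pattern", "cross_pattern", "cross_neuron")


def assemble_decoding_task(
    typesets: list[ResponseTypeResults],
    scope: str,
) -> tuple[np.ndarray, np.ndarray, list, int]:
    """Collect windows and class labels for one decoding scope.

    within_pattern: one cell; classes are its types plus ungrouped; k = 4.
    cross_pattern / cross_neuron: several cells; classes are (cell, type)
    pairs, ungrouped responses excluded; k = 9.

    Returns (windows, class_labels, class_names, k).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if not typesets:
        raise ValueError("typesets must be nonempty")
    wins, labs, names = [], [], []
    if scope == "within_pattern":
        if len(typesets) != 1:
            raise ValueError("within_pattern expects exactly one typeset")
        ts = typesets[0]
        if ts.windows is None:
            raise ValueError("typeset carries no windows")
        class_ids = sorted(np.unique(ts.labels).tolist())  # UNGROUPED sorts first
        names = ["ungrouped" if c == UNGROUPED else f"T{c}" for c in class_ids]
        lut = {c: i for i, c in enumerate(class_ids)}
        wins = ts.windows
        labs = np.array([lut[l] for l in ts.labels])
        k = 4
    else:
        for ts in typesets:
            if ts.windows is None:
                raise ValueError("typeset carries no windows")
            for t in range(ts.n_types):
                idx = ts.members(t)
                tag = (f"{ts.pattern_label}/T{t}" if scope == "cross_pattern"
                       else f"N{ts.neuron_id}/T{t}")
                cls = len(names)
                names.append(tag)
                wins.append(ts.windows[idx])
                labs.append(np.full(idx.size, cls))
        if len(names) < 2:
            raise ValueError(f"{scope}: need at least two classes")
        wins = np.concatenate(wins, axis=0)
        labs = np.concatenate(labs)
        k = 9
    if len(names) < 2:
        raise ValueError(f"{scope}: need at least two classes")
    return np.asarray(wins, dtype=float), np.asarray(labs), names, k


def decode_typesets(
    typesets: list[ResponseTypeResults],
    scope: str,
    n_iter: int = 40,
    seed: int = 0,
    var_frac: float = 0.95,
) -> DecodingResult:
    """End-to-end decoding at one scope: class means -> PCA -> kNN.

    Classes with fewer than two members cannot be split into train and test
    and are dropped from the task.
    """
    windows, labels, names, k = assemble_decoding_task(typesets, scope)
    counts = np.bincount(labels, minlength=len(names))
    if (counts < 2).any():
        keep_ids = np.flatnonzero(counts >= 2)
        if keep_ids.size < 2:
            raise ValueError("fewer than two classes with >= 2 members")
        lut = {old: new for new, old in enumerate(keep_ids)}
        mask = np.isin(labels, keep_ids)
        windows = windows[mask]
        labels = np.array([lut[l] for l in labels[mask]])
        names = [names[i] for i in keep_ids]
    means = np.stack([windows[labels == c].mean(axis=0)
                      for c in range(len(names))])
    basis = fit_pc_basis(means, var_frac)
    coords = project_responses(windows, basis)
    result = knn_decode(coords, labels, k=k, n_iter=n_iter, seed=seed)
    result.classes = names
    return result
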