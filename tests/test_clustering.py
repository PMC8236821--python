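import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

import tactypes as tt
from tactypes.clustering import (ClusterParams, agreement_between,
                                 cluster_agreement, cluster_responses,
                                 overshoot_matrix, pair_same_type,
                                 sensitivity_grid, UNGROUPED)


# ---------------------------------------------------------------------------
# pairwise similarity rule
# ---------------------------------------------------------------------------

def test_pair_identity_and_threshold_forcing():
    a = np.linspace(0, 1, 350)
    same, over = pair_same_type(a, a)
    assert same and over == 0.0
    # constant offset 0.20: overshoot 0.07 < 0.08 -> same type
    same, over = pair_same_type(a, a + 0.20)
    assert same and over == pytest.approx(0.07)
    # constant offset 0.25: overshoot 0.12 >= 0.08 -> different
    same, over = pair_same_type(a, a + 0.25)
    assert not same and over == pytest.approx(0.12)


@given(st.integers(0, 1000))
@settings(max_examples=30, deadline=None)
def test_pair_rule_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(0, 1, (2, 350))
    sa, oa = pair_same_type(a, b)
    sb, ob = pair_same_type(b, a)
    assert sa == sb and oa == pytest.approx(ob)


def test_pair_rule_rejects_length_mismatch():
    with pytest.raises(ValueError):
        pair_same_type(np.zeros(350), np.zeros(349))


def test_overshoot_matrix_matches_scalar_rule(rng):
    w = rng.uniform(0, 1, (8, 350))
    mat = overshoot_matrix(w, 0.13)
    for i in range(8):
        for j in range(8):
            assert mat[i, j] == pytest.approx(pair_same_type(w[i], w[j])[1])


# ---------------------------------------------------------------------------
# greedy extraction
# ---------------------------------------------------------------------------

def test_three_planted_blocks_recovered_exactly():
    base = np.zeros(350)
    windows = np.concatenate([
        np.tile(base, (30, 1)), np.tile(base + 0.3, (30, 1)),
        np.tile(base + 0.6, (30, 1))])
    res = cluster_responses(windows)
    assert res.n_types == 3
    assert all(res.members(k).size == 30 for k in range(3))
    assert res.ungrouped_fraction == 0.0


def test_small_groups_dissolve_into_ungrouped(rng):
    # 4 identical curves plus 26 mutually dissimilar curves
    idx = np.arange(26)
    scattered = 0.5 + 0.5 * np.sin(
        np.linspace(0, 40 * np.pi, 350)[None, :] * (idx[:, None] + 3) / 7)
    windows = np.vstack([np.tile(np.linspace(0, 1, 350), (4, 1)), scattered])
    res = cluster_responses(windows)
    # the 4-member group dissolves (min_members = 5)
    assert np.all(res.labels[:4] == UNGROUPED)


def test_single_window_is_ungrouped():
    res = cluster_responses(np.zeros((1, 350)))
    assert res.n_types == 0
    assert res.labels.tolist() == [UNGROUPED]


def test_degenerate_windows_never_cluster():
    windows = np.tile(np.linspace(0, 1, 350), (10, 1))
    degen = np.zeros(10, dtype=bool)
    degen[:3] = True
    res = cluster_responses(windows, degenerate=degen)
    assert np.all(res.labels[:3] == UNGROUPED)
    assert np.all(res.labels[3:] == 0)


def _oracle_greedy(windows, params):
    """Exhaustive reference: at every step, enumerate every remaining leader's
    candidate group and take the largest (ties to the lowest index)."""
    same = overshoot_matrix(windows, params.threshold_diff) < params.overshoot_thresh
    np.fill_diagonal(same, True)
    n = windows.shape[0]
    remaining = set(range(n))
    groups = []
    while remaining:
        best = None
        for r in sorted(remaining):
            group = {s for s in remaining if same[r, s]}
            if best is None or len(group) > len(best):
                best = group
        groups.append(sorted(best))
        remaining -= best
    labels = np.full(n, UNGROUPED)
    nid = 0
    for g in groups:
        if len(g) >= params.min_members:
            labels[g] = nid
            nid += 1
    return labels


@pytest.mark.parametrize("seed", range(8))
def test_greedy_extraction_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 13))
    # coarse levels make ties and borderline pairs common
    windows = rng.choice([0.0, 0.15, 0.3, 0.5], size=(n, 350))
    params = ClusterParams(min_members=2)
    res = cluster_responses(windows, params)
    oracle = _oracle_greedy(windows, params)
    np.testing.assert_array_equal(res.labels, oracle)


def test_permutation_preserves_type_size_multiset(rng):
    ws = tt.simulate_window_set(k_types=3, reps_per_type=10,
                                ungrouped_fraction=0.2, seed=8)
    res = cluster_responses(ws.windows)
    perm = rng.permutation(ws.windows.shape[0])
    res_p = cluster_responses(ws.windows[perm])
    sizes = sorted(np.sum(res.labels == k) for k in range(res.n_types))
    sizes_p = sorted(np.sum(res_p.labels == k) for k in range(res_p.n_types))
    assert sizes == sizes_p


def test_ground_truth_recovery_ari(window_set, clustered):
    ari = adjusted_rand_score(window_set.true_labels, clustered.labels)
    assert ari >= 0.9
    assert abs(clustered.ungrouped_fraction - 0.2) <= 0.1


def test_results_summary_table(clustered):
    table = clustered.summary()
    assert table.n_members.sum() == clustered.n_windows
    assert str(table.type.iloc[-1]) == "ungrouped"


# ---------------------------------------------------------------------------
# sensitivity grid and cluster agreement
# ---------------------------------------------------------------------------

def test_sensitivity_single_cell_self_normalizes(window_set):
    grid = sensitivity_grid(window_set.windows[:120], [0.13], [0.08])
    if grid.n_types[0, 0] >= 1:
        assert grid.proportion_grouped[0, 0] == 1.0


def test_sensitivity_default_cell_recovers_planted_types(window_set):
    grid = sensitivity_grid(window_set.windows,
                            [0.10, 0.13, 0.16], [0.06, 0.08, 0.10])
    assert grid.n_types[1, 1] == 4
    assert grid.proportion_ungrouped[1, 1] == pytest.approx(0.2, abs=0.1)
    # neighbors of the default cell agree well (smooth landscape)
    assert grid.mean_agreement[1, 1] >= 0.8


def test_raising_overshoot_never_shrinks_candidate_groups(rng):
    windows = rng.uniform(0, 1, (15, 350))
    ref = 0
    for o1, o2 in [(0.05, 0.08), (0.08, 0.12)]:
        s1 = overshoot_matrix(windows, 0.13)[ref] < o1
        s2 = overshoot_matrix(windows, 0.13)[ref] < o2
        assert s1.sum() <= s2.sum()


def test_agreement_worked_examples():
    # one center cluster fully inside one neighbor cluster
    mean_fwd, best_fwd = agreement_between([[0, 1]], [[0, 1, 2], [3, 4, 5]])
    assert mean_fwd == pytest.approx(1.0)
    # the reverse direction: (0.66 + 0) / 2 = 0.33
    mean_rev, best_rev = agreement_between([[0, 1, 2], [3, 4, 5]], [[0, 1]])
    assert mean_rev == pytest.approx(1 / 3, abs=0.01)
    assert best_rev == pytest.approx(2 / 3, abs=0.01)


def test_agreement_identical_grid_is_one(window_set):
    res = cluster_responses(window_set.windows[:150])
    grid = [[res, res], [res, res]]
    mean_map, max_map = cluster_agreement(grid)
    np.testing.assert_allclose(mean_map, 1.0)
    np.testing.assert_allclose(max_map, 1.0)


def test_cluster_params_validation():
    with pytest.raises(ValueError):
        ClusterParams(threshold_diff=0.0)
    with pytest.raises(ValueError):
        ClusterParams(min_members=0)
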