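"""Data-driven ROI machinery: importances, dendrogram, representative selection."""

import numpy as np
import pytest

from tauroi import cluster_features, cv_feature_importance, select_representatives


def _planted(seed, n=200, p=20, frac_pos=0.4):
    """One near-copy of the label planted among pure-noise regions."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: int(n * frac_pos)] = 1
    rng.shuffle(y)
    X = rng.normal(0, 1, (n, p))
    X[:, 7] = y + rng.normal(0, 0.05, n)
    labels = [f"r{i:02d}" for i in range(p)]
    return X, y, labels


def test_importance_sums_to_one_and_finds_planted_region():
    X, y, labels = _planted(seed=1)
    res = cv_feature_importance(X, y, labels, n_trees=150, seed=1)
    assert res.mean_importance.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(res.mean_importance >= 0) and np.all(res.sd_importance >= 0)
    assert res.ranking()[0] == "r07"


def test_importance_deterministic_and_order_invariant():
    X, y, labels = _planted(seed=2)
    a = cv_feature_importance(X, y, labels, n_trees=100, seed=3)
    b = cv_feature_importance(X, y, labels, n_trees=100, seed=3)
    np.testing.assert_array_equal(a.mean_importance, b.mean_importance)
    perm = np.random.default_rng(0).permutation(len(y))
    c = cv_feature_importance(X[perm], y[perm], labels, n_trees=100, seed=3)
    np.testing.assert_array_equal(a.mean_importance, c.mean_importance)


def test_importance_input_validation():
    X, y, labels = _planted(seed=3)
    with pytest.raises(ValueError, match="two classes"):
        cv_feature_importance(X, np.zeros(len(y)), labels)
    with pytest.raises(ValueError, match="constant"):
        cv_feature_importance(np.ones_like(X), y, labels)
    X_bad = X.copy()
    X_bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        cv_feature_importance(X_bad, y, labels)


def test_cluster_identical_regions_merge_first(rng):
    base = rng.normal(0, 1, 100)
    X = np.column_stack([base, 3.5 * base + 1.0, rng.normal(0, 1, 100)])
    dend = cluster_features(X, ["a", "a_scaled", "noise"])
    first_height = dend.linkage_matrix[0, 2]
    assert first_height < 1e-9
    assert set(dend.cut(2)[:2]) == {dend.cut(2)[0]}  # a and a_scaled together


def test_cluster_negated_region_merges_last(rng):
    base = rng.normal(0, 1, 200)
    X = np.column_stack([base, base + rng.normal(0, 0.2, 200), -base])
    dend = cluster_features(X, ["a", "b", "neg_a"])
    # the final merge joins the negated region at distance close to 2
    assert dend.linkage_matrix[-1, 2] > 1.5


def test_cluster_recovers_block_structure(rng):
    n = 400
    block1 = rng.normal(0, 1, n)
    block2 = rng.normal(0, 1, n)
    X = np.column_stack(
        [block1 + rng.normal(0, 0.45, n) for _ in range(3)]
        + [block2 + rng.normal(0, 0.45, n) for _ in range(2)]
    )
    labels = ["a1", "a2", "a3", "b1", "b2"]
    dend = cluster_features(X, labels)
    assign = dend.cut(2)
    assert len(set(assign[:3])) == 1 and len(set(assign[3:])) == 1
    assert assign[0] != assign[3]


def test_cluster_zero_variance_region_rejected(rng):
    X = np.column_stack([rng.normal(0, 1, 50), np.full(50, 2.0)])
    with pytest.raises(ValueError, match="flat"):
        cluster_features(X, ["ok", "flat"])


def test_selection_keeps_planted_region_at_every_k():
    X, y, labels = _planted(seed=5)
    imp = cv_feature_importance(X, y, labels, n_trees=150, seed=5)
    dend = cluster_features(X, labels)
    trace = select_representatives(dend, imp, X, y, K_max=6, seed=5)
    assert all("r07" in members for members in trace.selected)
    assert [len(m) for m in trace.selected] == list(trace.ks)
    assert all(0.0 <= s <= 1.0 for s in trace.scores)
    assert trace.chosen_k <= 6
    assert set(trace.final_members) <= set(labels)


def test_selection_one_representative_per_redundant_block(rng):
    n = 300
    y = np.zeros(n, dtype=int)
    y[:120] = 1
    rng.shuffle(y)
    f1 = y + rng.normal(0, 0.4, n)
    f2 = -0.5 * y + rng.normal(0, 0.4, n)
    X = np.column_stack(
        [f1 + rng.normal(0, 0.1, n) for _ in range(3)]
        + [f2 + rng.normal(0, 0.1, n) for _ in range(2)]
    )
    labels = ["a1", "a2", "a3", "b1", "b2"]
    imp = cv_feature_importance(X, y, labels, n_trees=150, seed=0)
    dend = cluster_features(X, labels)
    trace = select_representatives(dend, imp, X, y, K_max=4, seed=0)
    k2 = trace.selected[trace.ks.index(2)]
    assert sum(lab.startswith("a") for lab in k2) == 1
    assert sum(lab.startswith("b") for lab in k2) == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_pure_noise_null_selection_is_uninformative(seed):
    """On label-independent regions the chosen composite's CV AUC stays near 0.5
    and no region dominates the importance ranking."""
    rng = np.random.default_rng(200 + seed)
    n = 400
    y = np.zeros(n, dtype=int)
    y[:200] = 1
    rng.shuffle(y)
    X = rng.normal(0, 1, (n, 20))
    labels = [f"n{i:02d}" for i in range(20)]
    imp = cv_feature_importance(X, y, labels, n_trees=200, seed=seed)
    assert imp.mean_importance.max() < 3 * np.median(imp.mean_importance)
    dend = cluster_features(X, labels)
    trace = select_representatives(dend, imp, X, y, K_max=5, seed=seed)
    assert 0.4 <= trace.scores[trace.ks.index(trace.chosen_k)] <= 0.6


def test_selection_reproducible_and_validated():
    X, y, labels = _planted(seed=8, p=10)
    imp = cv_feature_importance(X, y, labels, n_trees=80, seed=8)
    dend = cluster_features(X, labels)
    t1 = select_representatives(dend, imp, X, y, K_max=5, seed=8)
    t2 = select_representatives(dend, imp, X, y, K_max=5, seed=8)
    assert t1 == t2
    with pytest.raises(ValueError, match="K_max"):
        select_representatives(dend, imp, X, y, K_max=11, seed=8)
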