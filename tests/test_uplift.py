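"""Uplift-tree split criterion, greedy search, and partition bookkeeping."""

import numpy as np
import pytest

from cfrlearn.uplift import (TreeConfig, best_split, build_tree, predict_uplift,
                             split_gain, tree_from_json, tree_rules, tree_to_json)


# ------------------------------------------------------------------- oracles

def brute_force_best_split(X, tau, kinds, config):
    """Exhaustive re-enumeration of every (feature, threshold) candidate."""
    n = tau.size
    if n < 2 * config.min_node_size:
        return None
    best = None
    for j in range(X.shape[1]):
        if kinds[j] == "binary":
            cands = [0.5]
        else:
            qs = np.unique(np.quantile(X[:, j], config.quantile_grid))
            cands = [c for c in qs if X[:, j].min() <= c < X[:, j].max()]
        for c in cands:
            left = X[:, j] <= c
            if left.sum() < config.min_node_size or (~left).sum() < config.min_node_size:
                continue
            g = split_gain(tau, tau[left], tau[~left], config.separation_weight)
            if g > 0 and (best is None or g > best[2]):
                best = (j, float(c), g)
    return best


def test_split_gain_hand_example():
    """Perfectly separated {-0.4,-0.4,0,0} at lam = 1: 0.04 - 0 - 0 + 0.4."""
    tau = np.array([-0.4, -0.4, 0.0, 0.0])
    gain = split_gain(tau, tau[:2], tau[2:], separation_weight=1.0)
    assert gain == pytest.approx(0.44, abs=1e-12)


def test_split_gain_constant_tau_is_zero():
    tau = np.full(6, -0.2)
    assert split_gain(tau, tau[:2], tau[2:], 1.0) == pytest.approx(0.0, abs=1e-15)


def test_gain_at_lambda_zero_equals_between_group_variance():
    """With lam = 0 the gain is exactly the between-group term of the law of
    total variance, for arbitrary partitions."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = rng.integers(4, 40)
        tau = rng.normal(size=n)
        k = rng.integers(1, n)
        l, r = tau[:k], tau[k:]
        between = (len(l) / n) * (l.mean() - tau.mean()) ** 2 \
            + (len(r) / n) * (r.mean() - tau.mean()) ** 2
        assert split_gain(tau, l, r, 0.0) == pytest.approx(between, abs=1e-12)


def test_best_split_matches_exhaustive_enumeration():
    """Greedy selection agrees with the brute-force oracle on random
    instances mixing binary and continuous covariates."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(60, 500))
        d = int(rng.integers(2, 9))
        kinds = ["binary" if rng.random() < 0.5 else "continuous" for _ in range(d)]
        X = np.column_stack([
            (rng.random(n) < 0.5).astype(float) if k == "binary" else rng.normal(size=n)
            for k in kinds
        ])
        tau = 0.3 * X[:, 0] + rng.normal(scale=0.2, size=n)
        cfg = TreeConfig(min_node_size=20, separation_weight=float(rng.random()))
        got = best_split(X, tau, kinds, cfg)
        want = brute_force_best_split(X, tau, kinds, cfg)
        if want is None:
            assert got is None
        else:
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])
            assert got[2] == pytest.approx(want[2], abs=1e-12)


def test_best_split_all_equal_tau_returns_none():
    X = np.column_stack([np.repeat([0.0, 1.0], 20)])
    tau = np.zeros(40)
    assert best_split(X, tau, ["binary"], TreeConfig(min_node_size=5)) is None


def test_tie_break_prefers_lower_feature_index():
    """Two identical copies of the best feature: the lower index wins."""
    rng = np.random.default_rng(2)
    x = (rng.random(60) < 0.5).astype(float)
    X = np.column_stack([x, x])
    tau = -0.4 * x + rng.normal(scale=0.01, size=60)
    got = best_split(X, tau, ["binary", "binary"], TreeConfig(min_node_size=10))
    assert got[0] == 0


def test_perfect_binary_separation_selected_with_hand_gain():
    x = np.repeat([0.0, 1.0], 20)
    tau = np.where(x == 0, -0.4, 0.0)
    got = best_split(x[:, None], tau, ["binary"], TreeConfig(min_node_size=5))
    assert got[0] == 0
    assert got[2] == pytest.approx(split_gain(tau, tau[x == 0], tau[x == 1], 1.0))


def test_variance_reduction_equivalence_at_zero_separation():
    """With separation_weight 0 and minimal node size the grown tree equals
    an independent variance-reduction splitter."""
    rng = np.random.default_rng(12)
    n = 200
    X = np.column_stack([(rng.random(n) < 0.5).astype(float),
                         (rng.random(n) < 0.3).astype(float)])
    tau = 0.5 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(scale=0.05, size=n)
    cfg = TreeConfig(max_depth=2, min_node_size=10, separation_weight=0.0, seed=0)
    tree = build_tree(X, tau, ["binary", "binary"], cfg)

    def variance_reduction_split(idx):
        best = None
        for j in range(2):
            left = idx[X[idx, j] <= 0.5]
            right = idx[X[idx, j] > 0.5]
            if len(left) < 10 or len(right) < 10:
                continue
            red = tau[idx].var() - len(left) / len(idx) * tau[left].var() \
                - len(right) / len(idx) * tau[right].var()
            if red > 0 and (best is None or red > best[1]):
                best = (j, red)
        return best

    idx = np.arange(n)
    want = variance_reduction_split(idx)
    assert tree.feature == want[0]
    assert tree.gain == pytest.approx(want[1], abs=1e-12)


def test_tree_stopping_and_partition_invariants():
    rng = np.random.default_rng(5)
    n = 300
    X = np.column_stack([(rng.random(n) < 0.5).astype(float), rng.normal(size=n)])
    tau = -0.3 * X[:, 0] + 0.1 * (X[:, 1] > 0) + rng.normal(scale=0.05, size=n)
    cfg = TreeConfig(max_depth=3, min_node_size=30, seed=1)
    tree = build_tree(X, tau, ["binary", "continuous"], cfg,
                      feature_names=["flag", "score"])
    rules = tree_rules(tree)
    assert sum(r["n"] for r in rules) == n
    # weighted leaf means reproduce the overall mean ITE exactly
    weighted = sum(r["n"] * r["mean_ite"] for r in rules) / n
    assert weighted == pytest.approx(tau.mean(), abs=1e-12)
    # every leaf respects the size floor, every depth the cap

    def walk(node):
        assert node.depth <= cfg.max_depth
        if node.is_leaf:
            assert node.n >= cfg.min_node_size
        else:
            assert node.gain > 0
            assert node.left.n + node.right.n == node.n
            assert node.left.depth == node.depth + 1
            walk(node.left)
            walk(node.right)

    walk(tree)
    # every training row's prediction equals its leaf mean
    preds = np.array([predict_uplift(tree, X[i]) for i in range(n)])
    leaf_means = {r["mean_ite"] for r in rules}
    assert set(np.round(preds, 12)) <= {round(v, 12) for v in leaf_means}


def test_depth_one_and_homogeneous_trees():
    x = np.repeat([0.0, 1.0], 30)
    tau = np.where(x == 0, -0.4, 0.1)
    cfg = TreeConfig(max_depth=1, min_node_size=5, seed=0)
    tree = build_tree(x[:, None], tau, ["binary"], cfg)
    assert not tree.is_leaf
    assert tree.left.is_leaf and tree.right.is_leaf
    # homogeneous: single leaf, zero-width interval at the constant
    flat = build_tree(x[:, None], np.full(60, -0.2), ["binary"], cfg)
    assert flat.is_leaf
    assert flat.mean_ite == pytest.approx(-0.2)
    assert flat.ci == (pytest.approx(-0.2), pytest.approx(-0.2))


def test_routing_and_missing_covariate_error():
    x = np.repeat([0.0, 1.0], 30)
    tau = np.where(x == 0, -0.4, 0.1)
    tree = build_tree(x[:, None], tau, ["binary"],
                      TreeConfig(max_depth=1, min_node_size=5, seed=0),
                      feature_names=["flag"])
    assert predict_uplift(tree, {"flag": 0.0}) == pytest.approx(-0.4)
    assert predict_uplift(tree, {"flag": 1.0}) == pytest.approx(0.1)
    with pytest.raises(KeyError, match="flag"):
        predict_uplift(tree, {"other": 1.0})


def test_json_roundtrip_preserves_structure_and_determinism():
    rng = np.random.default_rng(9)
    n = 200
    X = np.column_stack([(rng.random(n) < 0.5).astype(float), rng.normal(size=n)])
    tau = -0.2 * X[:, 0] + rng.normal(scale=0.05, size=n)
    cfg = TreeConfig(max_depth=2, min_node_size=20, seed=3)
    t1 = build_tree(X, tau, ["binary", "continuous"], cfg)
    t2 = build_tree(X, tau, ["binary", "continuous"], cfg)
    assert tree_to_json(t1) == tree_to_json(t2)  # seeded leaf CIs included
    t3 = tree_from_json(tree_to_json(t1))
    assert tree_to_json(t3) == tree_to_json(t1)
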