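"""Uplift trees: transparent subgroup rules from per-patient treatment effects.

The tree recursively partitions patients by baseline covariates to expose
heterogeneity in predicted benefit.  A candidate split of node sample S on
covariate j at threshold c produces children L = {x_j <= c} and R = {x_j > c},
scored by the heterogeneity gain

    Gain(j, c) = Var(tau_S) - (|L|/n) Var(tau_L) - (|R|/n) Var(tau_R)
                 + lam * |mean(tau_L) - mean(tau_R)|

with population variances (divide by group size), so at lam = 0 the gain
reduces exactly to the between-group term of the law of total variance and is
never negative.  lam weights between-node mean separation against within-node
homogeneity.  Growth stops when a node is smaller than twice the minimum node
size, the depth limit is reached, or no candidate has positive gain.

Binary covariates split at 0.5 (absent left, present right); continuous
covariates are tried at node-local empirical quantiles.  Each leaf stores the
mean ITE, a seeded bootstrap percentile confidence interval, and its support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .effects import bootstrap_ci

__all__ = [
    "TreeConfig",
    "UpliftTreeNode",
    "split_gain",
    "best_split",
    "build_tree",
    "tree_rules",
    "predict_uplift",
    "tree_to_json",
    "tree_from_json",
]


@dataclass
class TreeConfig:
    max_depth: int = 4
    min_node_size: int = 50
    separation_weight: float = 1.0
    quantile_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    ci_level: float = 0.95
    ci_bootstrap: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be at least 1")
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be at least 2")
        if self.separation_weight < 0:
            raise ValueError("separation_weight must be nonnegative")


@dataclass
class UpliftTreeNode:
    depth: int
    n: int
    mean_ite: float
    ci: tuple[float, float]
    feature: int | None = None
    feature_name: str | None = None
    threshold: float | None = None
    gain: float | None = None
    left: "UpliftTreeNode | None" = None
    right: "UpliftTreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def split_gain(tau_s: np.ndarray, tau_l: np.ndarray, tau_r: np.ndarray,
               separation_weight: float = 1.0) -> float:
    """Heterogeneity gain of a candidate partition; exact arithmetic contract."""
    tau_s, tau_l, tau_r = (np.asarray(a, dtype=float) for a in (tau_s, tau_l, tau_r))
    if tau_l.size == 0 or tau_r.size == 0:
        raise ValueError("both children must be nonempty")
    if tau_l.size + tau_r.size != tau_s.size:
        raise ValueError("children must partition the parent sample")
    n = tau_s.size
    gain = (tau_s.var() - (tau_l.size / n) * tau_l.var()
            - (tau_r.size / n) * tau_r.var())
    return float(gain + separation_weight * abs(tau_l.mean() - tau_r.mean()))


def _candidate_thresholds(x: np.ndarray, kind: str,
                          config: TreeConfig) -> np.ndarray:
    if kind == "binary":
        return np.array([0.5])
    qs = np.unique(np.quantile(x, config.quantile_grid))
    return qs[(qs >= x.min()) & (qs < x.max())]


def best_split(X: np.ndarray, tau: np.ndarray, kinds: list[str],
               config: TreeConfig) -> tuple[int, float, float] | None:
    """Exhaustive search over (feature, threshold) candidates.

    Returns (feature index, threshold, gain) maximizing the heterogeneity
    gain, or None when no admissible candidate has positive gain.  Ties break
    toward the lower feature index, then the lower threshold.
    """
    n = tau.size
    if n < 2 * config.min_node_size:
        return None
    best: tuple[float, int, float] | None = None  # (gain, j, c)
    for j in range(X.shape[1]):
        xj = X[:, j]
        for c in _candidate_thresholds(xj, kinds[j], config):
            left = xj <= c
            nl = int(left.sum())
            if nl < config.min_node_size or n - nl < config.min_node_size:
                continue
            g = split_gain(tau, tau[left], tau[~left], config.separation_weight)
            # strict > keeps the first maximizer: lower feature, lower threshold;
            # the 1e-12 floor treats float residue on constant nodes as "no gain"
            if g > 1e-12 and (best is None or g > best[0]):
                best = (g, j, float(c))
    if best is None:
        return None
    return best[1], best[2], best[0]


def build_tree(X: np.ndarray, tau: np.ndarray, kinds: list[str] | None = None,
               config: TreeConfig | None = None,
               feature_names: list[str] | None = None) -> UpliftTreeNode:
    """Grow the uplift tree by greedy recursive partitioning."""
    config = config or TreeConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    tau = np.asarray(tau, dtype=float)
    kinds = kinds or [
        "binary" if set(np.unique(X[:, j])) <= {0.0, 1.0} else "continuous"
        for j in range(X.shape[1])
    ]
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(config.seed)

    def leaf(idx: np.ndarray, depth: int) -> UpliftTreeNode:
        g = tau[idx]
        if g.size > 1 and g.std() > 0:
            ci = bootstrap_ci(g, level=config.ci_level, n_boot=config.ci_bootstrap,
                              seed=int(rng.integers(2**31)))
        else:
            ci = (float(g.mean()), float(g.mean()))
        return UpliftTreeNode(depth=depth, n=int(g.size),
                              mean_ite=float(g.mean()), ci=ci)

    def grow(idx: np.ndarray, depth: int) -> UpliftTreeNode:
        node = leaf(idx, depth)
        if depth >= config.max_depth:
            return node
        found = best_split(X[idx], tau[idx], kinds, config)
        if found is None:
            return node
        j, c, gain = found
        node.feature, node.feature_name = j, names[j]
        node.threshold, node.gain = c, gain
        left = X[idx, j] <= c
        node.left = grow(idx[left], depth + 1)
        node.right = grow(idx[~left], depth + 1)
        return node

    idx = np.arange(tau.size)
    if tau.size < config.min_node_size:
        import warnings
        warnings.warn("fewer rows than min_node_size; returning a single leaf",
                      stacklevel=2)
        return leaf(idx, 0)
    return grow(idx, 0)


def predict_uplift(tree: UpliftTreeNode, x: np.ndarray | dict,
                   feature_names: list[str] | None = None) -> float:
    """Route one patient down the tree and return the leaf mean ITE."""
    node = tree
    while not node.is_leaf:
        if isinstance(x, dict):
            if node.feature_name not in x:
                raise KeyError(f"covariate {node.feature_name!r} missing from input")
            v = x[node.feature_name]
        else:
            x = np.asarray(x, dtype=float).ravel()
            if node.feature >= x.size:
                raise KeyError(f"covariate {node.feature_name!r} missing from input")
            v = x[node.feature]
        node = node.left if v <= node.threshold else node.right
    return node.mean_ite


def tree_rules(tree: UpliftTreeNode) -> list[dict]:
    """Ordered leaf rules: path conditions plus (mean ITE, CI, support)."""
    rules: list[dict] = []

    def walk(node: UpliftTreeNode, conditions: list[str]):
        if node.is_leaf:
            rules.append({
                "conditions": list(conditions) or ["(all patients)"],
                "mean_ite": node.mean_ite, "ci": node.ci, "n": node.n,
                "depth": node.depth,
            })
            return
        walk(node.left, conditions + [f"{node.feature_name} <= {node.threshold:g}"])
        walk(node.right, conditions + [f"{node.feature_name} > {node.threshold:g}"])

    walk(tree, [])
    return rules


def format_rules(tree: UpliftTreeNode) -> str:
    lines = []
    for r in tree_rules(tree):
        cond = " AND ".join(r["conditions"])
        lines.append(f"IF {cond} THEN mean ITE = {r['mean_ite']:+.4f} "
                     f"(95% CI {r['ci'][0]:+.4f} to {r['ci'][1]:+.4f}, n = {r['n']})")
    return "\n".join(lines)


def _node_dict(node: UpliftTreeNode) -> dict:
    d = {"depth": node.depth, "n": node.n, "mean_ite": node.mean_ite,
         "ci": list(node.ci)}
    if not node.is_leaf:
        d.update({"feature": node.feature, "feature_name": node.feature_name,
                  "threshold": node.threshold, "gain": node.gain,
                  "left": _node_dict(node.left), "right": _node_dict(node.right)})
    return d


def tree_to_json(tree: UpliftTreeNode) -> str:
    return json.dumps(_node_dict(tree), indent=2)


def _node_from_dict(d: dict) -> UpliftTreeNode:
    node = UpliftTreeNode(depth=d["depth"], n=d["n"], mean_ite=d["mean_ite"],
                          ci=tuple(d["ci"]))
    if "feature" in d:
        node.feature = d["feature"]
        node.feature_name = d["feature_name"]
        node.threshold = d["threshold"]
        node.gain = d["gain"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def tree_from_json(s: str) -> UpliftTreeNode:
    return _node_from_dict(json.loads(s))
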