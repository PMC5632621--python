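"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's pruning/permutation code paths:
likelihoods come from exhaustive enumeration over ancestral state
assignments, marginals from conditional sums, and permutation p-values
from complete enumeration of label partitions.
"""

from __future__ import annotations

import itertools

import numpy as np


def mk_transition_expm(alpha: float, t: float, k: int) -> np.ndarray:
    """Mk transition matrix via matrix exponential of the rate matrix."""
    from scipy.linalg import expm

    Q = np.full((k, k), alpha)
    np.fill_diagonal(Q, -alpha * (k - 1))
    return expm(Q * t)


def _iter_nodes(tree):
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if n.child_nodes()]
    return nodes, internal


def mk_brute_likelihood_terms(tree, tip_states: dict, alpha: float, k: int):
    """Yield (assignment dict over internal nodes, joint probability)."""
    nodes, internal = _iter_nodes(tree)
    root = tree.seed_node
    P_cache = {}

    def P(t):
        if t not in P_cache:
            P_cache[t] = mk_transition_expm(alpha, t, k)
        return P_cache[t]

    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = {id(n): s for n, s in zip(internal, assign)}
        prob = 1.0 / k  # uniform root prior
        for n in nodes:
            if n is root:
                continue
            ps = amap[id(n.parent_node)]
            t = float(n.edge.length) if n.edge.length is not None else 1.0
            if n.child_nodes():
                prob *= P(t)[ps, amap[id(n)]]
            else:
                s = tip_states.get(n.taxon.label if n.taxon else n.label)
                if s is None or (isinstance(s, float) and np.isnan(s)):
                    prob *= 1.0
                else:
                    prob *= P(t)[ps, int(s)]
        yield amap, prob


def mk_brute_loglik(tree, tip_states: dict, alpha: float, k: int) -> float:
    total = sum(p for _, p in mk_brute_likelihood_terms(tree, tip_states, alpha, k))
    return float(np.log(total)) if total > 0 else -np.inf


def mk_brute_marginals(tree, tip_states: dict, alpha: float, k: int) -> dict:
    """Marginal state probabilities per internal-node label by enumeration."""
    _, internal = _iter_nodes(tree)
    sums = {n.label: np.zeros(k) for n in internal}
    id_to_label = {id(n): n.label for n in internal}
    for amap, prob in mk_brute_likelihood_terms(tree, tip_states, alpha, k):
        for nid, s in amap.items():
            sums[id_to_label[nid]][s] += prob
    return {lab: v / v.sum() for lab, v in sums.items()}


def two_cell_partition_pvalue(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Exhaustive equivalency p on a 2-cell environment.

    Points live in cell 0 or 1.  For a partition into groups of the
    original sizes, each group's occupancy is its cell-count proportion
    vector and D = 1 - 0.5 * sum|pa - pb|.  p = fraction of partitions
    with D <= observed (the observed partition counts itself).
    """
    def D_of(ga: np.ndarray, gb: np.ndarray) -> float:
        pa = np.array([(ga == 0).mean(), (ga == 1).mean()])
        pb = np.array([(gb == 0).mean(), (gb == 1).mean()])
        return 1.0 - 0.5 * np.abs(pa - pb).sum()

    D_obs = D_of(labels_a, labels_b)
    pooled = np.concatenate([labels_a, labels_b])
    n, n_a = len(pooled), len(labels_a)
    hits = total = 0
    for idx in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        if D_of(pooled[mask], pooled[~mask]) <= D_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def min_drop_sets(corr: np.ndarray, threshold: float):
    """All minimum-size variable drop-sets achieving max |r| <= threshold."""
    p = corr.shape[0]
    best: list[tuple[int, ...]] = []
    for size in range(p + 1):
        for drop in itertools.combinations(range(p), size):
            keep = [i for i in range(p) if i not in drop]
            if len(keep) < 2:
                best.append(drop)
                continue
            sub = np.abs(corr[np.ix_(keep, keep)])
            np.fill_diagonal(sub, 0)
            if sub.max() <= threshold:
                best.append(drop)
        if best:
            return size, best
    return p, best
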