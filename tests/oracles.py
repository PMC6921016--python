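"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from the definitions (adjacency
sums, exhaustive enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def modularity_from_definition(net: nx.Graph, clusters) -> float:
    """Q computed straight from the adjacency matrix."""
    nodes = list(net.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    f_vv = a.sum()
    deg = a.sum(axis=1)
    q = 0.0
    for cluster in clusters:
        idx = [pos[v] for v in cluster]
        q += a[np.ix_(idx, idx)].sum() / f_vv - (deg[idx].sum() / f_vv) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def best_partition_q(net: nx.Graph) -> tuple[float, list[list]]:
    """Exhaustive maximum-modularity partition (graphs up to ~8 vertices)."""
    best_q, best_p = -math.inf, None
    for partition in set_partitions(list(net.nodes)):
        q = modularity_from_definition(net, partition)
        if q > best_q:
            best_q, best_p = q, partition
    return best_q, best_p


def auc_by_pair_counting(values, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l != 1]
    total = 0.0
    for vp, vn in itertools.product(pos, neg):
        total += 1.0 if vp > vn else (0.5 if vp == vn else 0.0)
    return total / (len(pos) * len(neg))


def s_values_by_path_enumeration(term, dag, weights=None) -> dict:
    """Max edge-weight product over all upward paths, per reachable ancestor."""
    weights = weights or {"is_a": 0.8, "part_of": 0.6}
    best = {term: 1.0}

    def walk(node, product):
        for parent, relation in dag.parents(node):
            p = product * weights[relation]
            if p > best.get(parent, 0.0):
                best[parent] = p
            walk(parent, p)

    walk(term, 1.0)
    return best


def logistic_objective(w, b, x, y, c) -> float:
    """(1/2)(w'w + b^2) + C sum log(1 + exp(-y (x w + b))).

    The intercept enters the penalty because liblinear augments the
    design with a regularized bias column.
    """
    margins = y * (x @ w + b)
    return 0.5 * (np.dot(w, w) + b * b) + c * np.sum(np.logaddexp(0.0, -margins))


def grid_minimize_logistic(x, y, c, span=4.0, steps=4) -> float:
    """Iteratively refined dense grid search over (w1, w2, b)."""
    center = np.zeros(3)
    width = span
    best = math.inf
    for _ in range(steps):
        axes = [np.linspace(center[i] - width, center[i] + width, 21) for i in range(3)]
        w1, w2, b = np.meshgrid(*axes, indexing="ij")
        margins = y[:, None, None, None] * (
            x[:, 0][:, None, None, None] * w1
            + x[:, 1][:, None, None, None] * w2
            + b
        )
        obj = 0.5 * (w1**2 + w2**2 + b**2) + c * np.logaddexp(0.0, -margins).sum(axis=0)
        idx = np.unravel_index(np.argmin(obj), obj.shape)
        best = float(obj[idx])
        center = np.array([w1[idx], w2[idx], b[idx]])
        width /= 10.0
    return best
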