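"""Maximum modularity clustering (MMC) by greedy coarsening and refining.

For a weighted undirected graph (V, f) with f(X, Y) the total weight over
*ordered* vertex pairs (each undirected edge counted twice within a set),
deg(v) = sum_u f(u, v) and dev(X) = f(X, V), the modularity of a
partition C = {C1, ..., Ck} is

    Q(C) = sum_i [ f(Ci, Ci) / f(V, V) - dev(Ci)^2 / dev(V)^2 ],

the realized intra-cluster weight fraction minus its expectation under
the degree-preserving null model.  Two local operators drive the greedy
search, each scored by its exact modularity increase:

    merge Ci, Cj:   dQ = 2 f(Ci, Cj) / f(V, V) - 2 dev(Ci) dev(Cj) / dev(V)^2
    move v Ci->Cj:  dQ = 2 (f(v, Cj) - f(v, Ci - v)) / f(V, V)
                         - 2 dev(v) (dev(Cj) - dev(Ci - v)) / dev(V)^2

Starting from all singletons, one best positive-gain merge is applied
per round (coarsening), followed by sweeps of positive-gain
single-vertex moves (refining); when neither operator offers a positive
gain, a Kernighan-Lin pass chains single moves through temporary
modularity decreases and commits the best prefix, escaping the pairing
traps plain greedy search falls into (e.g. on path graphs).  Q strictly
increases at every accepted phase and is bounded above, so the loop
terminates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin

#: Gains below this are treated as zero (guards float noise in the greedy loop).
GAIN_EPS = 1e-12


@dataclass
class Clustering:
    """A partition of a vertex set with its modularity.

    ``modularity`` is ``None`` for edgeless graphs, where Q is
    undefined.  ``merges`` records the coarsening steps as
    (cluster_id_kept, cluster_id_absorbed, Q_after) triples; refinement
    moves are not part of the merge tree.
    """

    clusters: list[frozenset]
    modularity: float | None
    merges: list[tuple[Hashable, Hashable, float]] = field(default_factory=list)
    q_trace: list[float] = field(default_factory=list)

    def labels(self) -> dict:
        return {v: i for i, cluster in enumerate(self.clusters) for v in cluster}


def _edge_weight(net: nx.Graph, u, v) -> float:
    return net[u][v].get("weight", 1.0)


def total_weight(net: nx.Graph) -> float:
    """f(V, V): twice the sum of edge weights."""
    return 2.0 * net.size(weight="weight")


def modularity(net: nx.Graph, clustering: Iterable[Iterable]) -> float:
    """Q of a partition, recomputed from scratch."""
    clusters = [set(c) for c in clustering]
    covered = set().union(*clusters) if clusters else set()
    if covered != set(net.nodes) or sum(len(c) for c in clusters) != len(covered):
        raise ValueError("clustering must partition the vertex set")
    f_vv = total_weight(net)
    if f_vv == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    degree = dict(net.degree(weight="weight"))
    q = 0.0
    for cluster in clusters:
        intra = 2.0 * sum(
            _edge_weight(net, u, v)
            for u, v in net.edges(cluster)
            if u in cluster and v in cluster
        )
        dev = sum(degree[v] for v in cluster)
        q += intra / f_vv - (dev / f_vv) ** 2
    return q


def delta_merge(
    f_ij: float, dev_i: float, dev_j: float, f_vv: float
) -> float:
    """Exact modularity gain of merging clusters Ci, Cj.

    ``f_ij`` is the inter-cluster weight (each connecting edge counted
    once: one ordered orientation).
    """
    return 2.0 * f_ij / f_vv - 2.0 * dev_i * dev_j / (f_vv * f_vv)


def delta_move(
    f_v_cj: float,
    f_v_ci: float,
    dev_v: float,
    dev_cj: float,
    dev_ci_minus_v: float,
    f_vv: float,
) -> float:
    """Exact modularity gain of moving v from Ci to Cj.

    ``f_v_cj`` / ``f_v_ci`` are v's edge weights into Cj and into
    Ci - v; ``dev_ci_minus_v`` excludes v's own degree.
    """
    return (
        2.0 * (f_v_cj - f_v_ci) / f_vv
        - 2.0 * dev_v * (dev_cj - dev_ci_minus_v) / (f_vv * f_vv)
    )


class _State:
    """Mutable partition with cached cluster degrees and inter-cluster weights."""

    def __init__(self, net: nx.Graph):
        self.net = net
        self.f_vv = total_weight(net)
        self.degree = dict(net.degree(weight="weight"))
        # cluster id = smallest member vertex (stable, deterministic)
        self.members: dict = {v: {v} for v in net.nodes}
        self.cluster_of: dict = {v: v for v in net.nodes}
        self.dev: dict = {v: self.degree[v] for v in net.nodes}
        # inter/intra cluster weights, one orientation per edge pair
        self.w: dict = {}
        for u, v in net.edges:
            cu, cv = u, v
            key = (min(cu, cv), max(cu, cv))
            self.w[key] = self.w.get(key, 0.0) + _edge_weight(net, u, v)

    def _key(self, ci, cj):
        return (ci, cj) if ci <= cj else (cj, ci)

    def weight_between(self, ci, cj) -> float:
        return self.w.get(self._key(ci, cj), 0.0)

    def merge(self, ci, cj) -> Hashable:
        """Merge cj into ci (ci must sort first); returns surviving id."""
        keep, gone = (ci, cj) if ci <= cj else (cj, ci)
        self.members[keep] |= self.members[gone]
        for v in self.members[gone]:
            self.cluster_of[v] = keep
        self.dev[keep] += self.dev[gone]
        del self.members[gone], self.dev[gone]
        # the absorbed cluster's self-weight and the connecting weight
        # both become intra-cluster weight of the survivor
        intra_gain = self.w.pop((gone, gone), 0.0) + self.w.pop(
            self._key(gone, keep), 0.0
        )
        if intra_gain:
            self.w[(keep, keep)] = self.w.get((keep, keep), 0.0) + intra_gain
        # fold gone's inter-cluster weights into keep's
        for other in list(self.members):
            if other == keep:
                continue
            w = self.w.pop(self._key(gone, other), 0.0)
            if w:
                key = self._key(keep, other)
                self.w[key] = self.w.get(key, 0.0) + w
        return keep

    def vertex_weight_to(self, v, cluster_id) -> float:
        members = self.members[cluster_id]
        return sum(
            _edge_weight(self.net, v, u)
            for u in self.net.neighbors(v)
            if u in members and u != v
        )

    def move(self, v, ci, cj) -> tuple[Hashable, Hashable]:
        """Move v from ci to cj; returns the (possibly renamed) cluster ids."""
        self.members[ci].discard(v)
        self.dev[ci] -= self.degree[v]
        self.members[cj].add(v)
        self.dev[cj] += self.degree[v]
        self.cluster_of[v] = cj
        if not self.members[ci]:
            del self.members[ci], self.dev[ci]
            for other in list(self.members):
                self.w.pop(self._key(ci, other), None)
            ci = None
        # cluster ids are smallest members: rename where needed
        ci = self._maybe_rename(ci)
        cj = self._maybe_rename(cj)
        self._rebuild_weights()
        return ci, cj

    def _maybe_rename(self, cid):
        if cid is None or cid not in self.members:
            return cid
        new_id = min(self.members[cid])
        if new_id != cid:
            self.members[new_id] = self.members.pop(cid)
            self.dev[new_id] = self.dev.pop(cid)
            for v in self.members[new_id]:
                self.cluster_of[v] = new_id
            for other in list(self.members):
                if other == new_id:
                    continue
                w = self.w.pop(self._key(cid, other), None)
                if w is not None:
                    self.w[self._key(new_id, other)] = w
            w = self.w.pop(self._key(cid, cid), None)
            if w is not None:
                self.w[self._key(new_id, new_id)] = w
            return new_id
        return cid

    def _rebuild_weights(self) -> None:
        # moves perturb many pairwise weights; with complex-sized graphs a
        # rebuild is cheap and keeps the cache trivially coherent
        self.w = {}
        for u, v in self.net.edges:
            cu, cv = self.cluster_of[u], self.cluster_of[v]
            key = self._key(cu, cv)
            self.w[key] = self.w.get(key, 0.0) + _edge_weight(self.net, u, v)

    def split_out(self, v) -> None:
        """Move v out of its cluster into a fresh singleton cluster."""
        ci = self.cluster_of[v]
        if len(self.members[ci]) < 2:
            return
        self.members[ci].discard(v)
        self.dev[ci] -= self.degree[v]
        self._maybe_rename(ci)
        self.members[v] = {v}
        self.dev[v] = self.degree[v]
        self.cluster_of[v] = v
        self._rebuild_weights()

    def split_gain(self, v) -> float:
        """Modularity gain of splitting v into its own cluster."""
        ci = self.cluster_of[v]
        if len(self.members[ci]) < 2:
            return 0.0
        return delta_move(
            0.0,
            self.vertex_weight_to(v, ci),
            self.degree[v],
            0.0,
            self.dev[ci] - self.degree[v],
            self.f_vv,
        )

    def set_partition(self, assignment: dict) -> None:
        """Reset the state to an arbitrary vertex->cluster assignment."""
        groups: dict = {}
        for v, cid in assignment.items():
            groups.setdefault(cid, set()).add(v)
        self.members = {min(g): set(g) for g in groups.values()}
        self.cluster_of = {v: cid for cid, g in self.members.items() for v in g}
        self.dev = {
            cid: sum(self.degree[v] for v in g) for cid, g in self.members.items()
        }
        self._rebuild_weights()

    def current_q(self) -> float:
        q = 0.0
        for cid in self.members:
            intra = 2.0 * self.w.get((cid, cid), 0.0)
            q += intra / self.f_vv - (self.dev[cid] / self.f_vv) ** 2
        return q

    def partition(self) -> list[frozenset]:
        return sorted(
            (frozenset(c) for c in self.members.values()), key=lambda c: min(c)
        )


#: Graph size up to which the forced-first-move restart sweep runs; the
#: sweep is quadratic in vertices x clusters and only pays off on small
#: graphs, where short escape chains matter most.
DEEP_REFINE_MAX_VERTICES = 24


def _kl_pass(
    state: _State,
    forced_first: tuple | None = None,
    max_steps: int | None = None,
) -> float:
    """One Kernighan-Lin refinement pass.

    Vertices are moved one at a time to their best target cluster (each
    vertex at most once, negative gains allowed); the prefix of the move
    chain with the largest cumulative gain is kept if positive,
    otherwise the pass is rolled back entirely.  ``forced_first`` is an
    optional (vertex, target-or-None) move executed unconditionally as
    the first step of the chain.  Returns the accepted gain (0.0 when
    nothing improved).
    """
    start = dict(state.cluster_of)
    best_gain = 0.0
    best_assignment: dict | None = None
    cumulative = 0.0
    locked: set = set()
    if forced_first is not None:
        v, cj = forced_first
        if cj is None:
            gain = state.split_gain(v)
            state.split_out(v)
        else:
            ci = state.cluster_of[v]
            gain = delta_move(
                state.vertex_weight_to(v, cj),
                state.vertex_weight_to(v, ci),
                state.degree[v],
                state.dev[cj],
                state.dev[ci] - state.degree[v],
                state.f_vv,
            )
            state.move(v, ci, cj)
        locked.add(v)
        cumulative += gain
        if cumulative > best_gain + GAIN_EPS:
            best_gain = cumulative
            best_assignment = dict(state.cluster_of)
    steps = len(start) if max_steps is None else max_steps
    for _ in range(steps):
        if len(state.members) < 2:
            break
        best = None  # (gain, vertex, target); target None = new cluster
        for v in sorted(state.net.nodes):
            if v in locked:
                continue
            ci = state.cluster_of[v]
            f_v_ci = state.vertex_weight_to(v, ci)
            dev_ci_minus_v = state.dev[ci] - state.degree[v]
            for cj in sorted(state.members):
                if cj == ci:
                    continue
                gain = delta_move(
                    state.vertex_weight_to(v, cj),
                    f_v_ci,
                    state.degree[v],
                    state.dev[cj],
                    dev_ci_minus_v,
                    state.f_vv,
                )
                if (
                    best is None
                    or gain > best[0] + GAIN_EPS
                    or (
                        abs(gain - best[0]) <= GAIN_EPS
                        and best[2] is not None
                        and (v, cj) < (best[1], best[2])
                    )
                ):
                    best = (gain, v, cj)
            if len(state.members[ci]) > 1:
                # splitting v into a fresh singleton (existing targets
                # win ties, keeping the operator set minimal)
                gain = state.split_gain(v)
                if best is None or gain > best[0] + GAIN_EPS:
                    best = (gain, v, None)
        if best is None:
            break
        gain, v, cj = best
        if cj is None:
            state.split_out(v)
        else:
            state.move(v, state.cluster_of[v], cj)
        locked.add(v)
        cumulative += gain
        if cumulative > best_gain + GAIN_EPS:
            best_gain = cumulative
            best_assignment = dict(state.cluster_of)
    if best_gain > GAIN_EPS and best_assignment is not None:
        state.set_partition(best_assignment)
        return best_gain
    state.set_partition(start)
    return 0.0


def _forced_restart_sweep(state: _State) -> float:
    """Kernighan-Lin passes forced through every candidate first move.

    Deterministic: candidates are tried in sorted (vertex, target)
    order, splits last per vertex; the first chain whose best prefix is
    a net improvement is committed.
    """
    n = len(state.cluster_of)
    for v in sorted(state.net.nodes):
        ci = state.cluster_of[v]
        targets = [cj for cj in sorted(state.members) if cj != ci]
        if len(state.members[ci]) > 1:
            targets.append(None)
        for cj in targets:
            gain = _kl_pass(
                state, forced_first=(v, cj), max_steps=min(n, 12)
            )
            if gain > GAIN_EPS:
                return gain
    return 0.0


def mmc_cluster(net: nx.Graph, seed: int | None = None) -> Clustering:
    """Cluster a graph by greedy modularity coarsening and refining.

    Deterministic: merges break ties on the lexicographically smallest
    cluster-id pair and refinement sweeps vertices in sorted order; the
    ``seed`` argument is accepted for interface stability but unused.
    An edgeless graph yields all singletons with undefined modularity.
    """
    del seed
    if net.number_of_nodes() == 0:
        return Clustering([], None)
    if net.number_of_edges() == 0:
        return Clustering([frozenset([v]) for v in sorted(net.nodes)], None)
    state = _State(net)
    merges: list[tuple[Hashable, Hashable, float]] = []
    q = state.current_q()
    q_trace = [q]

    while True:
        # -- coarsening: the single best positive-gain merge, if any.
        # one merge per outer round, so refinement can reshape the
        # partition before the next pair of clusters is locked together
        improved = False
        best = None
        for ci, cj in list(state.w):
            if ci == cj:
                continue
            gain = delta_merge(
                state.weight_between(ci, cj),
                state.dev[ci],
                state.dev[cj],
                state.f_vv,
            )
            key = (ci, cj)
            if gain > GAIN_EPS and (
                best is None
                or gain > best[0] + GAIN_EPS
                or (abs(gain - best[0]) <= GAIN_EPS and key < best[1])
            ):
                best = (gain, key)
        if best is not None:
            gain, (ci, cj) = best
            kept = state.merge(ci, cj)
            q += gain
            merges.append((kept, cj if kept == ci else ci, q))
            q_trace.append(q)
            improved = True

        # -- refining: sweep single-vertex moves until a clean sweep
        moved_any = False
        while True:
            moved = False
            for v in sorted(state.net.nodes):
                ci = state.cluster_of[v]
                if len(state.members) < 2:
                    break
                f_v_ci = state.vertex_weight_to(v, ci)
                dev_ci_minus_v = state.dev[ci] - state.degree[v]
                best = None
                for cj in sorted(state.members):
                    if cj == ci:
                        continue
                    gain = delta_move(
                        state.vertex_weight_to(v, cj),
                        f_v_ci,
                        state.degree[v],
                        state.dev[cj],
                        dev_ci_minus_v,
                        state.f_vv,
                    )
                    if gain > GAIN_EPS and (best is None or gain > best[0]):
                        best = (gain, cj)
                if best is not None:
                    gain, cj = best
                    state.move(v, ci, cj)
                    q += gain
                    q_trace.append(q)
                    moved = True
            if not moved:
                break
            moved_any = True

        if improved or moved_any:
            continue
        # -- escape pass: Kernighan-Lin move chain with best-prefix commit
        kl_gain = _kl_pass(state)
        if kl_gain > GAIN_EPS:
            q += kl_gain
            q_trace.append(q)
            continue
        # -- on small graphs, additionally restart the chain from every
        # possible first move (the free chain can lock itself out of a
        # short escape that starts with the "wrong" negative move)
        if net.number_of_nodes() <= DEEP_REFINE_MAX_VERTICES:
            kl_gain = _forced_restart_sweep(state)
            if kl_gain > GAIN_EPS:
                q += kl_gain
                q_trace.append(q)
                continue
        break

    return Clustering(state.partition(), state.current_q(), merges, q_trace)


def merge_tree_newick(clustering: Clustering, all_vertices: Iterable) -> str:
    """Newick rendering of the merge sequence (branch depth = merge order)."""
    trees = {v: str(v) for v in all_vertices}
    for kept, gone, _q in clustering.merges:
        trees[kept] = f"({trees[kept]},{trees.pop(gone)})"
    return "(" + ",".join(trees[k] for k in sorted(trees, key=str)) + ");"


class MaxModularityClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn style wrapper around :func:`mmc_cluster`.

    ``fit`` accepts a symmetric adjacency matrix (dense or sparse) or a
    :class:`networkx.Graph`; fitted attributes are ``labels_``,
    ``modularity_`` and ``n_clusters_``.
    """

    def __init__(self, seed: int | None = None):
        self.seed = seed

    def fit(self, X, y=None):
        if isinstance(X, nx.Graph):
            net = X
            order: Sequence = sorted(X.nodes)
        else:
            if sparse.issparse(X):
                X = X.toarray()
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] != X.shape[1]:
                raise ValueError("adjacency matrix must be square")
            if not np.allclose(X, X.T):
                raise ValueError("adjacency matrix must be symmetric")
            net = nx.from_numpy_array(X)
            order = range(X.shape[0])
        self.clustering_ = mmc_cluster(net, seed=self.seed)
        label_of = self.clustering_.labels()
        self.labels_ = np.array([label_of[v] for v in order])
        self.modularity_ = self.clustering_.modularity
        self.n_clusters_ = len(self.clustering_.clusters)
        return self
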