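"""Wang-measure GO semantic similarity and functional clustering.

For a GO term A, its induced ancestor graph DAG_A contains A, all of A's
ancestors and the connecting edges.  Each term t in DAG_A gets an
S-value: S_A(A) = 1 and, for ancestors,

    S_A(t) = max { w_e * S_A(t') : t' a child of t inside DAG_A },

with edge weights w_e = 0.8 for is-a and 0.6 for part-of relations.  The
semantic value SV(A) is the sum of S-values over DAG_A, and two terms
compare through their shared ancestry:

    S_GO(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)).

Gene-level functional similarity uses the *max* strategy: the largest
S_GO over all cross-pairs of the two genes' annotation sets.  This gives
a coarse, conservative grouping signal appropriate for roughly
decomposing fully connected complexes, where topology is uninformative.
Sub-complexes are then obtained by average-linkage agglomerative
clustering on the distance 1 - Sim, cut at k clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .io import AnnotationSet, GoDag

#: Edge weights of the semantic contribution per relation type.
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def s_values(term: str, dag: GoDag, weights: Mapping[str, float] | None = None) -> dict[str, float]:
    """S-values of every term in DAG_term, computed upward from *term*.

    Each ancestor's S-value is the maximum edge-weight product over paths
    down to *term*; equivalently the recursion above, evaluated by a
    best-first (Dijkstra-like on -log weights) traversal from the term.
    """
    if term not in dag:
        raise KeyError(f"unknown GO term {term!r}")
    weights = RELATION_WEIGHTS if weights is None else weights
    out = {term: 1.0}
    # best-first: always settle the largest tentative S-value next, so
    # each term's final value respects the max rule over its children
    import heapq

    heap = [(-1.0, term)]
    settled: set[str] = set()
    while heap:
        neg_s, t = heapq.heappop(heap)
        if t in settled:
            continue
        settled.add(t)
        s_t = -neg_s
        for parent, relation in dag.parents(t):
            cand = weights[relation] * s_t
            if cand > out.get(parent, 0.0):
                out[parent] = cand
                heapq.heappush(heap, (-cand, parent))
    return out


def semantic_value(term: str, dag: GoDag) -> float:
    """SV(A): sum of S-values over A and its ancestors."""
    return sum(s_values(term, dag).values())


def term_similarity(term_a: str, term_b: str, dag: GoDag) -> float:
    """Wang similarity S_GO(A, B) in [0, 1]; 1 iff identical ancestry."""
    sa = s_values(term_a, dag)
    sb = s_values(term_b, dag)
    shared = set(sa) & set(sb)
    if not shared:
        return 0.0
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (sum(sa.values()) + sum(sb.values()))


def gene_similarity(
    gene_a: str,
    gene_b: str,
    ann: AnnotationSet,
    dag: GoDag,
) -> float:
    """Max-strategy functional similarity between two annotated genes.

    Raises for unannotated genes: their similarity is undefined, not 0.
    """
    terms_a = sorted(t for t in ann.terms_for(gene_a) if t in dag)
    terms_b = sorted(t for t in ann.terms_for(gene_b) if t in dag)
    if not terms_a or not terms_b:
        raise ValueError(
            f"gene similarity undefined: {gene_a!r} or {gene_b!r} has no GO terms"
        )
    cache = {t: s_values(t, dag) for t in set(terms_a) | set(terms_b)}
    best = 0.0
    for ta in terms_a:
        sa = cache[ta]
        sva = sum(sa.values())
        for tb in terms_b:
            sb = cache[tb]
            shared = set(sa) & set(sb)
            if not shared:
                continue
            sim = sum(sa[t] + sb[t] for t in shared) / (sva + sum(sb.values()))
            best = max(best, sim)
    return best


def similarity_matrix(
    genes: Sequence[str], ann: AnnotationSet, dag: GoDag
) -> np.ndarray:
    """Symmetric gene-by-gene similarity matrix (diagonal 1)."""
    n = len(genes)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = gene_similarity(genes[i], genes[j], ann, dag)
    return sim


def functional_cluster(similarity: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage clustering on distance 1 - Sim, cut at k clusters.

    Returns integer labels (0-based) per gene, deterministic under
    scipy's tie handling.
    """
    n = similarity.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n == 1:
        return np.zeros(1, dtype=int)
    # float round-off can push Sim a hair past 1; distances must be >= 0
    dist = np.clip(1.0 - similarity, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust") - 1


def functional_merge_tree(similarity: np.ndarray, genes: Sequence[str]) -> str:
    """Newick rendering of the average-linkage merge tree."""
    if len(genes) == 1:
        return f"({genes[0]});"
    dist = np.clip(1.0 - similarity, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    trees = {i: f"{genes[i]}" for i in range(len(genes))}
    heights = {i: 0.0 for i in range(len(genes))}
    for step, (a, b, h, _cnt) in enumerate(z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        idx = len(genes) + step
        trees[idx] = f"({trees[a]}:{la:.6f},{trees[b]}:{lb:.6f})"
        heights[idx] = h
    return trees[len(genes) + len(z) - 1] + ";"


@dataclass
class FunctionalClusters:
    genes: list[str]
    labels: np.ndarray

    def groups(self) -> list[set[str]]:
        return [
            {g for g, l in zip(self.genes, self.labels) if l == lab}
            for lab in sorted(set(self.labels))
        ]


def cluster_complex_functionally(
    members: Iterable[str],
    ann: AnnotationSet,
    dag: GoDag,
    k: int = 3,
) -> FunctionalClusters:
    """Functionally cluster one complex's subunits into k sub-complexes.

    Subunits without GO annotations cannot be placed and are reported in
    their own singleton clusters appended after the k similarity-based
    clusters.
    """
    members = sorted(members)
    annotated = [g for g in members if any(t in dag for t in ann.terms_for(g))]
    bare = [g for g in members if g not in set(annotated)]
    k = min(k, len(annotated)) if annotated else 0
    labels_all: dict[str, int] = {}
    if annotated:
        sim = similarity_matrix(annotated, ann, dag)
        labels = functional_cluster(sim, k)
        labels_all.update(zip(annotated, labels))
    next_label = (max(labels_all.values()) + 1) if labels_all else 0
    for g in bare:
        labels_all[g] = next_label
        next_label += 1
    return FunctionalClusters(
        genes=members, labels=np.array([labels_all[g] for g in members])
    )


class FunctionalClustering(BaseEstimator, ClusterMixin):
    """Scikit-learn style average-linkage clusterer on 1 - similarity.

    ``fit`` takes a precomputed symmetric similarity matrix in [0, 1];
    the fitted attribute ``labels_`` holds the k-cluster cut.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(X, X.T):
            raise ValueError("similarity matrix must be symmetric")
        self.labels_ = functional_cluster(X, self.n_clusters)
        return self
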