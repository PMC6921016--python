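"""GO term-presence features for gene pairs.

Each pair (i1, i2) is encoded as two sparse vectors over the global term
index G built from the training genes: the *target instance* from the
genes' own annotations and the *homolog instance* from homolog-transferred
annotations.  Component g is 2 if both genes carry term g, 1 if exactly
one does, 0 if neither; terms outside G are discarded.  Annotations are
used as-is, without propagating to ancestor terms, which keeps
inter-feature correlations low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .io import AnnotationSet


@dataclass(frozen=True)
class TermIndex:
    """Ordered (lexicographic) GO term universe G with positions."""

    terms: tuple[str, ...]
    positions: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", {t: i for i, t in enumerate(self.terms)}
        )

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.positions


def build_term_index(
    training_genes: Iterable[str],
    target_ann: AnnotationSet,
    homolog_ann: AnnotationSet,
) -> TermIndex:
    """G = union of target and homolog terms over the training genes.

    The order is lexicographic so model coefficients are reproducible
    across runs.  An empty union is an error (no gene can be encoded).
    """
    terms: set[str] = set()
    for gene in training_genes:
        terms |= target_ann.terms_for(gene)
        terms |= homolog_ann.terms_for(gene)
    if not terms:
        raise ValueError("no GO terms found for any training gene")
    return TermIndex(tuple(sorted(terms)))


def encode_pair(
    pair: Sequence[str], ann: AnnotationSet, index: TermIndex
) -> sparse.csr_matrix:
    """Encode one pair as a 1 x |G| sparse {0,1,2} vector."""
    return encode_pairs([pair], ann, index)


def encode_pairs(
    pairs: Iterable[Sequence[str]], ann: AnnotationSet, index: TermIndex
) -> sparse.csr_matrix:
    """Encode many pairs as a sparse (n_pairs x |G|) matrix.

    A gene with no in-index annotations contributes nothing; a pair where
    neither gene has in-index terms yields an all-zero row (flagged
    upstream as unpredictable, never an error here).
    """
    if len(index) == 0:
        raise ValueError("term index is empty")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    n = 0
    for n, (g1, g2) in enumerate(pairs, start=1):
        t1 = {index.positions[t] for t in ann.terms_for(g1) if t in index}
        t2 = {index.positions[t] for t in ann.terms_for(g2) if t in index}
        for col in t1 | t2:
            rows.append(n - 1)
            cols.append(col)
            vals.append(2 if (col in t1 and col in t2) else 1)
    return sparse.csr_matrix(
        (np.array(vals, dtype=np.float64), (rows, cols)),
        shape=(n, len(index)),
    )


def write_sparse(matrix: sparse.spmatrix, path) -> None:
    """Dump a sparse matrix in coordinate text form (row, col, value)."""
    coo = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# shape\t{coo.shape[0]}\t{coo.shape[1]}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{v:g}\n")


def write_term_index(index: TermIndex, path) -> None:
    with open(path, "w") as fh:
        for i, term in enumerate(index.terms):
            fh.write(f"{i}\t{term}\n")


def read_term_index(path) -> TermIndex:
    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, term = line.split("\t")
            terms.append(term)
    return TermIndex(tuple(terms))
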