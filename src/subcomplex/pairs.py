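"""Training-pair construction for the direct-contact classifier.

Positive pairs are co-complexed gene pairs that are also physical
interactions.  Negative (indirect) pairs are co-complexed pairs that are
*not* physical edges, drawn from two pools defined by the shortest path
between the genes in the physical network:

* ``no-path``   -- no connecting path at all (infinite path length; a gene
  absent from the network is binned here as well);
* ``no-less-than-two`` -- a shortest path of length >= 2 exists.

The two pools are mixed at a ratio ``lambda : 1`` (no-path :
no-less-than-two); the study default is ``lambda = 4``, at which the
negatives are dominated by the more credible no-path pairs.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

DIRECT = "direct"
NO_PATH = "no-path"
NO_LESS_THAN_TWO = "no-less-than-two"


@dataclass(frozen=True)
class PairRecord:
    """An unordered gene pair with its label and provenance.

    The pair is stored in canonical (sorted) order; ``label`` is ``+1``
    for direct contacts, ``-1`` for indirect interactions and ``0`` for
    unlabeled pairs.
    """

    gene_a: str
    gene_b: str
    label: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair genes must be distinct: {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class SamplerConfig:
    """Negative-sampling configuration.

    ``ratio`` is the no-path : no-less-than-two mixing ratio lambda
    (``math.inf`` draws everything from the no-path pool); ``n`` is the
    total number of negatives to draw.
    """

    n: int
    ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.ratio < 0:
            raise ValueError("ratio (lambda) must be >= 0")


def canonical(pair: Iterable[str]) -> tuple[str, str]:
    a, b = pair
    if a == b:
        raise ValueError(f"pair genes must be distinct: {a!r}")
    return (a, b) if a < b else (b, a)


def cocomplex_pairs(complexes: Mapping[str, Iterable[str]]) -> set[tuple[str, str]]:
    """All unordered within-complex gene pairs, deduplicated across complexes."""
    out: set[tuple[str, str]] = set()
    for members in complexes.values():
        members = list(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                out.add(canonical((members[i], members[j])))
    return out


def positive_pairs(
    cocomplex: set[tuple[str, str]],
    physical: nx.Graph,
    exclude: set[tuple[str, str]] | None = None,
) -> set[PairRecord]:
    """Co-complexed pairs that are physical edges, minus *exclude*.

    *exclude* holds curated indirect interactions (and any pairs reserved
    for an independent test set, to keep train/test disjoint).
    """
    exclude = {canonical(p) for p in exclude} if exclude else set()
    out = set()
    for pair in cocomplex:
        if pair in exclude:
            continue
        if physical.has_edge(*pair):
            out.add(PairRecord(*pair, label=+1, provenance="mapped-positive"))
    return out


def path_class(pair: Iterable[str], physical: nx.Graph) -> str:
    """Classify a pair by shortest path in the (unweighted) physical network.

    Returns ``direct`` (the edge exists), ``no-path`` (different
    components, or either gene absent from the network) or
    ``no-less-than-two`` (a shortest path of length >= 2 exists).
    """
    a, b = canonical(pair)
    if a not in physical or b not in physical:
        return NO_PATH
    if physical.has_edge(a, b):
        return DIRECT
    if nx.has_path(physical, a, b):
        return NO_LESS_THAN_TWO
    return NO_PATH


def negative_pools(
    cocomplex: set[tuple[str, str]],
    physical: nx.Graph,
    exclude: set[tuple[str, str]] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Candidate (no-path, no-less-than-two) pools, sorted for determinism."""
    exclude = {canonical(p) for p in exclude} if exclude else set()
    no_path: list[tuple[str, str]] = []
    nltt: list[tuple[str, str]] = []
    for pair in sorted(cocomplex):
        if pair in exclude:
            continue
        cls = path_class(pair, physical)
        if cls == NO_PATH:
            no_path.append(pair)
        elif cls == NO_LESS_THAN_TWO:
            nltt.append(pair)
    return no_path, nltt


def split_counts(n: int, ratio: float) -> tuple[int, int]:
    """Target draw counts (no-path, no-less-than-two) for ratio lambda.

    The no-path count is ``round(n * lambda / (lambda + 1))``; the
    remainder goes to the no-less-than-two pool.  ``lambda = inf`` sends
    everything to the no-path pool.
    """
    if math.isinf(ratio):
        return n, 0
    n_no_path = round(n * ratio / (ratio + 1.0))
    return n_no_path, n - n_no_path


def sample_negatives(
    cocomplex: set[tuple[str, str]],
    physical: nx.Graph,
    cfg: SamplerConfig,
    exclude: set[tuple[str, str]] | None = None,
) -> set[PairRecord]:
    """Draw ``cfg.n`` indirect pairs at ratio lambda from the two pools.

    Sampling is uniform without replacement within each pool and
    reproducible under ``cfg.seed``.  If one pool cannot cover its quota
    the deficit is drawn from the other pool with a logged warning; if
    both pools together are too small an error reports the pool sizes.
    """
    no_path_pool, nltt_pool = negative_pools(cocomplex, physical, exclude)
    if len(no_path_pool) + len(nltt_pool) < cfg.n:
        raise ValueError(
            f"cannot draw {cfg.n} negatives: no-path pool has "
            f"{len(no_path_pool)} pairs, no-less-than-two pool has "
            f"{len(nltt_pool)} pairs"
        )
    want_np, want_nltt = split_counts(cfg.n, cfg.ratio)
    take_np = min(want_np, len(no_path_pool))
    take_nltt = min(want_nltt, len(nltt_pool))
    # redistribute any deficit to the other pool
    deficit = cfg.n - take_np - take_nltt
    if deficit > 0:
        if take_np < want_np:
            extra = min(deficit, len(nltt_pool) - take_nltt)
            take_nltt += extra
        else:
            extra = min(deficit, len(no_path_pool) - take_np)
            take_np += extra
        logger.warning(
            "negative pool exhausted: drawing %d/%d no-path and %d/%d "
            "no-less-than-two pairs (requested ratio %s)",
            take_np,
            want_np,
            take_nltt,
            want_nltt,
            cfg.ratio,
        )
    rng = random.Random(cfg.seed)
    drawn_np = rng.sample(no_path_pool, take_np)
    drawn_nltt = rng.sample(nltt_pool, take_nltt)
    out = {
        PairRecord(*p, label=-1, provenance=NO_PATH) for p in drawn_np
    }
    out |= {
        PairRecord(*p, label=-1, provenance=NO_LESS_THAN_TWO) for p in drawn_nltt
    }
    return out


def write_pairs(records: Iterable[PairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# geneA\tgeneB\tlabel\tprovenance\n")
        for rec in sorted(records, key=lambda r: (r.gene_a, r.gene_b)):
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.label:+d}\t{rec.provenance}\n")


def read_pairs(path) -> list[PairRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, label, prov = line.split("\t")
            out.append(PairRecord(a, b, label=int(label), provenance=prov))
    return out
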