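"""Readers and writers for the formats the framework touches.

Gene identifiers are opaque, case-sensitive strings throughout: no
symbol/accession mapping is attempted.  The in-memory data model is

* :class:`GoDag` -- the Gene Ontology as a directed acyclic graph with
  child->parent edges typed ``is_a`` or ``part_of`` (the only two
  relations the semantic-similarity weights are defined for);
* :class:`AnnotationSet` -- gene -> set of GO term ids, tagged as
  ``target`` (the gene's own annotations) or ``homolog`` (annotations
  transferred from homologs, supplied precomputed);
* plain :class:`networkx.Graph` for undirected, non-negatively weighted
  physical-interaction networks;
* a ``dict[str, list[str]]`` for complex membership tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO relations ingested into the DAG; all others (regulates, occurs_in,
#: ...) are dropped because the semantic-similarity edge weights are
#: defined only for these two.
SUPPORTED_RELATIONS = ("is_a", "part_of")

#: Complexes smaller than this are dropped from substructure analysis.
MIN_COMPLEX_SIZE = 3


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class GoDag:
    """Gene Ontology terms with typed child->parent edges.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child
    to parent and carry a ``relation`` attribute (``is_a`` or
    ``part_of``).  Obsolete terms are never present.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of *term*."""
        return [
            (parent, data["relation"])
            for _, parent, data in self.graph.out_edges(term, data=True)
        ]

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def add_term(self, term: str, namespace: str | None = None) -> None:
        self.graph.add_node(term, namespace=namespace)

    def add_edge(self, child: str, parent: str, relation: str) -> None:
        if relation not in SUPPORTED_RELATIONS:
            raise ValueError(f"unsupported relation {relation!r}")
        self.graph.add_edge(child, parent, relation=relation)

    def validate(self) -> None:
        """Check the structural invariants (acyclicity, known relations)."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"GO relations contain a cycle: {cycle}")
        for child, parent, data in self.graph.edges(data=True):
            if data.get("relation") not in SUPPORTED_RELATIONS:
                raise FormatError(
                    f"edge {child}->{parent} has unsupported relation "
                    f"{data.get('relation')!r}"
                )


@dataclass
class AnnotationSet:
    """Mapping gene id -> set of GO term ids, tagged by provenance kind."""

    mapping: dict[str, set[str]] = field(default_factory=dict)
    kind: str = "target"

    def __post_init__(self) -> None:
        if self.kind not in ("target", "homolog"):
            raise ValueError(f"kind must be 'target' or 'homolog', got {self.kind!r}")

    def terms_for(self, gene: str) -> set[str]:
        return self.mapping.get(gene, set())

    def genes(self) -> set[str]:
        return set(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def restrict_to_dag(self, dag: GoDag) -> "AnnotationSet":
        """Drop term ids that do not resolve in *dag* (logged)."""
        dropped = 0
        cleaned: dict[str, set[str]] = {}
        for gene, terms in self.mapping.items():
            kept = {t for t in terms if t in dag}
            dropped += len(terms) - len(kept)
            if kept:
                cleaned[gene] = kept
        if dropped:
            logger.info("dropped %d annotations to unknown GO terms", dropped)
        return AnnotationSet(cleaned, self.kind)


def less_studied_genes(
    genes: Iterable[str], target: AnnotationSet, homolog: AnnotationSet
) -> set[str]:
    """Genes with neither own nor homolog-transferred GO terms.

    Such genes yield all-zero feature vectors for both instances and are
    reported as unpredictable downstream.
    """
    return {
        g
        for g in genes
        if not target.terms_for(g) and not homolog.terms_for(g)
    }


# ---------------------------------------------------------------------------
# OBO


def read_obo(path: str | Path) -> GoDag:
    """Parse an OBO flat file into a :class:`GoDag`.

    Only ``is_a`` and ``part_of`` edges are kept; obsolete terms are
    excluded.  A cyclic set of relations raises :class:`FormatError`.
    """
    try:
        multigraph = obonet.read_obo(str(path), ignore_obsolete=True)
    except (ValueError, KeyError) as exc:  # pragma: no cover - passthrough
        raise FormatError(f"malformed OBO file {path}: {exc}") from exc

    dag = GoDag()
    for term, data in multigraph.nodes(data=True):
        dag.add_term(term, namespace=data.get("namespace"))
    for child, parent, key in multigraph.edges(keys=True):
        if key in SUPPORTED_RELATIONS:
            dag.add_edge(child, parent, key)
    dag.validate()
    return dag


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Write a minimal OBO flat file round-trippable by :func:`read_obo`."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            ns = dag.namespace(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent, relation in sorted(dag.parents(term)):
                if relation == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


# ---------------------------------------------------------------------------
# Annotations (GAF 2.x or two-column TSV)


def read_annotations(path: str | Path, kind: str = "target") -> AnnotationSet:
    """Read gene->GO annotations from GAF 2.x or a gene<TAB>term table.

    GAF rows carrying a ``NOT`` qualifier are skipped.  The format is
    sniffed from the header: a leading ``!gaf-version`` line selects GAF.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        mapping = _read_gaf(path)
    else:
        mapping = _read_two_column(path)
    if not mapping:
        logger.warning("annotation file %s is empty", path)
    return AnnotationSet(mapping, kind)


def _read_gaf(path: Path) -> dict[str, set[str]]:
    from Bio.UniProt.GOA import gafiterator

    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for record in gafiterator(fh):
            if "NOT" in record.get("Qualifier", []):
                continue
            gene = record["DB_Object_Symbol"] or record["DB_Object_ID"]
            mapping.setdefault(gene, set()).add(record["GO_ID"])
    return mapping


def _read_two_column(path: Path) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'gene<TAB>term', got {line!r}"
                )
            gene, term = fields
            mapping.setdefault(gene, set()).add(term)
    return mapping


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.mapping):
            for term in sorted(ann.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Networks (whitespace/TSV edge lists)


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected edge list ``geneA geneB [weight]``.

    Self-loop rows are dropped with a warning; duplicate edges keep the
    maximum weight so that merging multi-source interaction files is
    idempotent.
    """
    net = nx.Graph()
    dropped_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected 'geneA geneB [weight]', got {line!r}"
                )
            u, v = fields[0], fields[1]
            w = float(fields[2]) if len(fields) == 3 else 1.0
            if w < 0:
                raise FormatError(f"{path}:{lineno}: negative weight {w}")
            if u == v:
                dropped_loops += 1
                continue
            if net.has_edge(u, v):
                net[u][v]["weight"] = max(net[u][v]["weight"], w)
            else:
                net.add_edge(u, v, weight=w)
    if dropped_loops:
        logger.warning("dropped %d self-loop rows from %s", dropped_loops, path)
    return net


def write_network(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in net.edges(data=True))
        ):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):g}\n")


# ---------------------------------------------------------------------------
# Complex membership tables


def read_complexes(
    path: str | Path, min_size: int | None = MIN_COMPLEX_SIZE
) -> dict[str, list[str]]:
    """Read a ``complexId<TAB>gene`` table into complex -> subunit lists.

    Subunit lists are deduplicated (first occurrence kept).  Complexes
    with fewer than *min_size* subunits are dropped; pass ``None`` to
    keep everything.
    """
    raw: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'complexId gene', got {line!r}"
                )
            cid, gene = fields
            members = raw.setdefault(cid, [])
            if gene not in members:
                members.append(gene)
    if min_size is None:
        return raw
    kept = {cid: genes for cid, genes in raw.items() if len(genes) >= min_size}
    if len(kept) < len(raw):
        logger.info(
            "dropped %d complexes with fewer than %d subunits",
            len(raw) - len(kept),
            min_size,
        )
    return kept


def write_complexes(complexes: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(complexes):
            for gene in complexes[cid]:
                fh.write(f"{cid}\t{gene}\n")
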