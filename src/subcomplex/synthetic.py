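"""Fully in-silico fixtures with the statistical structure the method assumes.

The generated world mimics, at desk scale, the data a practitioner would
assemble from complex databases, an interactome and GO:

* a random GO DAG: one root, "interaction-machinery" and "generic"
  term families, an optional subfamily level, and per-gene leaf terms;
  edges are is-a / part-of mixed at a configurable rate;
* complexes of two architectures.  *Fully connected* complexes (small,
  the majority) have every subunit pair in direct contact and carry
  ``groups_per_fully`` planted functional groups, each sharing signature
  GO terms -- topology is uninformative there and substructure lives in
  the annotations.  *Partially connected* complexes (larger) follow a
  core-attachment architecture: a dense core (within-core contact
  probability ``p_in``) plus peripheral subunits that rarely touch the
  core (``p_out``) and are mostly absent from the interactome, which
  populates the no-path negative pool; within-core non-edges populate
  the no-less-than-two pool;
* gene annotations that make direct contact *learnable by an additive
  model*: contact-prone (core / fully-complex) genes carry more terms,
  drawn from the interaction families, while peripheral genes carry few
  generic-family terms.  The homolog annotation set is the target set
  with configurable dropout and random term insertion, emulating noisy
  homology transfer;
* a background interactome: the true contact edges plus a random graph
  over extra non-complex genes.

Reference sub-complexes (the clustering ground truth) are the core of
each partially connected complex and the functional groups of each
fully connected complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import AnnotationSet, GoDag, write_annotations, write_complexes, write_network, write_obo
from .pairs import PairRecord, canonical, cocomplex_pairs

GO_ROOT = "GO:0000001"


@dataclass
class SyntheticConfig:
    """Knobs of the generated world (defaults = the study conditions)."""

    n_complexes: int = 50
    fully_fraction: float = 0.6
    #: truncated-geometric size draws: (min, max, success prob)
    fully_size: tuple[int, int, float] = (3, 12, 0.35)
    partial_size: tuple[int, int, float] = (8, 40, 0.15)
    groups_per_fully: int = 3
    periphery_fraction: float = 0.4
    p_in: float = 0.8
    p_out: float = 0.02
    #: ontology shape
    n_interaction_families: int = 6
    n_generic_families: int = 6
    subfamilies_per_family: int = 2
    is_a_fraction: float = 0.7
    #: annotation richness (Poisson means, plus one guaranteed term)
    terms_per_active_gene: float = 4.0
    terms_per_passive_gene: float = 1.0
    signature_terms_per_group: int = 2
    #: homolog transfer noise
    homolog_dropout: float = 0.2
    homolog_noise: float = 0.5
    #: background interactome
    n_background_genes: int = 30
    background_edge_prob: float = 0.1
    #: required separation between direct-contact rates of
    #: signature-sharing vs non-sharing co-complexed pairs
    effect_size: float = 0.5


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    seed: int
    dag: GoDag
    genes: list[str]
    target_ann: AnnotationSet
    homolog_ann: AnnotationSet
    complexes: dict[str, list[str]]
    #: planted reference sub-complexes per complex
    subcomplexes: dict[str, list[list[str]]]
    #: architecture actually planted ("fully" / "partially")
    architecture: dict[str, str]
    true_contacts: nx.Graph
    interactome: nx.Graph
    signature_terms: dict[str, set[str]] = field(default_factory=dict)

    def signature_effect(self) -> tuple[float, float]:
        """Direct-contact rate among signature-sharing vs non-sharing pairs."""
        sharing = [0, 0]
        non_sharing = [0, 0]
        for a, b in cocomplex_pairs(self.complexes):
            shares = bool(
                self.signature_terms.get(a, set())
                & self.signature_terms.get(b, set())
            )
            bucket = sharing if shares else non_sharing
            bucket[0] += int(self.true_contacts.has_edge(a, b))
            bucket[1] += 1
        rate = lambda b: b[0] / b[1] if b[1] else float("nan")
        return rate(sharing), rate(non_sharing)


def _truncated_geometric(rng: np.random.Generator, lo: int, hi: int, p: float) -> int:
    """lo + Geometric(p) - 1, redrawn into [lo, hi]."""
    while True:
        size = lo + int(rng.geometric(p)) - 1
        if size <= hi:
            return size


class _Ontology:
    """Incrementally grown random GO DAG."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.dag = GoDag()
        self._counter = 1
        self.dag.add_term(GO_ROOT, namespace="biological_process")
        self.interaction_parents: list[str] = []
        self.generic_parents: list[str] = []
        for kind, n in (
            ("interaction", cfg.n_interaction_families),
            ("generic", cfg.n_generic_families),
        ):
            for _ in range(n):
                family = self._new_term(GO_ROOT, relation="is_a")
                parents = [family]
                for _ in range(cfg.subfamilies_per_family):
                    parents.append(self._new_term(family))
                target = (
                    self.interaction_parents
                    if kind == "interaction"
                    else self.generic_parents
                )
                target.extend(parents)

    def _new_term(self, parent: str, relation: str | None = None) -> str:
        self._counter += 1
        term = f"GO:{self._counter:07d}"
        if relation is None:
            relation = (
                "is_a"
                if self.rng.random() < self.cfg.is_a_fraction
                else "part_of"
            )
        self.dag.add_term(term, namespace="biological_process")
        self.dag.add_edge(term, parent, relation)
        return term

    def leaf(self, active: bool) -> str:
        pool = self.interaction_parents if active else self.generic_parents
        parent = pool[int(self.rng.integers(len(pool)))]
        return self._new_term(parent)


def generate(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    validate: bool = True,
) -> SyntheticWorld:
    """Build a reproducible synthetic world.

    A single world seed derives fixed per-stage seeds (ontology,
    complex architecture, contacts, annotations, homolog transfer,
    background interactome), so each stage is locally reproducible.
    With ``validate`` (the default) a configuration that empties either
    negative-sampling pool is rejected; switch it off for degenerate
    worlds built on purpose, e.g. pure disjoint-clique contact networks
    (``p_in=1, p_out=0``), which leave no within-core non-edges.
    """
    cfg = config or SyntheticConfig()
    rng_onto = np.random.default_rng(seed * 10 + 1)
    rng_arch = np.random.default_rng(seed * 10 + 2)
    rng_edges = np.random.default_rng(seed * 10 + 3)
    rng_ann = np.random.default_rng(seed * 10 + 4)
    rng_hom = np.random.default_rng(seed * 10 + 5)
    rng_bg = np.random.default_rng(seed * 10 + 6)

    onto = _Ontology(cfg, rng_onto)

    genes: list[str] = []
    complexes: dict[str, list[str]] = {}
    subcomplexes: dict[str, list[list[str]]] = {}
    architecture: dict[str, str] = {}
    active: dict[str, bool] = {}
    groups: list[list[str]] = []  # planted groups needing signature terms

    def new_gene(is_active: bool) -> str:
        gene = f"G{len(genes):05d}"
        genes.append(gene)
        active[gene] = is_active
        return gene

    contacts = nx.Graph()
    for c in range(cfg.n_complexes):
        cid = f"CPX{c:04d}"
        fully = rng_arch.random() < cfg.fully_fraction
        architecture[cid] = "fully" if fully else "partially"
        if fully:
            size = _truncated_geometric(rng_arch, *cfg.fully_size)
            members = [new_gene(True) for _ in range(size)]
            # every pair in direct contact
            for i in range(size):
                for j in range(i + 1, size):
                    contacts.add_edge(members[i], members[j])
            # planted functional groups (balanced random split)
            k = min(cfg.groups_per_fully, size)
            order = list(rng_arch.permutation(size))
            planted = [sorted(members[i] for i in order[g::k]) for g in range(k)]
            subcomplexes[cid] = planted
            groups.extend(planted)
        else:
            size = _truncated_geometric(rng_arch, *cfg.partial_size)
            n_periph = max(1, round(cfg.periphery_fraction * size))
            n_core = size - n_periph
            core = [new_gene(True) for _ in range(n_core)]
            periphery = [new_gene(False) for _ in range(n_periph)]
            members = core + periphery
            for i in range(n_core):
                for j in range(i + 1, n_core):
                    if rng_edges.random() < cfg.p_in:
                        contacts.add_edge(core[i], core[j])
            for u in core:
                for v in periphery:
                    if rng_edges.random() < cfg.p_out:
                        contacts.add_edge(u, v)
            subcomplexes[cid] = [sorted(core)]
            groups.append(sorted(core))
        complexes[cid] = members
    contacts.add_nodes_from(
        g for g, is_active in active.items() if is_active
    )

    # annotations: unique leaf terms per gene, richer for contact-prone genes
    target: dict[str, set[str]] = {}
    signature_terms: dict[str, set[str]] = {}
    for gene in genes:
        mean = cfg.terms_per_active_gene if active[gene] else cfg.terms_per_passive_gene
        n_terms = 1 + int(rng_ann.poisson(mean))
        target[gene] = {onto.leaf(active[gene]) for _ in range(n_terms)}
    for group in groups:
        sigs = {
            onto.leaf(True) for _ in range(cfg.signature_terms_per_group)
        }
        for gene in group:
            target[gene] |= sigs
            signature_terms.setdefault(gene, set()).update(sigs)

    # homolog transfer: dropout + random insertions from existing leaves
    all_terms = sorted(t for g in genes for t in target[g])
    homolog: dict[str, set[str]] = {}
    for gene in genes:
        kept = {
            t for t in target[gene] if rng_hom.random() >= cfg.homolog_dropout
        }
        n_noise = int(rng_hom.poisson(cfg.homolog_noise))
        for _ in range(n_noise):
            kept.add(all_terms[int(rng_hom.integers(len(all_terms)))])
        if kept:
            homolog[gene] = kept

    # background interactome over extra, non-complex genes
    interactome = contacts.copy()
    bg_genes = [f"B{i:05d}" for i in range(cfg.n_background_genes)]
    for i in range(len(bg_genes)):
        for j in range(i + 1, len(bg_genes)):
            if rng_bg.random() < cfg.background_edge_prob:
                interactome.add_edge(bg_genes[i], bg_genes[j])

    world = SyntheticWorld(
        config=cfg,
        seed=seed,
        dag=onto.dag,
        genes=genes,
        target_ann=AnnotationSet(target, "target"),
        homolog_ann=AnnotationSet(homolog, "homolog"),
        complexes=complexes,
        subcomplexes=subcomplexes,
        architecture=architecture,
        true_contacts=contacts,
        interactome=interactome,
        signature_terms=signature_terms,
    )
    if validate:
        _validate_pools(world)
    return world


def _validate_pools(world: SyntheticWorld) -> None:
    from .pairs import negative_pools

    no_path, nltt = negative_pools(
        cocomplex_pairs(world.complexes), world.interactome
    )
    if not no_path or not nltt:
        raise ValueError(
            "synthetic config leaves a negative pool empty "
            f"(no-path={len(no_path)}, no-less-than-two={len(nltt)}); "
            "increase complex sizes or lower p_in/p_out"
        )


def truth_tables(
    world: SyntheticWorld,
) -> tuple[list[PairRecord], dict[str, list[list[str]]]]:
    """Gold-standard pair labels and reference sub-complex memberships.

    Every co-complexed pair is labeled +1 (direct contact) or -1
    (indirect) from the planted contact network.
    """
    records = []
    for a, b in sorted(cocomplex_pairs(world.complexes)):
        direct = world.true_contacts.has_edge(a, b)
        records.append(
            PairRecord(a, b, label=+1 if direct else -1, provenance="truth")
        )
    return records, world.subcomplexes


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write the world as the plain-text files the CLI stages consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_obo(world.dag, outdir / "ontology.obo")
    write_annotations(world.target_ann, outdir / "target.tsv")
    write_annotations(world.homolog_ann, outdir / "homolog.tsv")
    write_network(world.interactome, outdir / "interactome.tsv")
    write_complexes(world.complexes, outdir / "complexes.tsv")
    records, refs = truth_tables(world)
    from .pairs import write_pairs

    write_pairs(records, outdir / "truth_pairs.tsv")
    with open(outdir / "truth_subcomplexes.tsv", "w") as fh:
        fh.write("# complex\tgroup\tgene\n")
        for cid in sorted(refs):
            for gi, group in enumerate(refs[cid]):
                for gene in group:
                    fh.write(f"{cid}\t{gi}\t{gene}\n")
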