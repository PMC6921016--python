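import numpy as np
import pytest

from conftest import make_dag
from oracles import s_values_by_path_enumeration
from subcomplex.gosim import (
    FunctionalClustering,
    cluster_complex_functionally,
    functional_cluster,
    gene_similarity,
    s_values,
    semantic_value,
    similarity_matrix,
    term_similarity,
)
from subcomplex.io import AnnotationSet, GoDag


def ann(mapping):
    return AnnotationSet({g: set(t) for g, t in mapping.items()}, "target")


class TestSValues:
    def test_single_is_a_parent(self):
        dag = make_dag([("A", "R", "is_a")])
        assert s_values("A", dag) == {"A": 1.0, "R": pytest.approx(0.8)}

    def test_part_of_then_is_a_chain(self):
        dag = make_dag([("A", "P", "part_of"), ("P", "R", "is_a")])
        sv = s_values("A", dag)
        assert sv["P"] == pytest.approx(0.6)
        assert sv["R"] == pytest.approx(0.48)

    def test_diamond_takes_max_over_paths(self):
        dag = make_dag([
            ("A", "X", "is_a"), ("A", "Y", "part_of"),
            ("X", "R", "is_a"), ("Y", "R", "is_a"),
        ])
        sv = s_values("A", dag)
        assert sv["R"] == pytest.approx(max(0.8 * 0.8, 0.6 * 0.8))

    def test_unknown_term_raises(self):
        dag = make_dag([("A", "R", "is_a")])
        with pytest.raises(KeyError):
            s_values("Z", dag)

    def test_matches_path_enumeration_on_random_dags(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            dag = GoDag()
            names = [f"T{i}" for i in range(n)]
            for name in names:
                dag.add_term(name)
            for i in range(1, n):
                for parent in rng.choice(i, size=min(i, 2), replace=False):
                    rel = "is_a" if rng.random() < 0.7 else "part_of"
                    dag.add_edge(names[i], names[int(parent)], rel)
            term = names[-1]
            expected = s_values_by_path_enumeration(term, dag)
            assert s_values(term, dag) == pytest.approx(expected, abs=1e-12)


class TestSemanticValue:
    def test_root_alone(self):
        dag = make_dag([], extra_terms=["R"])
        assert semantic_value("R", dag) == 1.0

    def test_one_is_a_level(self):
        dag = make_dag([("A", "R", "is_a")])
        assert semantic_value("A", dag) == pytest.approx(1.8)

    def test_two_is_a_levels(self):
        dag = make_dag([("A", "B", "is_a"), ("B", "R", "is_a")])
        assert semantic_value("A", dag) == pytest.approx(1 + 0.8 + 0.64)


class TestTermSimilarity:
    def test_self_similarity_is_one(self):
        dag = make_dag([("A", "R", "is_a")])
        assert term_similarity("A", "A", dag) == pytest.approx(1.0)

    def test_siblings_under_shared_root(self):
        dag = make_dag([("A", "R", "is_a"), ("B", "R", "is_a")])
        assert term_similarity("A", "B", dag) == pytest.approx(
            (0.8 + 0.8) / (1.8 + 1.8)
        )  # 4/9

    def test_disjoint_components_similarity_zero(self):
        dag = make_dag([("A", "R1", "is_a"), ("B", "R2", "is_a")])
        assert term_similarity("A", "B", dag) == 0.0

    def test_symmetric_and_bounded_on_random_dags(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            dag = GoDag()
            names = [f"T{i}" for i in range(n)]
            for name in names:
                dag.add_term(name)
            for i in range(1, n):
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                dag.add_edge(names[i], names[int(rng.integers(i))], rel)
            a, b = names[-1], names[-2]
            s_ab = term_similarity(a, b, dag)
            assert s_ab == pytest.approx(term_similarity(b, a, dag), abs=1e-12)
            assert 0.0 <= s_ab <= 1.0 + 1e-12


class TestGeneSimilarity:
    def test_shared_term_gives_one(self):
        dag = make_dag([("A", "R", "is_a"), ("B", "R", "is_a")])
        a = ann({"g1": ["A", "B"], "g2": ["A"]})
        assert gene_similarity("g1", "g2", a, dag) == pytest.approx(1.0)

    def test_single_cross_pair(self):
        dag = make_dag([("A", "R", "is_a"), ("B", "R", "is_a")])
        a = ann({"g1": ["A"], "g2": ["B"]})
        assert gene_similarity("g1", "g2", a, dag) == pytest.approx(4 / 9)

    def test_max_over_cross_pairs(self):
        dag = make_dag([("A", "R", "is_a"), ("B", "R", "is_a")])
        a = ann({"g1": ["A", "R"], "g2": ["B"]})
        expected = max(
            term_similarity("A", "B", dag), term_similarity("R", "B", dag)
        )
        assert gene_similarity("g1", "g2", a, dag) == pytest.approx(expected)

    def test_unannotated_gene_is_undefined(self):
        dag = make_dag([("A", "R", "is_a")])
        with pytest.raises(ValueError, match="undefined"):
            gene_similarity("g1", "g2", ann({"g1": ["A"]}), dag)

    def test_adding_annotations_never_decreases_similarity(self):
        dag = make_dag([
            ("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "R", "part_of"),
        ])
        base = ann({"g1": ["A"], "g2": ["B"]})
        richer = ann({"g1": ["A", "C"], "g2": ["B"]})
        assert gene_similarity("g1", "g2", richer, dag) >= gene_similarity(
            "g1", "g2", base, dag
        )


class TestFunctionalClustering:
    def planted_two_groups(self):
        dag = make_dag([
            ("S1", "R", "is_a"), ("S2", "R", "is_a"),
            ("L1", "S1", "is_a"), ("L2", "S1", "is_a"),
            ("L3", "S2", "is_a"), ("L4", "S2", "is_a"),
        ])
        a = ann({
            "g1": ["L1"], "g2": ["L1", "L2"],   # group 1 shares L1
            "g3": ["L3"], "g4": ["L3", "L4"],   # group 2 shares L3
        })
        return dag, a

    def test_planted_groups_recovered_exactly(self):
        dag, a = self.planted_two_groups()
        genes = ["g1", "g2", "g3", "g4"]
        sim = similarity_matrix(genes, a, dag)
        labels = functional_cluster(sim, k=2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_trivial_cuts(self):
        dag, a = self.planted_two_groups()
        sim = similarity_matrix(["g1", "g2", "g3", "g4"], a, dag)
        assert len(set(functional_cluster(sim, k=4))) == 4
        assert len(set(functional_cluster(sim, k=1))) == 1
        with pytest.raises(ValueError):
            functional_cluster(sim, k=5)

    def test_estimator_wrapper(self):
        dag, a = self.planted_two_groups()
        sim = similarity_matrix(["g1", "g2", "g3", "g4"], a, dag)
        est = FunctionalClustering(n_clusters=2).fit(sim)
        assert len(set(est.labels_)) == 2

    def test_unannotated_members_become_singletons(self):
        dag, a = self.planted_two_groups()
        fc = cluster_complex_functionally(
            ["g1", "g2", "g3", "g4", "bare"], a, dag, k=2
        )
        groups = fc.groups()
        assert {"bare"} in groups
        assert len(groups) == 3
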