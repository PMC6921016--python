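import math

import numpy as np
import pytest

from oracles import grid_minimize_logistic, logistic_objective
from subcomplex.classifier import (
    DirectContactClassifier,
    combine_margins,
    label_from_value,
    predict_complex_network,
    train,
)
from subcomplex.io import AnnotationSet
from subcomplex.pairs import PairRecord


def ann(mapping, kind="target"):
    return AnnotationSet({g: set(t) for g, t in mapping.items()}, kind)


def toy_problem():
    """Six pairs over two GO terms; homolog knowledge absent.

    Target-instance design matrix (term order t1, t2):
        (2,0)+1  (0,2)-1  (1,1)+1  (0,2)-1  (2,0)+1  (1,1)-1
    """
    target = {}
    rows = [
        (("A1", "A2"), ["t1"], ["t1"], +1),
        (("B1", "B2"), ["t2"], ["t2"], -1),
        (("C1", "C2"), ["t1"], ["t2"], +1),
        (("D1", "D2"), ["t2"], ["t2"], -1),
        (("E1", "E2"), ["t1"], ["t1"], +1),
        (("F1", "F2"), ["t1"], ["t2"], -1),
    ]
    X, y = [], []
    for (g1, g2), t1, t2, label in rows:
        target[g1], target[g2] = set(t1), set(t2)
        X.append([g1, g2])
        y.append(label)
    return ann(target), X, y


class TestTraining:
    def test_objective_matches_grid_search_oracle(self):
        target, X, y = toy_problem()
        c = 1.0
        model = DirectContactClassifier(target, tol=1e-10, C=c).fit(X, y)
        x_mat = np.array(
            [[2, 0], [0, 2], [1, 1], [0, 2], [2, 0], [1, 1]], dtype=float
        )
        y_vec = np.array(y, dtype=float)
        fitted = logistic_objective(
            model.coef_, float(model.intercept_[0]), x_mat, y_vec, c
        )
        oracle = grid_minimize_logistic(x_mat, y_vec, c)
        assert abs(fitted - oracle) <= 1e-4

    def test_vanishing_c_shrinks_weights_to_zero(self):
        target, X, y = toy_problem()
        model = DirectContactClassifier(target, C=1e-6, tol=1e-10).fit(X, y)
        assert np.linalg.norm(model.coef_) < 1e-3

    def test_duplicated_training_set_equals_halved_c(self):
        target, X, y = toy_problem()
        base = DirectContactClassifier(target, C=1.0, tol=1e-10).fit(X, y)
        doubled = DirectContactClassifier(target, C=0.5, tol=1e-10).fit(
            X + X, y + y
        )
        np.testing.assert_allclose(doubled.coef_, base.coef_, atol=1e-4)
        np.testing.assert_allclose(doubled.intercept_, base.intercept_, atol=1e-4)

    def test_single_class_input_raises(self):
        target, X, y = toy_problem()
        keep = [i for i, label in enumerate(y) if label == 1]
        with pytest.raises(ValueError, match="both classes"):
            DirectContactClassifier(target).fit(
                [X[i] for i in keep], [1] * len(keep)
            )

    def test_sklearn_params_round_trip(self):
        model = DirectContactClassifier(C=2.0, delta=0.1)
        params = model.get_params()
        assert params["C"] == 2.0 and params["delta"] == 0.1
        model.set_params(C=3.0)
        assert model.C == 3.0


class TestDecisionCombination:
    @pytest.mark.parametrize(
        "m_t,m_h,delta,value,label",
        [
            (0.42, 0.10, 0.1, 0.42, +1),   # target dominates, passes delta
            (0.05, -0.03, 0.1, 0.05, 0),   # neither branch passes -> undetermined
            (0.0, 0.0, 0.0, 0.0, 0),       # zero margins undetermined at any delta
            (0.10, -0.30, 0.1, -0.30, -1), # homolog wins on magnitude
            (0.20, -0.20, 0.1, 0.20, +1),  # exact tie -> target instance wins
            (math.nan, 0.30, 0.1, 0.30, +1),  # all-zero target: homolog substitutes
            (math.nan, math.nan, 0.0, math.nan, 0),  # unpredictable pair
        ],
    )
    def test_combination_and_thresholding(self, m_t, m_h, delta, value, label):
        combined = combine_margins(m_t, m_h)
        if math.isnan(value):
            assert math.isnan(combined)
        else:
            assert combined == pytest.approx(value)
        assert label_from_value(combined, delta) == label

    def test_combined_value_is_one_of_the_instance_values(self, world):
        from subcomplex.pairs import cocomplex_pairs, positive_pairs, sample_negatives, SamplerConfig

        cocomplex = cocomplex_pairs(world.complexes)
        pos = positive_pairs(cocomplex, world.interactome)
        neg = sample_negatives(
            cocomplex, world.interactome, SamplerConfig(n=len(pos), ratio=4, seed=0)
        )
        records = sorted(pos | neg, key=lambda r: r.pair)[:400]
        model = train(records, world.target_ann, world.homolog_ann, seed=0)
        for rec in records[:50]:
            d = model.decide(rec.pair)
            assert d.value in (d.m_target, d.m_homolog)
            assert abs(d.value) == max(
                abs(v) for v in (d.m_target, d.m_homolog) if not math.isnan(v)
            )


class TestPredictComplexNetwork:
    def separable_model(self):
        # t_pos marks interacting genes, t_neg non-interacting ones
        target = {f"p{i}": {"t_pos"} for i in range(6)}
        target.update({f"n{i}": {"t_neg"} for i in range(6)})
        X = [[f"p{2*i}", f"p{2*i+1}"] for i in range(3)]
        X += [[f"n{2*i}", f"n{2*i+1}"] for i in range(3)]
        y = [1, 1, 1, -1, -1, -1]
        return ann(target), X, y

    def test_all_positive_model_gives_complete_graph(self):
        target, X, y = self.separable_model()
        model = DirectContactClassifier(target, C=10.0).fit(X, y)
        members = ["p0", "p1", "p2", "p3"]
        net = predict_complex_network(members, model)
        assert net.number_of_edges() == 6  # K4

    def test_oversized_delta_empties_the_network(self):
        target, X, y = self.separable_model()
        model = DirectContactClassifier(target, C=10.0).fit(X, y)
        net = predict_complex_network(["p0", "p1", "p2", "p3"], model, delta=0.49999)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"p0", "p1", "p2", "p3"}

    def test_raising_delta_never_adds_edges(self, world):
        from subcomplex.pairs import cocomplex_pairs, positive_pairs, sample_negatives, SamplerConfig

        cocomplex = cocomplex_pairs(world.complexes)
        pos = positive_pairs(cocomplex, world.interactome)
        neg = sample_negatives(
            cocomplex, world.interactome, SamplerConfig(n=len(pos), ratio=4, seed=0)
        )
        records = sorted(pos | neg, key=lambda r: r.pair)
        model = train(records, world.target_ann, world.homolog_ann, seed=0)
        members = next(
            m for cid, m in sorted(world.complexes.items()) if len(m) >= 5
        )
        previous = None
        for delta in (0.0, 0.1, 0.2, 0.3, 0.4, 0.49):
            edges = set(predict_complex_network(members, model, delta=delta).edges)
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_too_small_complex_rejected(self):
        target, X, y = self.separable_model()
        model = DirectContactClassifier(target).fit(X, y)
        with pytest.raises(ValueError):
            predict_complex_network(["p0", "p1"], model)
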