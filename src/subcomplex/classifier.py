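"""Direct-contact prediction by L2-regularized logistic regression.

Each labeled gene pair contributes up to two training examples: its
*target* instance (features from the genes' own GO annotations) and its
*homolog* instance (features from homolog-transferred annotations);
all-zero instances are skipped.  The model minimizes

    (1/2) w'w + C * sum_i log(1 + exp(-y_i w'x_i))

(solved in the dual by liblinear).  At prediction time each instance
yields a signed confidence m = P(+1 | x) - 0.5 in (-0.5, 0.5); the
combined decision value is the instance value of larger magnitude (the
target instance wins ties, homolog knowledge being the fallback).  The
final label applies a confidence threshold delta:

    +1 if m > delta,  -1 if -m > delta,  undetermined otherwise,

so weak predictions can be filtered out; the default delta = 0 keeps
every pair with a nonzero combined value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .features import TermIndex, build_term_index, encode_pairs
from .io import AnnotationSet
from .pairs import PairRecord

UNDETERMINED = 0

SETTINGS = ("combined", "target", "homolog")


@dataclass(frozen=True)
class Decision:
    """Per-pair prediction detail.

    ``value`` is the combined decision value (NaN when the pair is
    unpredictable, i.e. both instances are all-zero); ``label`` is +1,
    -1 or 0 (undetermined/unpredictable).
    """

    pair: tuple[str, str]
    m_target: float
    m_homolog: float
    value: float
    label: int

    @property
    def unpredictable(self) -> bool:
        return np.isnan(self.value)


def combine_margins(m_target: float, m_homolog: float) -> float:
    """Combined decision value: the instance margin of larger magnitude.

    NaN marks an unusable (all-zero) instance; the target instance wins
    exact ties.  Both NaN -> NaN (unpredictable pair).
    """
    if np.isnan(m_target):
        return m_homolog
    if np.isnan(m_homolog):
        return m_target
    return m_homolog if abs(m_homolog) > abs(m_target) else m_target


def label_from_value(value: float, delta: float) -> int:
    if np.isnan(value):
        return UNDETERMINED
    if value > delta:
        return +1
    if -value > delta:
        return -1
    return UNDETERMINED


class DirectContactClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style classifier over gene pairs.

    Parameters
    ----------
    target_ann, homolog_ann : AnnotationSet
        The gene -> GO term maps supplying the two instances.
    C : float
        Penalty parameter of the logistic loss (must be > 0).
    delta : float
        Confidence threshold of the final labeling; pairs with combined
        |m| <= delta come out undetermined (label 0).
    setting : {"combined", "target", "homolog"}
        Which instances participate in prediction; training always uses
        both.
    tol : float
        Solver tolerance.
    random_state : int or None
        Seed forwarded to the solver.

    Attributes
    ----------
    term_index_ : TermIndex
        Term universe G built from the training genes.
    coef_, intercept_ : ndarray
        Weight vector over ``term_index_`` and the intercept.
    classes_ : ndarray
        ``[-1, +1]``.
    """

    def __init__(
        self,
        target_ann: AnnotationSet | None = None,
        homolog_ann: AnnotationSet | None = None,
        C: float = 1.0,
        delta: float = 0.0,
        setting: str = "combined",
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.target_ann = target_ann
        self.homolog_ann = homolog_ann
        self.C = C
        self.delta = delta
        self.setting = setting
        self.tol = tol
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _check_anns(self) -> tuple[AnnotationSet, AnnotationSet]:
        target = self.target_ann or AnnotationSet({}, "target")
        homolog = self.homolog_ann or AnnotationSet({}, "homolog")
        return target, homolog

    @staticmethod
    def _as_pairs(X) -> list[tuple[str, str]]:
        return [(str(a), str(b)) for a, b in X]

    def _instance_matrices(
        self, pairs: Sequence[tuple[str, str]]
    ) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
        target, homolog = self._check_anns()
        xt = encode_pairs(pairs, target, self.term_index_)
        xh = encode_pairs(pairs, homolog, self.term_index_)
        return xt, xh

    # -- estimator interface --------------------------------------------

    def fit(self, X, y):
        """Fit on pairs X (n x 2 array-like of gene ids) and labels y in {-1,+1}."""
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        pairs = self._as_pairs(X)
        y = np.asarray(y, dtype=int)
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        labels = np.unique(y)
        if not np.array_equal(labels, [-1, 1]):
            raise ValueError(
                f"training labels must contain both classes -1 and +1, got {labels}"
            )
        target, homolog = self._check_anns()
        genes = sorted({g for p in pairs for g in p})
        self.term_index_ = build_term_index(genes, target, homolog)

        xt, xh = self._instance_matrices(pairs)
        # both instances of a pair join training, all-zero instances skipped
        keep_t = np.asarray(xt.sum(axis=1)).ravel() > 0
        keep_h = np.asarray(xh.sum(axis=1)).ravel() > 0
        x_all = sparse.vstack([xt[keep_t], xh[keep_h]]).tocsr()
        y_all = np.concatenate([y[keep_t], y[keep_h]])
        if x_all.shape[0] == 0:
            raise ValueError("no trainable instances (all feature vectors empty)")
        if len(np.unique(y_all)) < 2:
            raise ValueError("trainable instances cover a single class")
        self._lr = LogisticRegression(
            C=self.C,
            solver="liblinear",
            tol=self.tol,
            fit_intercept=True,
            random_state=self.random_state,
        )
        self._lr.fit(x_all, y_all)
        self.classes_ = np.array([-1, 1])
        self.coef_ = self._lr.coef_.ravel()
        self.intercept_ = self._lr.intercept_
        self.n_features_in_ = len(self.term_index_)
        self.n_instances_ = x_all.shape[0]
        return self

    def instance_margins(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Signed confidences (m_target, m_homolog); NaN for all-zero instances."""
        pairs = self._as_pairs(X)
        xt, xh = self._instance_matrices(pairs)
        out = []
        for mat in (xt, xh):
            pos_col = int(np.where(self._lr.classes_ == 1)[0][0])
            m = self._lr.predict_proba(mat)[:, pos_col] - 0.5
            empty = np.asarray(mat.sum(axis=1)).ravel() == 0
            m = np.where(empty, np.nan, m)
            out.append(m)
        return out[0], out[1]

    def decision_function(self, X, setting: str | None = None) -> np.ndarray:
        """Combined decision values m; NaN for unpredictable pairs."""
        setting = setting or self.setting
        if setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        m_t, m_h = self.instance_margins(X)
        if setting == "target":
            return m_t
        if setting == "homolog":
            return m_h
        return np.array([combine_margins(t, h) for t, h in zip(m_t, m_h)])

    def predict(self, X, setting: str | None = None) -> np.ndarray:
        """Final labels: +1 direct, -1 indirect, 0 undetermined/unpredictable."""
        values = self.decision_function(X, setting=setting)
        return np.array([label_from_value(v, self.delta) for v in values])

    def decide(self, pair: Sequence[str]) -> Decision:
        """Full per-pair decision record."""
        m_t, m_h = self.instance_margins([pair])
        value = combine_margins(float(m_t[0]), float(m_h[0]))
        return Decision(
            pair=tuple(pair),
            m_target=float(m_t[0]),
            m_homolog=float(m_h[0]),
            value=value,
            label=label_from_value(value, self.delta),
        )


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    records: Iterable[PairRecord],
    target_ann: AnnotationSet,
    homolog_ann: AnnotationSet,
    C: float = 1.0,
    delta: float = 0.0,
    seed: int | None = None,
    tol: float = 1e-6,
) -> DirectContactClassifier:
    """Train a :class:`DirectContactClassifier` from labeled pair records."""
    records = list(records)
    X = [[r.gene_a, r.gene_b] for r in records]
    y = [r.label for r in records]
    model = DirectContactClassifier(
        target_ann=target_ann,
        homolog_ann=homolog_ann,
        C=C,
        delta=delta,
        tol=tol,
        random_state=seed,
    )
    return model.fit(X, y)


def predict_complex_network(
    members: Sequence[str],
    model: DirectContactClassifier,
    delta: float | None = None,
) -> nx.Graph:
    """Predicted physical subunit network of one complex.

    Contains an edge for every pair labeled +1 (weight = combined
    decision magnitude); undetermined and unpredictable pairs yield no
    edge.  All subunits appear as vertices even if isolated.
    """
    if len(members) < 3:
        raise ValueError("complex must have >= 3 subunits")
    delta = model.delta if delta is None else delta
    net = nx.Graph()
    net.add_nodes_from(members)
    pairs = [
        (members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
    values = model.decision_function(pairs)
    for (u, v), m in zip(pairs, values):
        if label_from_value(m, delta) == +1:
            net.add_edge(u, v, weight=abs(m))
    return net


def save_model(model: DirectContactClassifier, path) -> None:
    """Serialize weights as TSV of (term, weight) with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# C\t{model.C:g}\n")
        fh.write(f"# delta\t{model.delta:g}\n")
        fh.write(f"# intercept\t{model.intercept_[0]!r}\n")
        fh.write(f"# n_instances\t{model.n_instances_}\n")
        for term, w in zip(model.term_index_.terms, model.coef_):
            fh.write(f"{term}\t{w!r}\n")
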