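"""End-to-end orchestration: files in, substructure calls and metrics out.

``run_pipeline`` chains the stages -- pair construction, feature
encoding, training with cross-validation, per-complex contact
prediction, connection-degree triage, modularity clustering of
partially connected complexes and functional clustering of fully
connected ones -- and writes every intermediate as TSV plus a
machine-readable ``summary.json``.  Every output file carries the hash
of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import io as sio
from .classifier import DirectContactClassifier, predict_complex_network, save_model
from .gosim import cluster_complex_functionally
from .metrics import (
    class_metrics,
    cluster_prf,
    confusion_matrix,
    discard_undetermined,
    f1,
    roc_auc,
)
from .mmc import mmc_cluster
from .networks import FULL_THRESHOLD, triage, write_profiles
from .pairs import (
    SamplerConfig,
    canonical,
    cocomplex_pairs,
    positive_pairs,
    read_pairs,
    sample_negatives,
    write_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, outputs and decision parameters of one run."""

    obo: str
    target_ann: str
    homolog_ann: str
    interactome: str
    complexes: str
    outdir: str
    exclude: str | None = None
    truth_pairs: str | None = None
    truth_subcomplexes: str | None = None
    #: negative sampling
    ratio: float = 4.0
    n_neg: int | None = None  # None -> balance the positive count
    #: classifier
    C: float = 1.0
    delta: float = 0.0
    #: triage and clustering
    full_threshold: float = FULL_THRESHOLD
    k: int = 3
    xi: float = 0.5
    cv_folds: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def read_subcomplex_table(path: str | Path) -> dict[str, list[list[str]]]:
    """Read a ``complex<TAB>group<TAB>gene`` reference sub-complex table."""
    refs: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, group, gene = line.split("\t")
            refs.setdefault(cid, {}).setdefault(group, []).append(gene)
    return {cid: list(groups.values()) for cid, groups in refs.items()}


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full framework; returns the run directory.

    Writes ``pairs.tsv``, ``model.tsv``, ``edges.tsv``, ``profiles.tsv``,
    ``clusters.tsv``, ``summary.json`` and ``run.log`` under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("subcomplex")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    logger.info("config %s: %s", chash, json.dumps(asdict(config), sort_keys=True))
    summary: dict = {"config_hash": chash, "config": asdict(config)}
    try:
        # ---- inputs ---------------------------------------------------
        dag = _stage("read-obo")(sio.read_obo)(config.obo)
        target = sio.read_annotations(config.target_ann, "target").restrict_to_dag(dag)
        homolog = sio.read_annotations(config.homolog_ann, "homolog").restrict_to_dag(dag)
        interactome = sio.read_network(config.interactome)
        complexes = sio.read_complexes(config.complexes)
        exclude = (
            {canonical(r.pair) for r in read_pairs(config.exclude)}
            if config.exclude
            else set()
        )

        # ---- pairs ----------------------------------------------------
        cocomplex = cocomplex_pairs(complexes)
        positives = _stage("positive-pairs")(positive_pairs)(
            cocomplex, interactome, exclude
        )
        n_neg = config.n_neg if config.n_neg is not None else len(positives)
        negatives = _stage("sample-negatives")(sample_negatives)(
            cocomplex,
            interactome,
            SamplerConfig(n=n_neg, ratio=config.ratio, seed=config.seed),
            exclude,
        )
        records = sorted(positives | negatives, key=lambda r: r.pair)
        write_pairs(records, outdir / "pairs.tsv")
        summary["n_positive"] = len(positives)
        summary["n_negative"] = len(negatives)

        # ---- cross-validation ----------------------------------------
        X = [[r.gene_a, r.gene_b] for r in records]
        y = np.array([r.label for r in records])
        cv = _stage("cross-validate")(cross_validate)(
            X, y, target, homolog, config
        )
        summary["cross_validation"] = cv

        # ---- final model ---------------------------------------------
        model = _stage("train")(
            DirectContactClassifier(
                target_ann=target,
                homolog_ann=homolog,
                C=config.C,
                delta=config.delta,
                random_state=config.seed,
            ).fit
        )(X, y)
        save_model(model, outdir / "model.tsv")

        # ---- per-complex prediction ----------------------------------
        predicted = {
            cid: predict_complex_network(members, model)
            for cid, members in complexes.items()
        }
        with open(outdir / "edges.tsv", "w") as fh:
            fh.write(f"# config {chash}\n# complex\tgeneA\tgeneB\tweight\n")
            for cid in sorted(predicted):
                for u, v, d in predicted[cid].edges(data=True):
                    a, b = canonical((u, v))
                    fh.write(f"{cid}\t{a}\t{b}\t{d['weight']:.6f}\n")

        # ---- triage ---------------------------------------------------
        profiles, fractions = triage(complexes, predicted, config.full_threshold)
        write_profiles(profiles, outdir / "profiles.tsv")
        summary["triage_fractions"] = fractions
        if all(p.category == "isolated" for p in profiles):
            logger.warning(
                "every complex is fully isolated (delta too strict?); "
                "no clustering performed"
            )

        # ---- clustering per category ---------------------------------
        clusters: dict[str, list[set[str]]] = {}
        for prof in profiles:
            cid = prof.complex_id
            if prof.category == "fully":
                fc = cluster_complex_functionally(
                    complexes[cid], target, dag, k=config.k
                )
                clusters[cid] = fc.groups()
            elif prof.category == "partially":
                clusters[cid] = [
                    set(c) for c in mmc_cluster(predicted[cid]).clusters
                ]
            else:
                clusters[cid] = []
        with open(outdir / "clusters.tsv", "w") as fh:
            fh.write(f"# config {chash}\n# complex\tcluster\tgene\n")
            for cid in sorted(clusters):
                for i, group in enumerate(clusters[cid]):
                    for gene in sorted(group):
                        fh.write(f"{cid}\t{i}\t{gene}\n")
        summary["n_clusters"] = sum(len(v) for v in clusters.values())

        # ---- evaluation against supplied truth ------------------------
        if config.truth_pairs:
            truth = {
                canonical(r.pair): r.label for r in read_pairs(config.truth_pairs)
            }
            eval_pairs = [r.pair for r in records if r.pair in truth]
            y_true = [truth[p] for p in eval_pairs]
            y_pred = list(model.predict(eval_pairs))
            y_true_f, y_pred_f, coverage = discard_undetermined(y_true, y_pred)
            summary["pair_metrics"] = {"coverage": coverage}
            if y_true_f:
                m = class_metrics(confusion_matrix(y_true_f, y_pred_f))
                summary["pair_metrics"].update(
                    precision_positive=m.precision[0],
                    sensitivity_positive=m.sensitivity[0],
                    mcc=m.overall_mcc,
                    accuracy=m.accuracy,
                    f1=f1(m.precision[0], m.sensitivity[0]),
                )
        if config.truth_subcomplexes:
            refs = read_subcomplex_table(config.truth_subcomplexes)
            pred_flat = [c for cid in clusters for c in clusters[cid]]
            ref_flat = [set(g) for cid in refs for g in refs[cid]]
            if pred_flat and ref_flat:
                p, r, fscore = cluster_prf(pred_flat, ref_flat, xi=config.xi)
                summary["cluster_metrics"] = {
                    "precision": p,
                    "recall": r,
                    "f_score": fscore,
                    "xi": config.xi,
                }
            else:
                logger.warning("no predicted clusters; cluster metrics skipped")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        logger.info("run complete: %s", outdir / "summary.json")
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


def cross_validate(
    X,
    y,
    target: sio.AnnotationSet,
    homolog: sio.AnnotationSet,
    config: RunConfig,
) -> dict:
    """Stratified k-fold CV; AUC per evaluation setting plus pair metrics."""
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    aucs: dict[str, list[float]] = {"combined": [], "target": [], "homolog": []}
    y_true_all: list[int] = []
    y_pred_all: list[int] = []
    for train_idx, test_idx in skf.split(X, y):
        model = DirectContactClassifier(
            target_ann=target,
            homolog_ann=homolog,
            C=config.C,
            delta=config.delta,
            random_state=config.seed,
        ).fit([X[i] for i in train_idx], y[train_idx])
        X_test = [X[i] for i in test_idx]
        for setting in aucs:
            values = model.decision_function(X_test, setting=setting)
            usable = ~np.isnan(values)
            aucs[setting].append(roc_auc(values[usable], y[test_idx][usable]))
        y_true_all.extend(int(v) for v in y[test_idx])
        y_pred_all.extend(int(v) for v in model.predict(X_test))
    y_true_f, y_pred_f, coverage = discard_undetermined(y_true_all, y_pred_all)
    out = {
        "auc": {k: float(np.mean(v)) for k, v in aucs.items()},
        "auc_per_fold": {k: [float(x) for x in v] for k, v in aucs.items()},
        "coverage": coverage,
    }
    if y_true_f:
        m = class_metrics(confusion_matrix(y_true_f, y_pred_f))
        out.update(
            precision_positive=m.precision[0],
            sensitivity_positive=m.sensitivity[0],
            mcc=m.overall_mcc,
            accuracy=m.accuracy,
            f1=f1(m.precision[0], m.sensitivity[0]),
        )
    else:
        logger.warning(
            "every prediction is undetermined at delta=%s; confusion-matrix "
            "metrics unavailable", config.delta,
        )
    return out
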