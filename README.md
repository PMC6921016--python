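# subcomplex

Predicting **direct physical contacts between subunits of protein
complexes** and partitioning complexes into **substructures
(sub-complexes)**.

Most computational work on protein complexes treats a complex as a flat
list of subunits. Two co-complexed proteins, however, may touch
physically (a direct contact) or merely belong to the same assembly (an
indirect interaction), and the pattern of direct contacts organizes the
complex into cores, attachments and functional modules. `subcomplex` is
aimed at computational biologists who have (i) complex membership tables
(CORUM/HPRD/Reactome-style), (ii) a physical protein–protein interaction
network, and (iii) GO annotations — their own and homolog-transferred —
and want a complex-scale map of which subunits touch and how the complex
decomposes.

## Method

The framework has two phases.

**Phase 1 — direct-contact classification.** Within-complex gene pairs
are labeled: pairs that are also physical PPI edges are positives; the
negatives are co-complexed pairs whose shortest path in the physical
network has length ≥ 2 (*no-less-than-two*) or does not exist
(*no-path*), sampled at ratio λ : 1 (default λ = 4, no-path favored as
the more credible indirect evidence). Each pair (i₁, i₂) is encoded over
the GO term universe G of the training genes as two sparse vectors
(target instance from the genes' own annotations, homolog instance from
transferred annotations) with component

    R[g] = 2 if both genes carry g, 1 if exactly one does, 0 otherwise,

and an L2-regularized logistic regression (ω found by minimizing
½ωᵀω + C Σᵢ log(1 + e^(−yᵢ ωᵀxᵢ))) is trained on both instances of every
pair. At prediction, each instance yields a signed confidence
m = P(+1|x) − 0.5; the combined decision value is the m of larger
magnitude, and a pair is called direct if m > δ, indirect if −m > δ,
undetermined otherwise (δ = 0 by default).

**Phase 2 — substructure inference.** Per complex of N subunits with M
predicted contacts, the *connection degree* 2M/(N(N−1)) triages the
predicted subunit network:

* **partially connected** networks are partitioned by **maximum
  modularity clustering**: greedy cluster merges and single-vertex moves
  scored by exact modularity gains (ΔQ), with Kernighan–Lin refinement,
  maximizing Q = Σᵢ [f(Cᵢ,Cᵢ)/f(V,V) − dev(Cᵢ)²/dev(V)²];
* **fully connected** networks (degree ≥ 0.95), where topology is
  uninformative, are decomposed by **functional clustering**:
  average-linkage on 1 − Sim(g₁,g₂), where Sim is the max-strategy Wang
  GO semantic similarity (S-values with edge weights 0.8 for is-a and
  0.6 for part-of);
* **isolated** networks (no predicted edges) are left unclustered.

Classifier quality is reported as ROC-AUC, precision, sensitivity, MCC
and F1 from the confusion matrix; clusterings are scored against
reference sub-complexes by Jaccard matching at threshold ξ (default
0.5).

A synthetic-data generator (`subcomplex.synthetic`) produces complete
in-silico worlds — random GO DAG, annotated genes, complexes with
planted cores and functional groups, a physical interactome — so the
entire pipeline is testable without any database downloads.

## Worked example

Generate a synthetic world and run the full pipeline on it:

```bash
subcomplex synth --seed 3 --outdir world/
subcomplex run \
    --obo world/ontology.obo \
    --target-ann world/target.tsv --homolog-ann world/homolog.tsv \
    --interactome world/interactome.tsv --complexes world/complexes.tsv \
    --truth-pairs world/truth_pairs.tsv \
    --truth-subcomplexes world/truth_subcomplexes.tsv \
    --outdir run/ --seed 3
```

The run directory contains `pairs.tsv`, `model.tsv`, `edges.tsv`,
`profiles.tsv`, `clusters.tsv` and `summary.json`. For this seed the
printed summary includes:

```
"n_positive": 653,  "n_negative": 653,
"cross_validation": {"auc": {"combined": 0.9504, "target": 0.9500, "homolog": 0.9470}, ...}
"triage_fractions": {"fully": 0.68, "partially": 0.32, "isolated": 0.0}
"cluster_metrics": {"precision": 0.621, "recall": 1.0, "f_score": 0.766, "xi": 0.5}
```

Reading: 653 co-complexed physical pairs were matched by 653 sampled
indirect pairs (λ = 4); 5-fold cross-validation separates direct from
indirect contacts with AUC ≈ 0.95, and the three near-coincident AUCs
show the homolog instances alone carry almost the full signal (the
point of homolog transfer: the model still works for barely annotated
genes). 68% of complexes come out fully connected and are decomposed
functionally, 32% partially connected and are decomposed by modularity;
every planted sub-complex is recovered at Jaccard ≥ 0.5 (recall 1.0).
Precision is lower because modularity clustering reports peripheral
subunits as singleton clusters, which match no reference group.

Library users get the same functionality as scikit-learn style
estimators — `DirectContactClassifier(target_ann, homolog_ann).fit(X, y)`
on an (n, 2) array of gene-id pairs, `MaxModularityClustering().fit(A)`
on an adjacency matrix, `FunctionalClustering(n_clusters=3).fit(S)` on a
similarity matrix — composable with sklearn model selection.

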