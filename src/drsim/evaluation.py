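"""Benchmark metrics for annotation and repositioning.

* ``moa_accuracy`` — fraction of queries whose predicted compound shares
  the true compound's mechanism of action;
* ``precision`` — fraction of truly effective compounds among those called
  effective;
* ``ndcg`` — normalized discounted cumulative gain of a ranked compound
  list under graded relevance;
* ``nmi`` / ``cluster_for_nmi`` — normalized mutual information between a
  k-means clustering and the true compound labels, before and after the
  learned transformation (a higher NMI after transformation means the
  learned space groups replicates of a compound together).
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .errors import SchemaError, ShapeError, UndefinedMetricError
from .io import SampleAnnotation, SignatureMatrix
from .metric_learning import DrSimModel, TrainingConfig, train
from .scoring import annotate

logger = logging.getLogger(__name__)

__all__ = [
    "moa_accuracy",
    "precision",
    "ndcg",
    "nmi",
    "cluster_for_nmi",
    "run_annotation_benchmark",
    "read_moa_map",
    "read_efficacy_truth",
]


def read_moa_map(path) -> dict[str, str]:
    """Read a compound -> MOA class TSV (columns ``compound``, ``moa``)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("compound", "moa"):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return dict(zip(table["compound"], table["moa"]))


def read_efficacy_truth(path) -> dict[str, bool]:
    """Read a compound -> effective flag TSV (columns ``compound``, ``effective``)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("compound", "effective"):
        if col not in table.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    truthy = {"1", "true", "yes", "y"}
    return {
        c: str(v).strip().lower() in truthy
        for c, v in zip(table["compound"], table["effective"])
    }


def moa_accuracy(
    predicted: list[str],
    truth: list[str],
    moa_map: dict[str, str] | None = None,
) -> float:
    """Fraction of queries whose prediction shares the truth's MOA.

    With ``moa_map=None`` compounds are their own MOA (compound-recovery
    accuracy).  Queries whose predicted or true compound is absent from
    the map are dropped, not counted wrong; the drop count is logged.
    """
    if len(predicted) != len(truth):
        raise ShapeError(f"{len(predicted)} predictions but {len(truth)} truths")
    if moa_map is None:
        pairs = list(zip(predicted, truth))
    else:
        pairs = [
            (moa_map[p], moa_map[t])
            for p, t in zip(predicted, truth)
            if p in moa_map and t in moa_map
        ]
        dropped = len(predicted) - len(pairs)
        if dropped:
            logger.info("moa_accuracy: dropped %d unmappable queries", dropped)
    if not pairs:
        raise UndefinedMetricError("no evaluable queries (all unmappable)")
    return sum(p == t for p, t in pairs) / len(pairs)


def precision(
    effective_calls: list[str],
    efficacy_truth: dict[str, bool],
) -> float:
    """TP / (TP + FP) over the compounds called effective.

    Compounds missing from the truth table are dropped with a logged
    count; an empty call set is undefined (reported as an error, not 0).
    """
    known = [c for c in effective_calls if c in efficacy_truth]
    dropped = len(effective_calls) - len(known)
    if dropped:
        logger.info("precision: dropped %d compounds without efficacy truth", dropped)
    if not known:
        raise UndefinedMetricError("no predicted-effective compound with known efficacy")
    tp = sum(efficacy_truth[c] for c in known)
    return tp / len(known)


def ndcg(
    ranked_compounds: list[str],
    relevance: dict[str, float],
    depth: int | None = None,
) -> float:
    """Normalized discounted cumulative gain of a ranking in [0, 1].

    ``DCG = sum_i rel_i / log2(i + 1)`` over the first ``depth`` ranks
    (default: the full list), normalized by the DCG of the
    relevance-sorted ideal ranking at the same depth.
    """
    rels = np.asarray([relevance.get(c, 0.0) for c in ranked_compounds], dtype=float)
    if np.any(rels < 0):
        raise UndefinedMetricError("relevance values must be >= 0")
    ideal = np.sort(np.asarray(list(relevance.values()), dtype=float))[::-1]
    if ideal.size == 0 or ideal[0] <= 0:
        raise UndefinedMetricError("nDCG needs at least one positive relevance")
    depth = len(ranked_compounds) if depth is None else depth
    discounts = 1.0 / np.log2(np.arange(2, depth + 2))
    dcg = float(rels[:depth] @ discounts[: len(rels[:depth])])
    idcg = float(ideal[:depth] @ discounts[: len(ideal[:depth])])
    return dcg / idcg


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (geometric-mean normalization) in [0, 1].

    1 for labelings identical up to renaming; 0 when either labeling is
    constant and they differ.
    """
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ShapeError(f"label lengths differ: {len(labels_a)} vs {len(labels_b)}")
    if len(labels_a) < 2:
        raise UndefinedMetricError("NMI needs at least 2 samples")
    return float(
        normalized_mutual_info_score(labels_a, labels_b, average_method="geometric")
    )


def cluster_for_nmi(
    model: DrSimModel | None,
    signatures: SignatureMatrix,
    true_labels: list[str],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """k-means NMI against true labels before and after the learned map.

    Clusters the samples in raw gene space and, when a model is given, in
    its transformed space, with k = number of true classes, 10 restarts,
    and a fixed seed.  Returns ``(labels_before, labels_after, nmi_before,
    nmi_after)``.
    """
    classes = sorted(set(true_labels))
    if len(classes) < 2:
        raise UndefinedMetricError("clustering needs at least 2 true classes")
    k = len(classes)

    def _cluster(points: np.ndarray) -> np.ndarray:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(points)

    before = _cluster(signatures.values.T)
    if model is None:
        after = before
    else:
        after = _cluster(model.transform(signatures.values).T)
    return before, after, nmi(before, true_labels), nmi(after, true_labels)


def run_annotation_benchmark(
    matrix: SignatureMatrix,
    annotations: list[SampleAnnotation],
    split_ratio: float = 0.3,
    config: TrainingConfig | None = None,
    seed: int = 0,
    moa_map: dict[str, str] | None = None,
    baseline_methods: tuple[str, ...] = (),
    gene_set_size: int | None = None,
) -> dict:
    """Stratified query/reference split, train, annotate, score accuracy.

    Splits each compound's replicates query:reference at ``split_ratio``
    (default 3:7), trains the similarity model on the reference side,
    annotates every query, and reports MOA accuracy (compound-recovery
    accuracy when no MOA map is given).  The no-LDA ablation is always
    reported; requested baseline methods are scored per replicate with
    max-magnitude aggregation per compound.
    """
    from .baselines import DEFAULT_GENE_SET_SIZE, score_collection  # local: avoid cycle
    from .synthetic import stratified_split

    config = config or TrainingConfig()
    query_ids, reference_ids = stratified_split(annotations, split_ratio, seed)
    by_id = {a.sample_id: a for a in annotations}
    ref_matrix = matrix.select_samples(reference_ids)
    ref_annotations = [by_id[s] for s in reference_ids]
    query_matrix = matrix.select_samples(query_ids)
    truth = [by_id[s].compound for s in query_ids]

    model = train(ref_matrix, ref_annotations, config, mode="forward")
    ablation = train(
        ref_matrix,
        ref_annotations,
        TrainingConfig(
            n_components=config.n_components,
            variance_fraction=config.variance_fraction,
            shrinkage=config.shrinkage,
            use_lda=False,
            min_replicates=config.min_replicates,
        ),
        mode="forward",
    )
    predictions = {
        "drsim": [annotate(model, query_matrix.values[:, i]) for i in range(len(query_ids))],
        "no_lda": [
            annotate(ablation, query_matrix.values[:, i]) for i in range(len(query_ids))
        ],
    }
    if baseline_methods:
        k = gene_set_size or min(
            DEFAULT_GENE_SET_SIZE, matrix.n_genes - matrix.n_genes % 2
        )
        compound_of = {a.sample_id: a.compound for a in ref_annotations}
        frame = query_matrix.to_frame()
        for method in baseline_methods:
            preds = []
            for sample in query_ids:
                scores = score_collection(
                    method, frame[sample], ref_matrix, compound_of, k=k, extreme_n=k // 2
                )
                preds.append(str(scores.idxmax()))
            predictions[method] = preds

    accuracy = {
        name: moa_accuracy(preds, truth, moa_map) for name, preds in predictions.items()
    }
    return {
        "n_query": len(query_ids),
        "n_reference": len(reference_ids),
        "n_classes": len(model.class_labels),
        "split_ratio": split_ratio,
        "seed": seed,
        "config": asdict(config),
        "accuracy": accuracy,
        "predictions": predictions,
        "truth": truth,
    }
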