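"""Query transformation, similarity ranking, and effectiveness calls.

A query signature, aligned to the model's gene space, is projected by the
learned map and compared with every compound's transformed median
reference (TMR) by cosine similarity.  In forward mode the rank-1 compound
annotates the query (drug annotation); against a reversed-mode model a
high similarity means the compound is expected to reverse the query
phenotype (drug repositioning).

Significance is assessed against *background scores*: the query's gene
values are permuted across gene positions and re-scored, preserving the
query's value distribution while destroying gene identity.  The empirical
p-value uses add-one smoothing, ``p = (1 + #{null >= observed}) / (B + 1)``,
and a compound is called effective when ``p < alpha`` (strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    ModeMisuseError,
    ParameterError,
    ShapeError,
    UndefinedSimilarityError,
)
from .metric_learning import DrSimModel

__all__ = [
    "transform_query",
    "cosine_similarity",
    "score_query",
    "annotate",
    "background_scores",
    "empirical_pvalue",
    "call_effective",
    "score_with_pvalues",
    "reposition",
]

DEFAULT_PERMUTATIONS = 999
DEFAULT_SEED = 17
DEFAULT_ALPHA = 0.01

SCORE_COLUMNS = ["query_id", "compound", "similarity", "rank"]


def transform_query(model: DrSimModel, query_vector: np.ndarray) -> np.ndarray:
    """Project a gene-space query into the learned space: ``L' P' (q - mu)``."""
    q = np.asarray(query_vector, dtype=np.float64).ravel()
    if q.shape[0] != len(model.gene_ids):
        raise ShapeError(
            f"query has {q.shape[0]} genes, model expects {len(model.gene_ids)}"
        )
    return model.transform(q)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"vector lengths differ: {a.shape[0]} vs {b.shape[0]}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine similarity of a zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _rank_table(query_id: str, class_labels, similarities: np.ndarray) -> pd.DataFrame:
    table = pd.DataFrame(
        {"query_id": query_id, "compound": list(class_labels), "similarity": similarities}
    )
    table = table.sort_values(
        ["similarity", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _class_similarities(model: DrSimModel, tq: np.ndarray) -> np.ndarray:
    norm_q = np.linalg.norm(tq)
    if norm_q == 0:
        raise UndefinedSimilarityError(
            "transformed query is the zero vector; similarity undefined "
            "(a larger gene overlap with the model may help)"
        )
    norms = np.linalg.norm(model.tmr, axis=0)
    if np.any(norms == 0):
        zero = [c for c, n in zip(model.class_labels, norms) if n == 0]
        raise UndefinedSimilarityError(f"zero-norm TMR for classes {zero}")
    return np.clip(model.tmr.T @ tq / (norms * norm_q), -1.0, 1.0)


def score_query(model: DrSimModel, query: np.ndarray, query_id: str = "query") -> pd.DataFrame:
    """Cosine similarity of the transformed query to every compound's TMR.

    Rows are sorted by decreasing similarity with ties broken by ascending
    compound label; ``rank`` is 1-based with 1 = most similar.
    """
    tq = transform_query(model, query)
    return _rank_table(query_id, model.class_labels, _class_similarities(model, tq))


def annotate(model: DrSimModel, query: np.ndarray) -> str:
    """Label a query with its most similar compound (forward mode only)."""
    if model.mode != "forward":
        raise ModeMisuseError(
            "annotate requires a forward-mode model; this model was trained reversed"
        )
    table = score_query(model, query)
    return str(table.loc[0, "compound"])


def background_scores(
    model: DrSimModel,
    query: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
) -> np.ndarray:
    """Null similarities from gene-position permutations of the query.

    Returns an ``(n_permutations, C)`` array; row ``b`` holds the per-class
    similarities of the ``b``-th permuted query.  Deterministic for a fixed
    seed.
    """
    if n_permutations < 99:
        raise ParameterError(f"n_permutations must be >= 99, got {n_permutations}")
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.shape[0] != len(model.gene_ids):
        raise ShapeError(
            f"query has {q.shape[0]} genes, model expects {len(model.gene_ids)}"
        )
    rng = np.random.default_rng(seed)
    perms = np.empty((q.shape[0], n_permutations))
    for b in range(n_permutations):
        perms[:, b] = q[rng.permutation(q.shape[0])]
    TQ = model.transform(perms)  # (q_dim, B)
    norms_q = np.linalg.norm(TQ, axis=0)
    norms_q[norms_q == 0] = np.nan  # degenerate permutation: similarity undefined
    norms_r = np.linalg.norm(model.tmr, axis=0)
    sims = (TQ.T @ model.tmr) / np.outer(norms_q, norms_r)
    return np.clip(np.nan_to_num(sims, nan=0.0), -1.0, 1.0)


def empirical_pvalue(observed: float, null_samples: np.ndarray) -> float:
    """One-sided (high-similarity tail) permutation p-value with add-one smoothing."""
    null_samples = np.asarray(null_samples, dtype=np.float64).ravel()
    if null_samples.size < 1:
        raise ParameterError("at least one null sample is required")
    b = int(np.count_nonzero(null_samples >= observed))
    return (1 + b) / (null_samples.size + 1)


def call_effective(score_table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Flag compounds with ``p_value < alpha`` (strict) as effective."""
    if not 0 < alpha < 1 and alpha != 1.0:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    if "p_value" not in score_table.columns:
        raise ParameterError("score table has no p_value column; compute p-values first")
    out = score_table.copy()
    out["effective"] = out["p_value"] < alpha
    return out


def score_with_pvalues(
    model: DrSimModel,
    query: np.ndarray,
    query_id: str = "query",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Rank compounds and attach background-score p-values and effective calls."""
    tq = transform_query(model, query)
    sims = _class_similarities(model, tq)
    nulls = background_scores(model, query, n_permutations, seed)
    pvals = {
        c: empirical_pvalue(sims[i], nulls[:, i])
        for i, c in enumerate(model.class_labels)
    }
    table = _rank_table(query_id, model.class_labels, sims)
    table["p_value"] = table["compound"].map(pvals)
    return call_effective(table, alpha)


def reposition(
    model: DrSimModel,
    query: np.ndarray,
    query_id: str = "query",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = DEFAULT_SEED,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Rank compounds expected to reverse a disease query (reversed mode only)."""
    if model.mode != "reversed":
        raise ModeMisuseError(
            "reposition requires a reversed-mode model; train with mode='reversed'"
        )
    return score_with_pvalues(model, query, query_id, n_permutations, seed, alpha)
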