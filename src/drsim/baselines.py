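"""Classic unsupervised connectivity scores.

Six comparator similarity methods between a query signature and a
reference signature, all operating on a shared data model:

* ``cosine_baseline`` — full-vector cosine over shared genes;
* ``ks_connectivity`` — the two-set Kolmogorov–Smirnov connectivity score
  of the original connectivity-map work;
* ``gsea_connectivity`` — weighted running-sum enrichment of the up/down
  sets in the rank-ordered reference;
* ``xsum`` / ``xcos`` — extreme-gene methods: the reference is truncated
  to its most extreme values before summing or taking a cosine;
* ``sscmap_score`` — normalized signed-rank sum.

Queries enter the rank-based scores as a pair of gene sets: the top and
bottom ``k/2`` differentially expressed genes (``k`` defaults to 200, the
conventional total set size).  Signatures are :class:`pandas.Series`
indexed by gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedScoreError, UndefinedSimilarityError
from .io import SignatureMatrix
from .scoring import cosine_similarity

logger = logging.getLogger(__name__)

DEFAULT_GENE_SET_SIZE = 200
DEFAULT_EXTREME_N = 200

BASELINE_METHODS = ("cosine", "ks", "gsea", "xsum", "xcos", "sscmap")

__all__ = [
    "QueryGeneSets",
    "RankedReference",
    "make_gene_sets",
    "rank_reference",
    "cosine_baseline",
    "ks_connectivity",
    "gsea_connectivity",
    "xsum",
    "xcos",
    "sscmap_score",
    "baseline_score",
    "score_collection",
    "BASELINE_METHODS",
]


@dataclass(frozen=True)
class QueryGeneSets:
    """Top/bottom differentially expressed gene sets of a query signature.

    ``values`` keeps the full query signature so that value-aware scores
    (XCos) can use actual query magnitudes rather than set membership.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    values: pd.Series | None = None

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ParameterError("up and down gene sets must be disjoint")

    @property
    def k(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class RankedReference:
    """A reference signature's genes ordered by descending value."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def positions(self, genes) -> list[int]:
        """1-based ranks (1 = largest value) of the genes present; absent dropped."""
        pos = {g: i + 1 for i, g in enumerate(self.gene_ids)}
        return sorted(pos[g] for g in genes if g in pos)


def make_gene_sets(query_signature: pd.Series, k: int = DEFAULT_GENE_SET_SIZE) -> QueryGeneSets:
    """Top and bottom ``k/2`` genes of a query, ties broken by gene label."""
    if k % 2 != 0 or k < 2:
        raise ParameterError(f"gene-set size k must be a positive even number, got {k}")
    if k > len(query_signature):
        raise ParameterError(
            f"k={k} exceeds the query's {len(query_signature)} genes"
        )
    if query_signature.nunique() == 1:
        logger.warning("make_gene_sets: all query values identical; sets are label-ordered")
    frame = pd.DataFrame(
        {"gene": query_signature.index.astype(str), "value": query_signature.to_numpy()}
    )
    up = frame.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    down = frame.sort_values(["value", "gene"], ascending=[True, True], kind="mergesort")
    half = k // 2
    return QueryGeneSets(
        up=tuple(up["gene"].head(half)),
        down=tuple(down["gene"].head(half)),
        values=query_signature.astype(float),
    )


def rank_reference(reference_signature: pd.Series) -> RankedReference:
    """Order a reference's genes by descending value; ties by gene label."""
    frame = pd.DataFrame(
        {"gene": reference_signature.index.astype(str), "value": reference_signature.to_numpy()}
    )
    n_ties = len(frame) - frame["value"].nunique()
    if len(frame) and n_ties / len(frame) > 0.01:
        logger.warning("rank_reference: %d of %d values tie", n_ties, len(frame))
    frame = frame.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    return RankedReference(tuple(frame["gene"]), frame["value"].to_numpy(dtype=float))


def _shared(query: pd.Series, reference: pd.Series) -> pd.Index:
    return query.index.intersection(reference.index)


def cosine_baseline(query_signature: pd.Series, reference_signature: pd.Series) -> float:
    """Cosine similarity over the genes shared by query and reference."""
    genes = _shared(query_signature, reference_signature)
    if len(genes) == 0:
        raise UndefinedScoreError("query and reference share no genes")
    try:
        return cosine_similarity(
            query_signature.loc[genes].to_numpy(float),
            reference_signature.loc[genes].to_numpy(float),
        )
    except UndefinedSimilarityError as exc:
        raise UndefinedScoreError(str(exc)) from exc


def _ks_statistic(positions: list[int], n: int) -> float:
    """Two-sided Kolmogorov–Smirnov set statistic at the given rank positions."""
    t = len(positions)
    j = np.arange(1, t + 1)
    pos = np.asarray(positions, dtype=float)
    a = float(np.max(j / t - pos / n))
    b = float(np.max(pos / n - (j - 1) / t))
    return a if a > b else -b


def _combine_two_sets(score_up: float, score_down: float | None) -> float:
    """Two-set combination rule: opposite signs combine, same signs cancel."""
    if score_down is None:
        return score_up / 2.0
    if np.sign(score_up) == np.sign(score_down):
        return 0.0
    return (score_up - score_down) / 2.0


def ks_connectivity(gene_sets: QueryGeneSets, ranked_reference: RankedReference) -> float:
    """KS connectivity score in [-1, 1].

    Up genes near the top and down genes near the bottom of the reference
    ranking give a positive score; the reverse placement is negative; when
    both set statistics have the same sign the score is 0.
    """
    scores = []
    for genes in (gene_sets.up, gene_sets.down):
        if not genes:
            scores.append(None)
            continue
        positions = ranked_reference.positions(genes)
        if not positions:
            raise UndefinedScoreError("no query set gene found in the reference")
        scores.append(_ks_statistic(positions, ranked_reference.n))
    if scores[0] is None:
        raise UndefinedScoreError("empty up set")
    return _combine_two_sets(scores[0], scores[1])


def _weighted_es(
    positions: list[int], weights: np.ndarray, n: int
) -> float:
    """Running-sum enrichment score: extremum by absolute value."""
    t = len(positions)
    total_hit = weights.sum()
    if total_hit == 0:
        # all hit weights zero: fall back to unweighted increments
        weights = np.ones(t)
        total_hit = float(t)
    miss = 1.0 / (n - t) if n > t else 0.0
    running = 0.0
    extremum = 0.0
    prev = 0
    for pos, w in zip(positions, weights):
        running -= (pos - prev - 1) * miss
        if abs(running) > abs(extremum):
            extremum = running
        running += w / total_hit
        if abs(running) > abs(extremum):
            extremum = running
        prev = pos
    running -= (n - prev) * miss
    if abs(running) > abs(extremum):
        extremum = running
    return extremum


def gsea_connectivity(
    gene_sets: QueryGeneSets,
    ranked_reference: RankedReference,
    weight_exponent: float = 1.0,
) -> float:
    """Weighted running-sum enrichment connectivity score.

    Hits increment the running sum proportionally to ``|value|^exponent``
    (normalized over the set's hits); misses decrement by ``1/(N - t)``.
    ``weight_exponent=0`` recovers the unweighted KS running statistic.
    The up/down combination rule matches :func:`ks_connectivity`.
    """
    if weight_exponent < 0:
        raise ParameterError(f"weight_exponent must be >= 0, got {weight_exponent}")
    pos_of = {g: i + 1 for i, g in enumerate(ranked_reference.gene_ids)}
    scores = []
    for genes in (gene_sets.up, gene_sets.down):
        if not genes:
            scores.append(None)
            continue
        positions = sorted(pos_of[g] for g in genes if g in pos_of)
        if not positions:
            raise UndefinedScoreError("no query set gene found in the reference")
        vals = np.abs(
            np.asarray([ranked_reference.values[p - 1] for p in positions], dtype=float)
        )
        weights = vals**weight_exponent
        scores.append(_weighted_es(positions, weights, ranked_reference.n))
    if scores[0] is None:
        raise UndefinedScoreError("empty up set")
    return _combine_two_sets(scores[0], scores[1])


def _extreme_restricted(reference_signature: pd.Series, extreme_n: int) -> pd.Series:
    """Keep the ``extreme_n`` largest and smallest reference values, zero the rest."""
    if extreme_n < 1:
        raise ParameterError(f"extreme_n must be >= 1, got {extreme_n}")
    frame = pd.DataFrame(
        {"gene": reference_signature.index.astype(str), "value": reference_signature.to_numpy()}
    )
    top = frame.sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    bottom = frame.sort_values(["value", "gene"], ascending=[True, True], kind="mergesort")
    keep = set(top["gene"].head(extreme_n)) | set(bottom["gene"].head(extreme_n))
    restricted = reference_signature.astype(float).copy()
    restricted[~restricted.index.isin(keep)] = 0.0
    return restricted


def xsum(
    gene_sets: QueryGeneSets,
    reference_signature: pd.Series,
    extreme_n: int = DEFAULT_EXTREME_N,
) -> float:
    """Extreme-sum score: sum of extreme reference values over up minus down genes."""
    restricted = _extreme_restricted(reference_signature, extreme_n)
    up = restricted.reindex(list(gene_sets.up)).dropna().sum()
    down = restricted.reindex(list(gene_sets.down)).dropna().sum()
    return float(up - down)


def xcos(
    gene_sets: QueryGeneSets,
    reference_signature: pd.Series,
    extreme_n: int = DEFAULT_EXTREME_N,
) -> float:
    """Extreme-cosine score: cosine between query values and the
    extreme-restricted reference over the query's set genes."""
    if gene_sets.values is None:
        raise ParameterError("xcos needs query values; build sets with make_gene_sets")
    restricted = _extreme_restricted(reference_signature, extreme_n)
    nonzero = restricted.index[restricted.to_numpy() != 0.0]
    genes = [g for g in (*gene_sets.up, *gene_sets.down) if g in set(nonzero)]
    genes = [g for g in genes if g in gene_sets.values.index]
    if not genes:
        raise UndefinedScoreError(
            "query gene sets and the reference's extreme genes are disjoint"
        )
    try:
        return cosine_similarity(
            gene_sets.values.loc[genes].to_numpy(float),
            restricted.loc[genes].to_numpy(float),
        )
    except UndefinedSimilarityError as exc:
        raise UndefinedScoreError(str(exc)) from exc


def sscmap_score(gene_sets: QueryGeneSets, ranked_reference: RankedReference) -> float:
    """Normalized signed-rank-sum connection score in [-1, 1].

    The reference's genes carry centered signed ranks (``N-1`` for the
    most up-regulated down to ``1-N`` for the most down-regulated); query
    up genes contribute with sign +1 and down genes with sign -1; the sum
    is divided by its maximum attainable magnitude for the same set sizes.
    """
    n = ranked_reference.n
    pos_of = {g: i + 1 for i, g in enumerate(ranked_reference.gene_ids)}

    def centered_rank(position: int) -> int:
        return n + 1 - 2 * position

    total = 0.0
    n_up = n_down = 0
    for g in gene_sets.up:
        if g in pos_of:
            total += centered_rank(pos_of[g])
            n_up += 1
    for g in gene_sets.down:
        if g in pos_of:
            total -= centered_rank(pos_of[g])
            n_down += 1
    if n_up + n_down == 0:
        raise UndefinedScoreError("no query set gene found in the reference")
    d = float(
        sum(n + 1 - 2 * i for i in range(1, n_up + 1))
        + sum(n + 1 - 2 * i for i in range(1, n_down + 1))
    )
    if d == 0:
        raise UndefinedScoreError("degenerate reference: maximal signed-rank sum is 0")
    return float(total / d)


def baseline_score(
    method: str,
    query_signature: pd.Series,
    reference_signature: pd.Series,
    k: int = DEFAULT_GENE_SET_SIZE,
    extreme_n: int = DEFAULT_EXTREME_N,
    weight_exponent: float = 1.0,
) -> float:
    """Dispatch one of the six connectivity scores by name."""
    if method not in BASELINE_METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {BASELINE_METHODS}")
    if method == "cosine":
        return cosine_baseline(query_signature, reference_signature)
    sets = make_gene_sets(query_signature, k=min(k, len(query_signature) - len(query_signature) % 2))
    if method == "xsum":
        return xsum(sets, reference_signature, extreme_n)
    if method == "xcos":
        return xcos(sets, reference_signature, extreme_n)
    ranked = rank_reference(reference_signature)
    if method == "ks":
        return ks_connectivity(sets, ranked)
    if method == "gsea":
        return gsea_connectivity(sets, ranked, weight_exponent)
    return sscmap_score(sets, ranked)


def score_collection(
    method: str,
    query_signature: pd.Series,
    reference: SignatureMatrix,
    compound_of_sample: dict[str, str],
    k: int = DEFAULT_GENE_SET_SIZE,
    extreme_n: int = DEFAULT_EXTREME_N,
    aggregate: str = "max_magnitude",
) -> pd.Series:
    """Score a query against every reference replicate, aggregated per compound.

    ``aggregate`` is ``"max_magnitude"`` (the replicate score with the
    largest absolute value represents its compound) or ``"mean"``.
    """
    if aggregate not in ("max_magnitude", "mean"):
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    ref_frame = reference.to_frame()
    per_compound: dict[str, list[float]] = {}
    for sample in reference.sample_ids:
        score = baseline_score(method, query_signature, ref_frame[sample], k, extreme_n)
        per_compound.setdefault(compound_of_sample[sample], []).append(score)
    out = {}
    for compound, scores in per_compound.items():
        arr = np.asarray(scores)
        if aggregate == "mean":
            out[compound] = float(arr.mean())
        else:
            out[compound] = float(arr[np.argmax(np.abs(arr))])
    return pd.Series(out).sort_index()
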