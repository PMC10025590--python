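"""Connectivity baselines checked against naive, loop-based oracles.

Each oracle below re-implements the score definition in the most direct
way possible (explicit per-gene walks, no vectorization, no shared code
with the package) so that agreement to 1e-12 is meaningful evidence.
"""

import numpy as np
import pandas as pd
import pytest

from drsim.baselines import (
    BASELINE_METHODS,
    QueryGeneSets,
    baseline_score,
    cosine_baseline,
    gsea_connectivity,
    ks_connectivity,
    make_gene_sets,
    rank_reference,
    score_collection,
    sscmap_score,
    xcos,
    xsum,
)
from drsim.errors import ParameterError, UndefinedScoreError
from drsim.io import SignatureMatrix


# ---------------------------------------------------------------- oracles


def naive_rank_order(reference):
    """Gene ids ordered by descending value (ties by label), plain Python."""
    return [g for g, _ in sorted(reference.items(), key=lambda kv: (-kv[1], kv[0]))]


def naive_ks_set(genes, order):
    present = [g for g in genes if g in order]
    n = len(order)
    positions = sorted(order.index(g) + 1 for g in present)
    t = len(positions)
    a = max(j / t - positions[j - 1] / n for j in range(1, t + 1))
    b = max(positions[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


def naive_combine(up_score, down_score):
    if down_score is None:
        return up_score / 2.0
    if (up_score >= 0) == (down_score >= 0):
        return 0.0
    return (up_score - down_score) / 2.0


def naive_ks(up, down, reference):
    order = naive_rank_order(reference)
    return naive_combine(
        naive_ks_set(up, order), naive_ks_set(down, order) if down else None
    )


def naive_gsea_set(genes, reference, w):
    """Per-gene running-sum walk over every reference position."""
    order = naive_rank_order(reference)
    in_set = set(g for g in genes if g in order)
    t = len(in_set)
    n = len(order)
    total_hit = sum(abs(reference[g]) ** w for g in in_set)
    running, extremum = 0.0, 0.0
    for g in order:
        if g in in_set:
            running += abs(reference[g]) ** w / total_hit
        else:
            running -= 1.0 / (n - t)
        if abs(running) > abs(extremum):
            extremum = running
    return extremum


def naive_gsea(up, down, reference, w=1.0):
    return naive_combine(
        naive_gsea_set(up, reference, w),
        naive_gsea_set(down, reference, w) if down else None,
    )


def naive_extreme(reference, extreme_n):
    by_desc = naive_rank_order(reference)
    keep = set(by_desc[:extreme_n]) | set(by_desc[-extreme_n:])
    return {g: (v if g in keep else 0.0) for g, v in reference.items()}


def naive_xsum(up, down, reference, extreme_n):
    r = naive_extreme(reference, extreme_n)
    return sum(r.get(g, 0.0) for g in up) - sum(r.get(g, 0.0) for g in down)


def naive_xcos(up, down, query, reference, extreme_n):
    r = naive_extreme(reference, extreme_n)
    genes = [g for g in (*up, *down) if r.get(g, 0.0) != 0.0 and g in query]
    qv = [query[g] for g in genes]
    rv = [r[g] for g in genes]
    num = sum(a * b for a, b in zip(qv, rv))
    den = np.sqrt(sum(a * a for a in qv)) * np.sqrt(sum(b * b for b in rv))
    return num / den


def naive_sscmap(up, down, reference):
    order = naive_rank_order(reference)
    n = len(order)
    total, n_up, n_down = 0.0, 0, 0
    for g in up:
        if g in order:
            total += n + 1 - 2 * (order.index(g) + 1)
            n_up += 1
    for g in down:
        if g in order:
            total -= n + 1 - 2 * (order.index(g) + 1)
            n_down += 1
    d = sum(n + 1 - 2 * i for i in range(1, n_up + 1)) + sum(
        n + 1 - 2 * i for i in range(1, n_down + 1)
    )
    return total / d


def _random_case(seed, n=20):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(n)]
    query = pd.Series(rng.normal(size=n), index=genes)
    reference = pd.Series(rng.normal(size=n), index=genes)
    return query, reference


# ------------------------------------------------------- oracle agreement


@pytest.mark.parametrize("seed", range(20))
def test_all_methods_agree_with_naive_oracles(seed):
    query, reference = _random_case(seed)
    sets = make_gene_sets(query, k=8)
    ranked = rank_reference(reference)
    ref_dict = reference.to_dict()
    q_dict = query.to_dict()

    assert ks_connectivity(sets, ranked) == pytest.approx(
        naive_ks(sets.up, sets.down, ref_dict), abs=1e-12
    )
    assert gsea_connectivity(sets, ranked, 1.0) == pytest.approx(
        naive_gsea(sets.up, sets.down, ref_dict, 1.0), abs=1e-12
    )
    assert gsea_connectivity(sets, ranked, 0.0) == pytest.approx(
        naive_gsea(sets.up, sets.down, ref_dict, 0.0), abs=1e-12
    )
    assert xsum(sets, reference, extreme_n=5) == pytest.approx(
        naive_xsum(sets.up, sets.down, ref_dict, 5), abs=1e-12
    )
    assert xcos(sets, reference, extreme_n=5) == pytest.approx(
        naive_xcos(sets.up, sets.down, q_dict, ref_dict, 5), abs=1e-12
    )
    assert sscmap_score(sets, ranked) == pytest.approx(
        naive_sscmap(sets.up, sets.down, ref_dict), abs=1e-12
    )
    shared = query.index
    num = float(query @ reference)
    den = float(np.linalg.norm(query) * np.linalg.norm(reference))
    assert cosine_baseline(query, reference) == pytest.approx(num / den, abs=1e-12)
    assert len(shared) == 20


# ----------------------------------------------------------- worked example


def test_xsum_worked_example():
    """Reference A:+2, B:+1, C:-1, D:-2 with up={A,C}, down={B,D}:
    (2 + -1) - (1 + -2) = 2."""
    reference = pd.Series({"A": 2.0, "B": 1.0, "C": -1.0, "D": -2.0})
    sets = QueryGeneSets(up=("A", "C"), down=("B", "D"))
    assert xsum(sets, reference, extreme_n=2) == pytest.approx(2.0, abs=1e-12)


# -------------------------------------------------------- exact boundaries


def test_sscmap_perfect_and_inverted_placement():
    n = 10
    genes = [f"G{i}" for i in range(n)]
    reference = pd.Series(np.arange(n, 0, -1, dtype=float), index=genes)
    ranked = rank_reference(reference)
    sets = QueryGeneSets(up=tuple(genes[:3]), down=tuple(genes[-3:]))
    assert sscmap_score(sets, ranked) == pytest.approx(1.0, abs=1e-12)
    flipped = QueryGeneSets(up=tuple(genes[-3:]), down=tuple(genes[:3]))
    assert sscmap_score(flipped, ranked) == pytest.approx(-1.0, abs=1e-12)


def test_ks_same_sign_sets_give_zero():
    # both sets concentrated at the top: both statistics positive -> 0
    genes = [f"G{i}" for i in range(10)]
    reference = pd.Series(np.arange(10, 0, -1, dtype=float), index=genes)
    ranked = rank_reference(reference)
    sets = QueryGeneSets(up=("G0", "G1"), down=("G2", "G3"))
    assert ks_connectivity(sets, ranked) == 0.0


def test_ks_concordant_positive_discordant_negative():
    genes = [f"G{i}" for i in range(12)]
    reference = pd.Series(np.arange(12, 0, -1, dtype=float), index=genes)
    ranked = rank_reference(reference)
    concordant = QueryGeneSets(up=("G0", "G1"), down=("G10", "G11"))
    discordant = QueryGeneSets(up=("G10", "G11"), down=("G0", "G1"))
    s = ks_connectivity(concordant, ranked)
    assert s > 0
    assert ks_connectivity(discordant, ranked) == pytest.approx(-s, abs=1e-12)


# ------------------------------------------------------------- symmetries


@pytest.mark.parametrize("seed", range(5))
def test_xsum_antisymmetries(seed):
    query, reference = _random_case(seed)
    sets = make_gene_sets(query, k=8)
    swapped = QueryGeneSets(up=sets.down, down=sets.up, values=sets.values)
    s = xsum(sets, reference, extreme_n=6)
    assert xsum(swapped, reference, extreme_n=6) == pytest.approx(-s, abs=1e-12)
    assert xsum(sets, -reference, extreme_n=6) == pytest.approx(-s, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_gsea_swapping_sets_negates(seed):
    query, reference = _random_case(seed)
    sets = make_gene_sets(query, k=8)
    ranked = rank_reference(reference)
    swapped = QueryGeneSets(up=sets.down, down=sets.up, values=sets.values)
    assert gsea_connectivity(swapped, ranked) == pytest.approx(
        -gsea_connectivity(sets, ranked), abs=1e-12
    )


def test_cosine_baseline_restricted_to_shared_genes():
    query = pd.Series({"A": 1.0, "B": 2.0, "X": 100.0})
    reference = pd.Series({"A": 1.0, "B": 2.0, "Y": -50.0})
    assert cosine_baseline(query, reference) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(UndefinedScoreError):
        cosine_baseline(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}))


# ------------------------------------------------------------ gene sets


class TestMakeGeneSets:
    def test_sizes_and_disjointness(self):
        query, _ = _random_case(0)
        sets = make_gene_sets(query, k=10)
        assert len(sets.up) == len(sets.down) == 5
        assert not set(sets.up) & set(sets.down)
        assert sets.k == 10

    def test_membership_matches_sorted_values(self):
        query, _ = _random_case(1)
        sets = make_gene_sets(query, k=6)
        ordered = query.sort_values(ascending=False)
        assert set(sets.up) == set(ordered.index[:3])
        assert set(sets.down) == set(ordered.index[-3:])

    def test_tie_break_by_gene_label(self):
        query = pd.Series({"B": 1.0, "A": 1.0, "C": 0.0, "D": -1.0})
        sets = make_gene_sets(query, k=2)
        assert sets.up == ("A",)
        assert sets.down == ("D",)

    @pytest.mark.parametrize("k", [0, 3, -2, 7])
    def test_bad_k_rejected(self, k):
        query, _ = _random_case(2)
        with pytest.raises(ParameterError):
            make_gene_sets(query, k=k)

    def test_k_larger_than_query_rejected(self):
        with pytest.raises(ParameterError):
            make_gene_sets(pd.Series({"A": 1.0, "B": 2.0}), k=4)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ParameterError):
            QueryGeneSets(up=("A", "B"), down=("B", "C"))


def test_missing_set_genes_rejected():
    reference = pd.Series({"A": 1.0, "B": -1.0})
    ranked = rank_reference(reference)
    sets = QueryGeneSets(up=("X",), down=("Y",))
    with pytest.raises(UndefinedScoreError):
        ks_connectivity(sets, ranked)
    with pytest.raises(UndefinedScoreError):
        sscmap_score(sets, ranked)


# ------------------------------------------------------------- dispatch


@pytest.mark.parametrize("method", BASELINE_METHODS)
def test_dispatch_bounds_and_determinism(method):
    query, reference = _random_case(9)
    s1 = baseline_score(method, query, reference, k=8, extreme_n=5)
    s2 = baseline_score(method, query, reference, k=8, extreme_n=5)
    assert s1 == s2
    if method != "xsum":
        assert -1.0 - 1e-12 <= s1 <= 1.0 + 1e-12


def test_dispatch_unknown_method():
    query, reference = _random_case(9)
    with pytest.raises(ParameterError):
        baseline_score("pearson", query, reference)


class TestScoreCollection:
    def _reference(self):
        rng = np.random.default_rng(14)
        genes = [f"G{i:02d}" for i in range(20)]
        samples = [f"s{j}" for j in range(6)]
        matrix = SignatureMatrix(genes, samples, rng.normal(size=(20, 6)))
        compound_of = {s: f"C{j // 2}" for j, s in enumerate(samples)}
        return matrix, compound_of

    def test_max_magnitude_aggregation(self):
        matrix, compound_of = self._reference()
        query = pd.Series(
            np.random.default_rng(15).normal(size=20), index=matrix.gene_ids
        )
        out = score_collection("cosine", query, matrix, compound_of)
        assert list(out.index) == ["C0", "C1", "C2"]
        frame = matrix.to_frame()
        for compound in out.index:
            scores = [
                cosine_baseline(query, frame[s])
                for s in matrix.sample_ids
                if compound_of[s] == compound
            ]
            assert out[compound] == max(scores, key=abs)

    def test_mean_aggregation(self):
        matrix, compound_of = self._reference()
        query = pd.Series(
            np.random.default_rng(16).normal(size=20), index=matrix.gene_ids
        )
        out = score_collection("cosine", query, matrix, compound_of, aggregate="mean")
        frame = matrix.to_frame()
        expected = np.mean(
            [cosine_baseline(query, frame[s]) for s in ("s0", "s1")]
        )
        assert out["C0"] == pytest.approx(expected, abs=1e-12)

    def test_unknown_aggregate(self):
        matrix, compound_of = self._reference()
        query = pd.Series(np.zeros(20) + 1.0, index=matrix.gene_ids)
        with pytest.raises(ParameterError):
            score_collection("cosine", query, matrix, compound_of, aggregate="median")
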