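"""Distance, ranking and the precision / recall / AP / MAP metrics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braincbir.feature_store import FeatureDatabase
from braincbir.retrieval import (
    RankedResult,
    average_precision,
    euclidean_distance,
    evaluate_database,
    mean_average_precision,
    precision_recall,
    query,
)


def brute_force_distance(v, v0):
    total = 0.0
    for a, b in zip(v, v0):
        total += (a - b) ** 2
    return total**0.5


def brute_force_ap(flags, n_relevant_total):
    """Oracle: enumerate recall levels; precision at the rank where the n-th
    relevant item appears, zero for relevant items never retrieved."""
    ranks = [i + 1 for i, f in enumerate(flags) if f]
    total = 0.0
    for n, rank in enumerate(ranks, start=1):
        total += n / rank
    return total / n_relevant_total


def toy_db(vectors, labels=None, ids=None):
    vectors = np.asarray(vectors, dtype=np.float32)
    n = len(vectors)
    return FeatureDatabase(
        ids=ids or [f"r{i}" for i in range(n)],
        labels=np.asarray(labels if labels is not None else np.zeros(n), dtype=int),
        vectors=vectors,
    )


# --- Euclidean distance ------------------------------------------------------


def test_distance_identity_and_345():
    assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert euclidean_distance([3.0, 4.0], [0.0, 0.0]) == 5.0


def test_distance_matches_elementwise_accumulation(rng):
    v, v0 = rng.normal(0, 1, (2, 1024))
    assert euclidean_distance(v, v0) == pytest.approx(
        brute_force_distance(v, v0), rel=1e-12
    )


def test_distance_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        euclidean_distance([1.0], [1.0, 2.0])


def test_distance_is_a_metric_on_sampled_triples(rng):
    pts = rng.normal(0, 1, (30, 8))
    for _ in range(200):
        i, j, k = rng.integers(0, 30, 3)
        dij = euclidean_distance(pts[i], pts[j])
        assert dij == pytest.approx(euclidean_distance(pts[j], pts[i]), abs=1e-12)
        assert dij <= (
            euclidean_distance(pts[i], pts[k])
            + euclidean_distance(pts[k], pts[j])
            + 1e-9
        )


# --- query -------------------------------------------------------------------


def test_query_exact_match_ranks_first(rng):
    vecs = rng.normal(0, 1, (20, 6))
    db = toy_db(vecs)
    res = query(db, db.vectors[7], top_k=3)  # query with the stored vector
    assert res.entries[0][0] == "r7"
    assert res.entries[0][2] == 0.0


def test_query_full_ranking_matches_sorting_oracle(rng):
    vecs = rng.normal(0, 1, (50, 5))
    db = toy_db(vecs)
    q = rng.normal(0, 1, 5)
    res = query(db, q, top_k=50)
    dists = np.linalg.norm(db.vectors.astype(np.float64) - q, axis=1)
    expect = [f"r{i}" for i in np.argsort(dists, kind="stable")]
    assert [e[0] for e in res.entries] == expect
    assert all(
        res.entries[i][2] <= res.entries[i + 1][2] for i in range(49)
    )


def test_query_tie_break_by_id():
    vecs = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
    db = toy_db(vecs, ids=["b", "a", "c"])
    res = query(db, np.zeros(2), top_k=3)
    assert [e[0] for e in res.entries] == ["c", "a", "b"]  # ties a before b


def test_query_top_k_one_returns_global_minimum(rng):
    vecs = rng.normal(0, 1, (30, 4))
    db = toy_db(vecs)
    q = rng.normal(0, 1, 4)
    res = query(db, q, top_k=1)
    assert len(res.entries) == 1
    dists = np.linalg.norm(db.vectors.astype(np.float64) - q, axis=1)
    assert res.entries[0][2] == pytest.approx(dists.min(), rel=1e-12)


def test_query_oversized_top_k_warns_and_returns_all(rng):
    db = toy_db(rng.normal(0, 1, (5, 3)))
    with pytest.warns(RuntimeWarning, match="top_k"):
        res = query(db, np.zeros(3), top_k=10)
    assert len(res.entries) == 5


def test_query_empty_db_and_dim_mismatch(rng):
    db = toy_db(rng.normal(0, 1, (4, 3)))
    with pytest.raises(ValueError, match="dim"):
        query(db, np.zeros(5), top_k=1)
    empty = FeatureDatabase(ids=[], labels=np.array([], dtype=int),
                            vectors=np.empty((0, 3), dtype=np.float32))
    with pytest.raises(RuntimeError, match="empty"):
        query(empty, np.zeros(3), top_k=1)


def test_query_relevance_flags(rng):
    db = toy_db(rng.normal(0, 1, (6, 2)), labels=[0, 0, 1, 1, 2, 2])
    res = query(db, np.zeros(2), top_k=6, query_label=1)
    assert res.relevance == [lab == 1 for _, lab, _ in res.entries]


# --- precision / recall ------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, c, p, r",
    [(8, 2, 2, 0.8, 0.8), (5, 0, 0, 1.0, 1.0), (0, 3, 4, 0.0, 0.0)],
)
def test_precision_recall_exact(a, b, c, p, r):
    m = precision_recall(a, b, c)
    assert m.precision == p and m.recall == r


def test_precision_recall_zero_denominator():
    with pytest.raises(ZeroDivisionError):
        precision_recall(0, 0, 5)
    with pytest.raises(ZeroDivisionError):
        precision_recall(0, 5, 0)


def test_precision_recall_negative_counts():
    with pytest.raises(ValueError):
        precision_recall(-1, 1, 1)


# --- average precision -------------------------------------------------------


def test_ap_perfect_ranking_is_one():
    assert average_precision([True] * 5, 5) == 1.0


def test_ap_single_relevant_at_rank_two():
    assert average_precision([False, True], 1) == 0.5


def test_ap_zero_when_nothing_relevant_retrieved():
    assert average_precision([False, False], 3) == 0.0


def test_ap_requires_positive_relevant_count():
    with pytest.raises(ValueError):
        average_precision([True], 0)


def test_ap_matches_brute_force_on_random_lists(rng):
    for _ in range(300):
        n = int(rng.integers(1, 40))
        flags = (rng.random(n) < 0.4).tolist()
        n_rel = int(sum(flags) + rng.integers(0, 4))
        if n_rel == 0:
            continue
        assert average_precision(flags, n_rel) == pytest.approx(
            brute_force_ap(flags, n_rel), rel=1e-12
        )


@settings(deadline=None, max_examples=200)
@given(st.lists(st.booleans(), min_size=2, max_size=30), st.data())
def test_promoting_a_relevant_item_never_decreases_ap(flags, data):
    """Rank sensitivity: swapping a relevant item with the irrelevant item
    just above it cannot lower AP."""
    if not any(flags):
        return
    n_rel = sum(flags)
    base = average_precision(flags, n_rel)
    idx = data.draw(
        st.sampled_from(
            [i for i in range(1, len(flags)) if flags[i] and not flags[i - 1]]
            or [0]
        )
    )
    if idx == 0:
        return
    swapped = list(flags)
    swapped[idx - 1], swapped[idx] = swapped[idx], swapped[idx - 1]
    assert average_precision(swapped, n_rel) >= base


# --- MAP ---------------------------------------------------------------------


def test_map_single_query_equals_its_ap():
    ap = average_precision([True, False, True], 2)
    assert mean_average_precision([ap]) == ap


def test_map_is_arithmetic_mean():
    assert mean_average_precision([1.0, 0.0]) == 0.5


def test_map_empty_query_set_rejected():
    with pytest.raises(ValueError):
        mean_average_precision([])


def test_map_recomposes_individual_aps(rng):
    aps = []
    results = []
    for _ in range(20):
        flags = (rng.random(15) < 0.5).tolist()
        n_rel = max(1, sum(flags))
        results.append(average_precision(flags, n_rel))
        aps.append(brute_force_ap(flags, n_rel))
    assert mean_average_precision(results) == pytest.approx(np.mean(aps), rel=1e-12)


# --- leave-query-out evaluation ---------------------------------------------


def test_evaluate_database_on_separable_clusters(rng):
    """Three tight, well-separated clusters retrieve perfectly."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    vecs, labels = [], []
    for c, center in enumerate(centers):
        for _ in range(8):
            vecs.append(center + rng.normal(0, 0.1, 2))
            labels.append(c)
    db = toy_db(np.array(vecs), labels=labels)
    df, map_value = evaluate_database(db, top_k=5)
    assert map_value == pytest.approx(1.0)
    assert (df["precision"] == 1.0).all()
    # top_k=5 of 7 relevant others: recall is 5/7 for every query
    np.testing.assert_allclose(df["recall"], 5 / 7, rtol=1e-12)


def test_reduced_and_raw_rankings_agree_on_top_neighbor(phantom_set, trained_toy):
    """PCA-reduced retrieval finds the same nearest neighbour as raw
    4096-dim retrieval for at least 90% of phantom queries."""
    import warnings

    from braincbir.feature_store import fit_pca, reduce as pca_reduce
    from braincbir.nn.network import extract_descriptors

    net, _ = trained_toy
    descs = extract_descriptors(net, phantom_set)
    raw = np.stack([d.values for d in descs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pca = fit_pca(descs, k=1024)  # clips to the data rank
    red = np.stack([pca_reduce(pca, d).values for d in descs])
    ids = [im.id for im in phantom_set]
    labels = np.array([im.label for im in phantom_set])
    db_raw = toy_db(raw, labels=labels, ids=ids)
    db_red = toy_db(red, labels=labels, ids=ids)
    agree = 0
    for i, qid in enumerate(ids):
        top_raw = query(
            db_raw, db_raw.vectors[i].astype(np.float64), top_k=1,
            exclude_ids={qid},
        ).entries[0][0]
        top_red = query(
            db_red, db_red.vectors[i].astype(np.float64), top_k=1,
            exclude_ids={qid},
        ).entries[0][0]
        agree += top_raw == top_red
    assert agree / len(ids) >= 0.9


def test_evaluate_database_excludes_query_record(rng):
    vecs = rng.normal(0, 1, (6, 3))
    db = toy_db(vecs, labels=[0, 0, 0, 1, 1, 1])
    df, _ = evaluate_database(db, top_k=3)
    # with the self-match excluded there are 2 relevant others per query
    assert set(df["query_id"]) == set(db.ids)
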