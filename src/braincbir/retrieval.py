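"""Euclidean-distance retrieval against the feature database, and the
precision / recall / average-precision evaluation of retrieval quality.

Similarity between a query descriptor v0 and a database descriptor v is the
Euclidean distance S = ||v - v0||_2; candidates are returned sorted by
ascending distance (ties broken by image id), so the first entry is the most
similar stored image.

Evaluation treats a retrieved image as *relevant* when it shares the query's
disease-class label.  With a retrieved set containing `a` relevant and `b`
irrelevant images, and `c` relevant images left unretrieved, precision is
P = a/(a+b) and recall R = a/(a+c).  Average precision for one query is the
mean of the precision values observed at each rank where a relevant image
appears (one per recall increment), normalised by the total number of
relevant images N_R; mean average precision (MAP) averages AP over the query
set, which restores the rank sensitivity that a single P/R pair lacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_store import FeatureDatabase, ReducedDescriptor

__all__ = [
    "RankedResult",
    "RetrievalMetrics",
    "euclidean_distance",
    "query",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
    "evaluate_queries",
    "evaluate_database",
]


@dataclass
class RankedResult:
    """Ordered retrieval list for one query.

    ``entries`` holds (image_id, label, distance) sorted by ascending
    distance; ``relevance`` flags entries whose label equals the query's
    (empty when the query label is unknown).
    """

    query_id: str
    entries: list[tuple[str, int, float]]
    relevance: list[bool] = field(default_factory=list)


@dataclass
class RetrievalMetrics:
    a: int
    b: int
    c: int
    precision: float
    recall: float
    ap: float = float("nan")


def euclidean_distance(v: np.ndarray, v0: np.ndarray) -> float:
    """S_{v,v0} = ||v - v0||_2."""
    v = np.asarray(v, dtype=np.float64)
    v0 = np.asarray(v0, dtype=np.float64)
    if v.shape != v0.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {v0.shape}")
    return float(np.linalg.norm(v - v0))


def query(
    db: FeatureDatabase,
    q: ReducedDescriptor | np.ndarray,
    top_k: int = 10,
    *,
    query_label: int | None = None,
    exclude_ids: set[str] | None = None,
) -> RankedResult:
    """Rank database records by ascending Euclidean distance to the query.

    The shortest distance marks the most similar image.  Ties are broken by
    image id so rankings are deterministic.  ``exclude_ids`` removes records
    (e.g. the query's own) before ranking; if ``top_k`` exceeds the database
    size the full ranking is returned with a warning.
    """
    if len(db) == 0:
        raise RuntimeError("cannot query an empty feature database")
    qv = np.asarray(
        q.values if isinstance(q, ReducedDescriptor) else q, dtype=np.float64
    )
    if qv.shape != (db.dim,):
        raise ValueError(
            f"query length {qv.shape} does not match database dim {db.dim}"
        )
    keep = np.ones(len(db), dtype=bool)
    if exclude_ids:
        keep = np.array([i not in exclude_ids for i in db.ids])
        if not keep.any():
            raise RuntimeError("all database records excluded from query")
    vecs = db.vectors[keep].astype(np.float64)
    ids = [i for i, k in zip(db.ids, keep) if k]
    labels = db.labels[keep]
    dists = np.sqrt(((vecs - qv) ** 2).sum(axis=1))
    if top_k > dists.size:
        warnings.warn(
            f"top_k={top_k} exceeds database size {dists.size}; "
            "returning the full ranking",
            RuntimeWarning,
            stacklevel=2,
        )
        top_k = dists.size
    order = np.lexsort((np.array(ids), dists))[:top_k]
    q_id = q.image_id if isinstance(q, ReducedDescriptor) else ""
    entries = [(ids[i], int(labels[i]), float(dists[i])) for i in order]
    relevance = (
        [lab == query_label for _, lab, _ in entries]
        if query_label is not None
        else []
    )
    return RankedResult(query_id=q_id, entries=entries, relevance=relevance)


def precision_recall(a: int, b: int, c: int) -> RetrievalMetrics:
    """Exact P = a/(a+b), R = a/(a+c) from retrieval counts."""
    if min(a, b, c) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or a + c == 0:
        raise ZeroDivisionError(
            "precision/recall undefined: a+b and a+c must both be positive"
        )
    return RetrievalMetrics(a=a, b=b, c=c, precision=a / (a + b), recall=a / (a + c))


def average_precision(
    result: RankedResult | list[bool], n_relevant_total: int
) -> float:
    """AP(q) = (1/N_R) * sum of precision at each relevant rank.

    One precision value is taken per recall increment R_n, i.e. at every
    rank where a relevant image appears; ranks beyond the retrieved list
    contribute zero (their relevant images were never reached).
    """
    if n_relevant_total < 1:
        raise ValueError("n_relevant_total must be >= 1 (no relevant items)")
    flags = result.relevance if isinstance(result, RankedResult) else list(result)
    hits = 0
    total = 0.0
    for rank, rel in enumerate(flags, start=1):
        if rel:
            hits += 1
            total += hits / rank
    return total / n_relevant_total


def mean_average_precision(aps) -> float:
    """MAP = (1/|Q|) * sum over the query set of AP(q)."""
    aps = list(aps)
    if not aps:
        raise ValueError("query set is empty")
    return float(np.mean(aps))


def evaluate_queries(
    db: FeatureDatabase,
    query_ids: list[str],
    query_labels,
    query_vectors: np.ndarray,
    top_k: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Evaluate a set of labelled queries against the database.

    A query whose id also exists in the database (the leave-query-out case)
    is excluded from its own ranking.  Per query the table reports precision
    and recall at the fixed ``top_k`` cutoff and the AP over the full
    ranking; the second return value is the MAP across all queries.
    """
    if len(db) < 2:
        raise RuntimeError("evaluation needs at least 2 database records")
    id_set = set(db.ids)
    rows = []
    for qid, q_label, qv in zip(query_ids, query_labels, query_vectors):
        q_label = int(q_label)
        exclude = {qid} if qid in id_set else None
        n_rel_total = int((db.labels == q_label).sum()) - (1 if exclude else 0)
        if n_rel_total < 1:
            raise RuntimeError(f"query {qid}: no database record shares its label")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            full = query(
                db, qv, top_k=len(db), query_label=q_label, exclude_ids=exclude
            )
        ap = average_precision(full, n_rel_total)
        cut = full.relevance[:top_k]
        a = int(sum(cut))
        b = len(cut) - a
        c = n_rel_total - a
        pr = precision_recall(a, b, c)
        rows.append(
            {
                "query_id": qid,
                "label": q_label,
                "precision": pr.precision,
                "recall": pr.recall,
                "ap": ap,
            }
        )
    df = pd.DataFrame(rows)
    return df, mean_average_precision(df["ap"])


def evaluate_database(
    db: FeatureDatabase, top_k: int = 10
) -> tuple[pd.DataFrame, float]:
    """Leave-query-out evaluation: every stored image queries the rest."""
    return evaluate_queries(db, db.ids, db.labels, db.vectors, top_k=top_k)
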