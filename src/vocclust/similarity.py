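"""Pairwise match scores, neighbor rankings, and the Jaccard similarity matrix.

Three classifiers rank, for every call, all other calls from best to worst
match: dynamic time warping (distance between feature/spectrum matrices),
k-nearest neighbors (Euclidean distance between flattened row vectors), and
cross-correlation (maximum correlation coefficient over all shifts). The
top-k neighbor sets of two calls are then compared by Jaccard similarity
|A ∩ B| / |A ∪ B|, giving an N x N similarity matrix in [0, 1]. The value of
k is selected automatically: every k in a grid is clustered, and the k whose
cluster count equals the most frequent count and whose mean silhouette is
highest wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class NeighborRanking:
    """Best-match-first neighbor ordering per call (self excluded)."""

    order: np.ndarray  # N x (N-1) int matrix of call indices
    score_kind: Literal["distance", "correlation"]
    call_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.order.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Jaccard-of-top-k similarity with unit diagonal."""

    S: np.ndarray
    k_used: int
    classifier: Literal["dtw", "knn", "xcorr"]
    call_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# classifiers

def dtw_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """Unconstrained DTW distance between two sequences of column vectors.

    Columns (windows) may be repeated to minimize the cumulative Euclidean
    column distance along a monotone warping path. 1-D inputs are treated as
    sequences of scalars. Symmetric, and zero for identical inputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if X.size == 0 or Y.size == 0:
        raise InputError("empty input to DTW")
    if X.shape[0] != Y.shape[0]:
        raise InputError(f"row-dimension mismatch: {X.shape[0]} vs {Y.shape[0]}")
    # local cost: Euclidean distance between every column pair
    sq = (
        np.sum(X ** 2, axis=0)[:, None]
        + np.sum(Y ** 2, axis=0)[None, :]
        - 2.0 * X.T @ Y
    )
    cost = np.sqrt(np.maximum(sq, 0.0))
    n, m = cost.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        for j in range(1, m + 1):
            row[j] = cost[i - 1, j - 1] + min(prev[j - 1], prev[j], row[j - 1])
    return float(acc[n, m])


def xcorr_max(X: np.ndarray, Y: np.ndarray, time_lag_only: bool = False) -> float:
    """Maximum cross-correlation coefficient over all shifts.

    Vectors are zero-padded at the end to equal length and correlated over
    all 1-D lags. Matrices are correlated over all 2-D (row, column) lags;
    with ``time_lag_only`` the row (frequency) lag is fixed to 0 and only the
    column (time) axis slides, which is much cheaper for tall matrices.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.size == 0 or Y.size == 0:
        raise InputError("empty input to cross-correlation")
    if X.ndim == 1 and Y.ndim == 1:
        n = max(X.size, Y.size)
        x = np.pad(X, (0, n - X.size))
        y = np.pad(Y, (0, n - Y.size))
        return float(np.max(sp_signal.correlate(x, y, mode="full", method="auto")))
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    if X.shape[0] != Y.shape[0]:
        raise InputError(f"row-dimension mismatch: {X.shape[0]} vs {Y.shape[0]}")
    if time_lag_only:
        c = sum(
            sp_signal.correlate(X[r], Y[r], mode="full", method="auto")
            for r in range(X.shape[0])
        )
        return float(np.max(c))
    c = sp_signal.correlate(X, Y, mode="full", method="auto")
    return float(np.max(c))


def score_matrix(reps: Sequence[np.ndarray], scorer: Callable[[np.ndarray, np.ndarray], float],
                 symmetric: bool = True) -> np.ndarray:
    """Dense pairwise score matrix from a per-call representation list."""
    n = len(reps)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = scorer(reps[i], reps[j])
            M[j, i] = M[i, j] if symmetric else scorer(reps[j], reps[i])
    return M


def rank_from_scores(scores: np.ndarray, score_kind: str,
                     call_ids: list[str] | None = None) -> NeighborRanking:
    """Best-first neighbor ranking from an N x N score matrix.

    Distances rank ascending, correlations descending; ties resolve by
    ascending call index for determinism. The self-match is excluded.
    """
    n = scores.shape[0]
    keyed = scores if score_kind == "distance" else -scores
    order = np.empty((n, n - 1), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # stable sort on score => ties keep ascending-index order
        order[i] = others[np.argsort(keyed[i, others], kind="stable")]
    return NeighborRanking(order=order, score_kind=score_kind,
                           call_ids=call_ids or [str(i) for i in range(n)])


def knn_rank(rows) -> NeighborRanking:
    """Full Euclidean-distance neighbor ranking of a (z-scored) row matrix."""
    matrix = rows.matrix if hasattr(rows, "matrix") else np.asarray(rows)
    ids = list(rows.call_ids) if hasattr(rows, "call_ids") else [str(i) for i in range(len(matrix))]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate call ids in row matrix")
    if matrix.shape[0] < 3:
        raise InputError("need at least 3 calls for neighbor ranking")
    sq = (
        np.sum(matrix ** 2, axis=1)[:, None]
        + np.sum(matrix ** 2, axis=1)[None, :]
        - 2.0 * matrix @ matrix.T
    )
    d = np.sqrt(np.maximum(sq, 0.0))
    return rank_from_scores(d, "distance", call_ids=ids)


# ---------------------------------------------------------------------------
# Jaccard similarity and silhouette

def build_jaccard_similarity(ranking: NeighborRanking, k: int,
                             classifier: str = "knn") -> SimilarityMatrix:
    """S[i, j] = |topk(i) ∩ topk(j)| / |topk(i) ∪ topk(j)|, diagonal 1."""
    n = ranking.n
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k={k} outside [1, {n - 1}]")
    # membership indicator of each call's top-k set
    member = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    member[rows, ranking.order[:, :k].reshape(-1)] = True
    inter = (member.astype(np.int32) @ member.T.astype(np.int32)).astype(np.float64)
    union = 2 * k - inter
    S = inter / union
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S=S, k_used=k, classifier=classifier,
                            call_ids=list(ranking.call_ids))


def mean_silhouette(labels: Sequence[int], distances: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) from a precomputed distance matrix.

    ``a`` is the mean within-cluster distance of a point (singletons
    contribute 0), ``b`` the smallest mean distance to another cluster.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise InputError("silhouette undefined for a single cluster")
    n = labels.size
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same <= 1:
            s[i] = 0.0
            continue
        a = distances[i, same].sum() / (n_same - 1)
        b = min(distances[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def default_k_grid(n: int) -> list[int]:
    """Candidate neighbor counts: 2 up to about sqrt(N) (at least 10, at most
    30 and N-1).

    Top-k neighbor sets carry class information only while k stays below the
    typical class size; counting cluster-count frequencies over k values far
    beyond that floods the selection with washed-out solutions, so the grid
    is capped near the usual kNN-graph heuristic of sqrt(N).
    """
    cap = min(n - 1, 30, max(10, int(round(np.sqrt(n)))))
    return list(range(2, cap + 1))


def auto_select_k(ranking: NeighborRanking,
                  cluster_fn: Callable[[SimilarityMatrix], "object"],
                  k_grid: Iterable[int] | None = None,
                  classifier: str = "knn"):
    """Automatic k selection for the Jaccard similarity matrix.

    Every k in the grid is turned into a similarity matrix and clustered;
    the most frequent cluster count K is taken as the stable solution, and
    among the k values yielding it, the one with the highest mean silhouette
    (ties: smallest k) is selected.

    Returns ``(k_star, SimilarityMatrix, diagnostics)`` where diagnostics is
    a DataFrame with one row per k (columns k, K, silhouette). Degenerate
    grids where every clustering collapses to one cluster are flagged in
    ``diagnostics.attrs['warning']``.
    """
    grid = list(k_grid) if k_grid is not None else default_k_grid(ranking.n)
    if not grid:
        raise ParameterError("empty k grid")
    rows = []
    results = {}
    for k in grid:
        S = build_jaccard_similarity(ranking, k, classifier=classifier)
        res = cluster_fn(S)
        labels = np.asarray(res.labels)
        K = res.K
        if K >= 2:
            sil = mean_silhouette(labels, 1.0 - S.S)
        else:
            sil = np.nan
        rows.append({"k": k, "K": K, "silhouette": sil})
        results[k] = (S, res)
    diag = pd.DataFrame(rows)
    usable = diag[diag["K"] >= 2]
    if usable.empty:
        diag.attrs["warning"] = "all clusterings degenerate (K == 1 for every k)"
        k_star = grid[0]
        return k_star, results[k_star][0], diag
    counts = usable["K"].value_counts()
    modal = counts[counts == counts.max()].index
    cand = usable[usable["K"].isin(modal)].copy()
    # among the most frequent cluster counts, the highest silhouette wins;
    # silhouette ties resolve to the smallest k
    cand = cand.sort_values(["silhouette", "k"], ascending=[False, True], kind="stable")
    k_star = int(cand.iloc[0]["k"])
    return k_star, results[k_star][0], diag
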