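"""The four clustering back-ends with automated parameter handling.

* Greedy modularity community detection on the weighted Jaccard-similarity
  graph (agglomerative: start from singleton communities, repeatedly apply
  the merge with the largest modularity gain, return the partition at the
  maximum modularity Q along the merge sequence).
* Adaptive affinity propagation: exemplar-based message passing swept over a
  preference schedule (start at the median similarity, reduce uniformly until
  at most 3 clusters emerge, then sweep upward to 1); the most frequently
  occurring cluster count over the sweep wins, realized at the step with the
  best silhouette.
* HDBSCAN (density-based, minpts = minclustsize = 2); unassignable points are
  labeled 0 (noise).
* Fuzzy c-means swept over the fuzziness exponent (1.1 to 2.5, step 0.05)
  from 15 initial centroids; centroids closer than epsilon = 0.01 are merged
  transitively, and the cluster count persisting over the most fuzziness
  values is selected.

All labels are positive integers assigned by first occurrence; 0 is reserved
for HDBSCAN noise. All methods are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN as SKHDBSCAN
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .errors import InputError, ParameterError, VocclustError
from .similarity import SimilarityMatrix, mean_silhouette
from .transform import RowMatrix

DEFAULT_SEED = 42


@dataclass
class ClusterResult:
    """Labels plus provenance for one clustering run.

    ``labels`` are integers 1..K; 0 marks HDBSCAN noise. ``K`` counts
    distinct non-noise clusters. ``stability_table`` records the parameter
    sweep (one row per parameter value with the resulting K and silhouette).
    """

    labels: np.ndarray
    K: int
    mean_silhouette: float
    method: str
    params: dict = field(default_factory=dict)
    stability_table: Optional[pd.DataFrame] = None
    call_ids: list[str] = field(default_factory=list)


def _canonical_labels(raw: np.ndarray, noise_value=None) -> np.ndarray:
    """Relabel by first occurrence to 1..K; ``noise_value`` maps to 0."""
    out = np.zeros(len(raw), dtype=int)
    mapping: dict = {}
    nxt = 1
    for i, r in enumerate(raw):
        if noise_value is not None and r == noise_value:
            continue
        if r not in mapping:
            mapping[r] = nxt
            nxt += 1
        out[i] = mapping[r]
    return out


# ---------------------------------------------------------------------------
# community detection

def modularity(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Weighted modularity Q = sum_c (w_in_c / W - (deg_c / 2W)^2)."""
    A = np.asarray(adjacency, dtype=np.float64)
    W = A.sum() / 2.0
    if W == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_in = A[np.ix_(mask, mask)].sum() / 2.0
        deg = A[mask].sum()
        q += w_in / W - (deg / (2.0 * W)) ** 2
    return float(q)


def community_detection(S: SimilarityMatrix) -> ClusterResult:
    """Greedy agglomerative modularity maximization on the weighted graph.

    Edge weights are the similarity entries with the diagonal zeroed. The
    merge sequence runs to a single community and the partition with the
    highest Q is returned; since the single-community endpoint scores Q = 0,
    the best Q is never negative.
    """
    A = np.array(S.S, dtype=np.float64)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    W = A.sum() / 2.0
    if W == 0:
        labels = np.arange(1, n + 1)
        return ClusterResult(labels=labels, K=n, mean_silhouette=np.nan,
                             method="community_detection",
                             params={"k_used": S.k_used, "Q": 0.0,
                                     "warning": "all-zero graph: every call its own cluster"},
                             call_ids=list(S.call_ids))
    # B[i, j]: between-community weight; B[i, i]: 2 x internal weight
    B = A.copy()
    deg = B.sum(axis=1)
    groups = [[i] for i in range(n)]
    labels_now = np.arange(n)
    q = float(-np.sum((deg / (2 * W)) ** 2))
    best_q, best_labels = q, labels_now.copy()
    while len(groups) > 1:
        d = B / W - np.outer(deg, deg) / (2.0 * W * W)
        np.fill_diagonal(d, -np.inf)
        a, b = np.unravel_index(np.argmax(d), d.shape)  # first max: deterministic
        if a > b:
            a, b = b, a
        q += d[a, b]
        B[a, :] += B[b, :]
        B[:, a] += B[:, b]
        B = np.delete(np.delete(B, b, axis=0), b, axis=1)
        deg = B.sum(axis=1)
        groups[a].extend(groups[b])
        del groups[b]
        labels_now = np.empty(n, dtype=int)
        for g, members in enumerate(groups):
            labels_now[members] = g
        if q > best_q + 1e-12:
            best_q, best_labels = q, labels_now.copy()
    labels = _canonical_labels(best_labels)
    K = len(np.unique(labels))
    sil = mean_silhouette(labels, 1.0 - S.S) if K >= 2 else np.nan
    return ClusterResult(labels=labels, K=K, mean_silhouette=sil,
                         method="community_detection",
                         params={"k_used": S.k_used, "Q": max(best_q, 0.0)},
                         call_ids=list(S.call_ids))


# ---------------------------------------------------------------------------
# adaptive affinity propagation

def _run_ap(S: np.ndarray, preference: float, seed: int,
            damping_start: float = 0.5) -> Optional[np.ndarray]:
    """One AP solve; escalates damping on non-convergence, None if hopeless."""
    damping = damping_start
    while damping <= 0.95:
        with warnings.catch_warnings():
            # preference sweeps intentionally pass through degenerate regimes
            # (all-equal similarities); only non-convergence matters here
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ap = AffinityPropagation(
                    affinity="precomputed", preference=preference,
                    damping=damping, random_state=seed, max_iter=400,
                ).fit(S)
            except ConvergenceWarning:
                damping = round(damping + 0.1, 2)
                continue
        if len(ap.cluster_centers_indices_) == 0:
            damping = round(damping + 0.1, 2)
            continue
        return ap.labels_
    return None


def adaptive_affinity_propagation(S: SimilarityMatrix,
                                  seed: int = DEFAULT_SEED,
                                  n_down: int = 20, n_up: int = 50) -> ClusterResult:
    """Affinity propagation with an adaptive preference sweep.

    Preferences start at the median of the input similarities and are reduced
    uniformly until at most 3 clusters emerge, then swept upward step-by-step
    to the maximum of 1 (the Jaccard ceiling). Every step records the cluster
    count and silhouette; the most stable solution — the non-degenerate step
    (1 < K < N) with the highest silhouette — is returned, per the adaptive
    scanning strategy this sweep follows. Non-convergence triggers damping
    escalation; a step that still fails is skipped.
    """
    Smat = np.array(S.S, dtype=np.float64)
    off = Smat[~np.eye(Smat.shape[0], dtype=bool)]
    med = float(np.median(off))
    rng_s = float(off.max() - off.min()) if off.size else 1.0
    step = (rng_s if rng_s > 0 else 1.0) / n_down

    steps: list[tuple[float, np.ndarray]] = []
    n_failed = 0

    def attempt(pref: float) -> Optional[int]:
        nonlocal n_failed
        labels = _run_ap(Smat, pref, seed)
        if labels is None:
            n_failed += 1
            return None
        steps.append((pref, labels))
        return len(np.unique(labels))

    # downward phase: reduce uniformly from the median until at most 3
    # clusters emerge; sparse similarity graphs can need preferences far
    # below the similarity range, so the scan extends (with growing steps)
    # rather than stopping at an arbitrary floor
    start_pref = med
    pref = med
    for i in range(8 * n_down):
        K = attempt(float(pref))
        start_pref = float(pref)
        if K is not None and K <= 3:
            break
        if i >= 4 * n_down:
            step *= 2.0
        pref -= step
    # upward phase: from the start-preference up to 1
    for pref in np.linspace(start_pref, 1.0, n_up + 1)[1:]:
        attempt(float(pref))

    if not steps:
        raise VocclustError(
            "affinity propagation failed to converge at every preference "
            f"({n_failed} steps attempted)"
        )
    rows = []
    for pref, labels in steps:
        K = len(np.unique(labels))
        sil = mean_silhouette(labels, 1.0 - Smat) if 2 <= K < Smat.shape[0] else np.nan
        rows.append({"preference": pref, "K": K, "silhouette": sil})
    table = pd.DataFrame(rows)
    # K == 1 and K == N are degenerate endpoints of the preference sweep
    # (no partition / every call its own exemplar); the stable solution is
    # sought among the non-trivial steps, by silhouette
    usable = table[(table["K"] >= 2) & (table["K"] < Smat.shape[0])]
    pool = usable if not usable.empty else table
    sils = pool["silhouette"]
    idx = int(sils.idxmax()) if sils.notna().any() else int(pool.index[0])
    labels = _canonical_labels(steps[idx][1])
    K = len(np.unique(labels))
    sil = table.loc[idx, "silhouette"]
    return ClusterResult(labels=labels, K=K, mean_silhouette=float(sil),
                         method="adaptive_affinity_propagation",
                         params={"k_used": S.k_used, "preference": steps[idx][0],
                                 "seed": seed, "n_failed_steps": n_failed},
                         stability_table=table, call_ids=list(S.call_ids))


# ---------------------------------------------------------------------------
# HDBSCAN

def hdbscan_cluster(rows: RowMatrix, minpts: int = 2, minclustsize: int = 2) -> ClusterResult:
    """Density-based clustering; unassignable points get noise label 0."""
    X = rows.matrix
    if X.shape[0] < max(minclustsize, 3):
        raise InputError(f"need at least {max(minclustsize, 3)} calls for HDBSCAN")
    model = SKHDBSCAN(min_cluster_size=minclustsize, min_samples=minpts,
                      cluster_selection_method="eom", allow_single_cluster=True,
                      copy=True)
    raw = model.fit_predict(X)
    labels = _canonical_labels(raw, noise_value=-1)
    K = len(np.unique(labels[labels > 0]))
    sil = np.nan
    mask = labels > 0
    if K >= 2 and mask.sum() >= 3:
        d = cdist(X[mask], X[mask])
        sil = mean_silhouette(labels[mask], d)
    return ClusterResult(labels=labels, K=K, mean_silhouette=sil,
                         method="hdbscan",
                         params={"minpts": minpts, "minclustsize": minclustsize},
                         call_ids=list(rows.call_ids))


# ---------------------------------------------------------------------------
# fuzzy c-means with centroid merging

def mu_from_dimensions(n_dimensions: int) -> float:
    """Optional fuzziness heuristic for high-dimensional data: 1 + 2/D."""
    return 1.0 + 2.0 / n_dimensions


def _fcm(X: np.ndarray, centroids: np.ndarray, mu: float,
         tol: float = 1e-6, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray]:
    """Plain fuzzy c-means iteration; returns (centroids, memberships)."""
    c = centroids.copy()
    expo = 2.0 / (mu - 1.0)
    for _ in range(max_iter):
        d = cdist(X, c)
        u = np.zeros_like(d)
        zero = d < 1e-300
        any_zero = zero.any(axis=1)
        if any_zero.any():
            u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        ok = ~any_zero
        if ok.any():
            ratios = d[ok][:, :, None] / d[ok][:, None, :]
            u[ok] = 1.0 / np.sum(ratios ** expo, axis=2)
        um = u ** mu
        denom = um.sum(axis=0)
        new_c = c.copy()
        nonempty = denom > 0
        new_c[nonempty] = (um.T[nonempty] @ X) / denom[nonempty, None]
        move = np.max(np.linalg.norm(new_c - c, axis=1))
        c = new_c
        if move < tol:
            break
    return c, u


def _merge_centroids(centroids: np.ndarray, epsilon: float) -> np.ndarray:
    """Transitive merging of centroids closer than epsilon (union-find)."""
    k = centroids.shape[0]
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = cdist(centroids, centroids)
    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] < epsilon:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(k)])


def fuzzy_sweep(rows: RowMatrix, cmax: int = 15,
                mu_grid: Optional[np.ndarray] = None, epsilon: float = 0.01,
                seed: int = DEFAULT_SEED) -> ClusterResult:
    """Fuzzy c-means swept over the fuzziness exponent with centroid merging.

    The sweep is warm-started: clustering begins from ``cmax`` randomly
    chosen data rows (fixed seed) at the lowest fuzziness, and at every
    subsequent value the converged centroids of the previous step carry over.
    Centroids within ``epsilon`` of each other are merged transitively and
    the merge is permanent, so the cluster count is decimated monotonically
    as fuzziness grows. Hard labels are taken by maximum summed membership.
    The cluster count persisting over the most fuzziness values is selected
    (ties: the smaller count), realized at its best-silhouette value; counts
    equal to ``cmax`` (no merging yet — still the arbitrary starting
    condition) or below 2 are not candidate solutions unless nothing else
    exists.
    """
    X = rows.matrix
    n = X.shape[0]
    if cmax >= n:
        raise ParameterError(f"cmax={cmax} must be smaller than the number of calls ({n})")
    if mu_grid is None:
        mu_grid = np.round(np.arange(1.1, 2.5 + 1e-9, 0.05), 10)
    rng = np.random.default_rng(seed)
    centroids = X[np.sort(rng.choice(n, size=cmax, replace=False))].copy()
    d_euclid = cdist(X, X)

    rows_out = []
    label_store = []
    for mu in mu_grid:
        centroids, u = _fcm(X, centroids, float(mu))
        group = _merge_centroids(centroids, epsilon)
        uniq_groups = np.unique(group)
        merged = np.zeros((n, len(uniq_groups)))
        for gi, g in enumerate(uniq_groups):
            merged[:, gi] = u[:, group == g].sum(axis=1)
        centroids = np.vstack([centroids[group == g].mean(axis=0) for g in uniq_groups])
        hard = _canonical_labels(np.argmax(merged, axis=1))
        K = len(np.unique(hard))
        sil = mean_silhouette(hard, d_euclid) if 2 <= K < n else np.nan
        rows_out.append({"mu": float(mu), "K": K, "silhouette": sil})
        label_store.append(hard)
    table = pd.DataFrame(rows_out)
    pool = table[(table["K"] >= 2) & (table["K"] < cmax)]
    if pool.empty:
        pool = table
    counts = pool["K"].value_counts()
    k_star = int(min(counts[counts == counts.max()].index))
    cand = table[table["K"] == k_star]
    sils = cand["silhouette"]
    idx = int(sils.idxmax()) if sils.notna().any() else int(cand.index[0])
    labels = label_store[idx]
    return ClusterResult(labels=labels, K=k_star,
                         mean_silhouette=float(table.loc[idx, "silhouette"]),
                         method="fuzzy",
                         params={"cmax": cmax, "epsilon": epsilon, "seed": seed,
                                 "mu": float(table.loc[idx, "mu"])},
                         stability_table=table, call_ids=list(rows.call_ids))
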