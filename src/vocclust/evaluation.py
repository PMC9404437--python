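"""Agreement between labelings and cross-method concordance.

Two labelings of the same calls are compared by normalized mutual
information, NMI(x, y) = I(x, y) / sqrt(H(x) H(y)), which is 1 for identical
partitions (up to renaming) and near 0 for independent ones. The deviation in
cluster counts |K_est - K_ref| (delta-cluster) complements NMI, since a high
NMI does not guarantee the right number of clusters. A method passes the
reliability thresholds when NMI > 0.5 and delta-cluster <= 1. HDBSCAN noise
points (label 0) are discarded from both labelings before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .clustering import ClusterResult
from .errors import InputError

NMI_THRESHOLD = 0.5
DELTA_THRESHOLD = 1


@dataclass
class ConcordanceReport:
    """Pairwise NMI between methods plus cluster-count summaries."""

    methods: list[str]
    nmi_matrix: pd.DataFrame
    k_per_method: list[int]
    k_median: float
    k_mode: int
    delta_vs_reference: Optional[list[int]] = None
    nmi_vs_reference: Optional[list[float]] = None


def nmi(x: Sequence[int], y: Sequence[int]) -> float:
    """Normalized mutual information with geometric-mean normalization.

    Invariant to label renaming; by convention 0 when exactly one labeling is
    constant, and 1 when both are constant (trivially identical partitions).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise InputError(f"label lists differ in length: {x.size} vs {y.size}")
    const_x = len(np.unique(x)) == 1
    const_y = len(np.unique(y)) == 1
    if const_x and const_y:
        return 1.0
    if const_x or const_y:
        return 0.0
    return float(normalized_mutual_info_score(x, y, average_method="geometric"))


def delta_cluster(k_est: int, k_ref: int) -> int:
    """Absolute deviation between estimated and reference cluster counts."""
    return abs(int(k_est) - int(k_ref))


def align_for_comparison(a_labels: Sequence[int], b_labels: Sequence[int]):
    """Drop calls labeled 0 (noise) in either labeling before comparison.

    Returns ``(x, y, n_retained)``.
    """
    a = np.asarray(a_labels)
    b = np.asarray(b_labels)
    if a.shape != b.shape:
        raise InputError(f"label lists differ in length: {a.size} vs {b.size}")
    keep = (a != 0) & (b != 0)
    if keep.sum() < 2:
        raise InputError("fewer than 2 calls retained after noise discard")
    return a[keep], b[keep], int(keep.sum())


def threshold_check(nmi_value: float, delta_value: int) -> bool:
    """Pass iff NMI strictly exceeds 0.5 and delta-cluster is at most 1."""
    return bool(nmi_value > NMI_THRESHOLD and delta_value <= DELTA_THRESHOLD)


def noise_aligned_nmi(a_labels: Sequence[int], b_labels: Sequence[int]) -> float:
    x, y, _ = align_for_comparison(a_labels, b_labels)
    return nmi(x, y)


def concordance(results: list[ClusterResult],
                reference: Optional[Sequence[int]] = None) -> ConcordanceReport:
    """Pairwise NMI between clustering results, K summaries, and optional
    delta-cluster / NMI against a reference labeling."""
    if len(results) < 2:
        raise InputError("need at least 2 clustering results for concordance")
    n_calls = {len(r.labels) for r in results}
    if len(n_calls) != 1:
        raise InputError("clustering results cover different call sets")
    methods = [r.method for r in results]
    m = len(results)
    mat = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = noise_aligned_nmi(results[i].labels, results[j].labels)
    ks = [r.K for r in results]
    counts = pd.Series(ks).value_counts()
    k_mode = int(min(counts[counts == counts.max()].index))
    delta_ref = nmi_ref = None
    if reference is not None:
        ref = np.asarray(reference)
        if ref.size != n_calls.pop():
            raise InputError("reference labeling covers a different call set")
        k_ref = len(np.unique(ref[ref != 0]))
        delta_ref = [delta_cluster(r.K, k_ref) for r in results]
        nmi_ref = [noise_aligned_nmi(r.labels, ref) for r in results]
    return ConcordanceReport(
        methods=methods,
        nmi_matrix=pd.DataFrame(mat, index=methods, columns=methods),
        k_per_method=ks,
        k_median=float(np.median(ks)),
        k_mode=k_mode,
        delta_vs_reference=delta_ref,
        nmi_vs_reference=nmi_ref,
    )
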