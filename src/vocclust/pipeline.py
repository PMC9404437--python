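"""Orchestration of the full procedure grid.

A procedure is one path through the grid {features, spectra} x {all_in_one,
win, win_pct} x {knn_cd, knn_ap, dtw_cd, dtw_ap, xcorr_cd, xcorr_ap, hdbscan,
fuzzy} — 48 combinations in total. Similarity-based methods (``*_cd``,
``*_ap``) rank neighbors with the named classifier, build the Jaccard
similarity matrix with automatic k selection, and cluster it; vector-based
methods (``hdbscan``, ``fuzzy``) consume the flattened, z-scored row matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .audio_io import Vocalization, preprocess
from .clustering import (
    DEFAULT_SEED,
    ClusterResult,
    adaptive_affinity_propagation,
    community_detection,
    fuzzy_sweep,
    hdbscan_cluster,
)
from .errors import ParameterError, VocclustError
from .evaluation import concordance, noise_aligned_nmi, threshold_check
from .features import FEATURE_NAMES, extract_features
from .similarity import (
    auto_select_k,
    dtw_distance,
    knn_rank,
    rank_from_scores,
    score_matrix,
    xcorr_max,
)
from .transform import (
    RowMatrix,
    all_in_one_spectrum,
    plan_windows,
    reshape_to_row_matrix,
    windowed_spectrogram,
    zscore_columns,
    zscore_windowed,
)

REPRESENTATIONS = ("features", "spectra")
MODES = ("all_in_one", "win", "win_pct")
METHODS = ("knn_cd", "knn_ap", "dtw_cd", "dtw_ap", "xcorr_cd", "xcorr_ap",
           "hdbscan", "fuzzy")


@dataclass(frozen=True)
class ProcedureSpec:
    """One cell of the procedure grid plus preprocessing and seed."""

    representation: str
    mode: str
    method: str
    seed: int = DEFAULT_SEED
    highpass_hz: float = 600.0
    filter_order: int = 5
    xcorr_time_lag_only: bool = False
    k_grid: Optional[tuple] = None

    def __post_init__(self):
        if self.representation not in REPRESENTATIONS:
            raise ParameterError(f"unknown representation {self.representation!r}")
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}")

    @property
    def name(self) -> str:
        return f"{self.representation}-{self.mode}-{self.method}"


def all_procedures(seed: int = DEFAULT_SEED, highpass_hz: float = 600.0,
                   **kwargs) -> list[ProcedureSpec]:
    """Enumerate the full 48-procedure grid."""
    return [
        ProcedureSpec(representation=r, mode=m, method=meth, seed=seed,
                      highpass_hz=highpass_hz, **kwargs)
        for r in REPRESENTATIONS for m in MODES for meth in METHODS
    ]


def _feature_row_matrix(vectors: list[dict], call_ids: list[str]) -> RowMatrix:
    matrix = np.array([[vec[name] for name in FEATURE_NAMES] for vec in vectors])
    return RowMatrix(matrix=zscore_columns(matrix), call_ids=call_ids, zscored=True)


def _build_inputs(vocalizations: Sequence[Vocalization], spec: ProcedureSpec):
    """Transform preprocessed calls into the representation the method needs.

    Returns ``(row_matrix, per_call_matrices)``; exactly one is None except
    in all_in_one mode, where the z-scored rows double as the per-call
    vectors for DTW/Xcorr.
    """
    calls = [preprocess(v, spec.highpass_hz, order=spec.filter_order)
             for v in vocalizations]
    ids = [v.id for v in calls]
    plan = plan_windows(calls, spec.mode)
    vector_based = spec.method in ("knn_cd", "knn_ap", "hdbscan", "fuzzy")

    if spec.mode == "all_in_one":
        if spec.representation == "features":
            rows = _feature_row_matrix([extract_features(v, plan) for v in calls], ids)
        else:
            rows = RowMatrix(matrix=zscore_columns(
                np.vstack([all_in_one_spectrum(v) for v in calls])),
                call_ids=ids, zscored=True)
        mats = None if vector_based else [rows.matrix[i] for i in range(len(ids))]
        return rows, mats

    if spec.representation == "features":
        reps = [extract_features(v, plan) for v in calls]
    else:
        reps = [windowed_spectrogram(v, plan) for v in calls]
    if vector_based:
        return reshape_to_row_matrix(reps), None
    reps = zscore_windowed(reps)
    return None, [r.matrix for r in reps]


def run_procedure(vocalizations: Sequence[Vocalization],
                  spec: ProcedureSpec) -> ClusterResult:
    """Run one procedure end to end and return labels with provenance."""
    rows, mats = _build_inputs(vocalizations, spec)
    ids = [v.id for v in vocalizations]

    if spec.method == "hdbscan":
        result = hdbscan_cluster(rows)
    elif spec.method == "fuzzy":
        result = fuzzy_sweep(rows, seed=spec.seed)
    else:
        classifier, clusterer = spec.method.split("_")
        if classifier == "knn":
            ranking = knn_rank(rows)
        elif classifier == "dtw":
            ranking = rank_from_scores(score_matrix(mats, dtw_distance),
                                       "distance", call_ids=ids)
        else:  # xcorr
            scorer = lambda x, y: xcorr_max(x, y, time_lag_only=spec.xcorr_time_lag_only)
            ranking = rank_from_scores(score_matrix(mats, scorer),
                                       "correlation", call_ids=ids)
        cluster_fn = (community_detection if clusterer == "cd"
                      else lambda S: adaptive_affinity_propagation(S, seed=spec.seed))
        k_star, S_star, diagnostics = auto_select_k(
            ranking, cluster_fn, k_grid=spec.k_grid, classifier=classifier)
        result = cluster_fn(S_star)
        result.params["k_selection"] = diagnostics.to_dict(orient="list")
        result.params["k_used"] = k_star
    result.method = spec.name
    result.params["procedure"] = asdict(spec)
    result.call_ids = ids
    return result


def run_grid(vocalizations: Sequence[Vocalization],
             specs: Sequence[ProcedureSpec] | str = "all48",
             reference: Optional[Sequence[int]] = None):
    """Run many procedures; failures are recorded and the grid continues.

    Returns ``(results, report, summary)``: per-spec ClusterResults (None on
    failure), a :class:`ConcordanceReport` over the successful runs (None if
    fewer than 2), and a summary DataFrame with per-procedure K, silhouette,
    and — when a reference labeling is supplied — NMI, delta-cluster, and the
    pass/fail verdict at the NMI > 0.5, delta <= 1 thresholds.
    """
    if isinstance(specs, str):
        if specs != "all48":
            raise ParameterError(f"unknown grid preset {specs!r}")
        specs = all_procedures()
    if len(specs) < 2:
        raise ParameterError("need at least 2 procedures for a grid run")
    results: dict[str, Optional[ClusterResult]] = {}
    errors: dict[str, str] = {}
    for spec in specs:
        try:
            results[spec.name] = run_procedure(vocalizations, spec)
        except VocclustError as exc:
            results[spec.name] = None
            errors[spec.name] = str(exc)
    ok = [r for r in results.values() if r is not None]
    report = concordance(ok, reference=reference) if len(ok) >= 2 else None

    rows = []
    for spec in specs:
        res = results[spec.name]
        row = {"procedure": spec.name,
               "K": res.K if res else None,
               "silhouette": res.mean_silhouette if res else None,
               "error": errors.get(spec.name, "")}
        if reference is not None and res is not None:
            ref = np.asarray(reference)
            k_ref = len(np.unique(ref[ref != 0]))
            row["nmi"] = noise_aligned_nmi(res.labels, ref)
            row["delta_cluster"] = abs(res.K - k_ref)
            row["passes"] = threshold_check(row["nmi"], row["delta_cluster"])
        rows.append(row)
    return results, report, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization

def labels_frame(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame({"id": result.call_ids, "label": result.labels})


def write_labels(result: ClusterResult, path) -> None:
    labels_frame(result).to_csv(path, index=False)


def write_report(result: ClusterResult, path) -> None:
    payload = {
        "method": result.method,
        "K": int(result.K),
        "mean_silhouette": None if np.isnan(result.mean_silhouette) else float(result.mean_silhouette),
        "params": _jsonable(result.params),
        "stability_table": (result.stability_table.to_dict(orient="list")
                            if result.stability_table is not None else None),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj
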