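"""Data-transformation modes and reshaping.

Three modes are supported:

* ``all_in_one`` — one value per quantity for the whole call (single FFT or
  per-feature summary).
* ``win`` — fixed 2048-sample windows at 50% overlap; calls of different
  duration yield different window counts.
* ``win_pct`` — the window *count* is fixed to that of the shortest call
  (whose windows are 2048 samples) and the window *size* grows with call
  duration, still at 50% overlap.

Windowed per-call matrices (features-by-windows or frequency-bins-by-windows)
are consumed directly by DTW and cross-correlation; for vector-based methods
(kNN, HDBSCAN, fuzzy c-means) they are flattened window-by-window into one
row per call, zero-padded to the longest call, and z-scored per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import rfft, rfftfreq

from .audio_io import Vocalization
from .errors import InputError, ParameterError

Mode = Literal["all_in_one", "win", "win_pct"]

WINDOW_SAMPLES = 2048
OVERLAP = 0.5
FMAX_HZ = 20000.0
NBINS = 2000

#: fixed frequency grid: 10, 20, ..., 20000 Hz (2000 bins)
FREQ_GRID = np.arange(1, NBINS + 1) * (FMAX_HZ / NBINS)


@dataclass(frozen=True)
class WindowPlan:
    """Per-call windowing layout for one of the three modes."""

    mode: Mode
    window_length: dict[str, int]  # call id -> window length in samples
    n_windows: dict[str, int]      # call id -> number of windows
    overlap_fraction: float = OVERLAP

    def starts(self, call_id: str, n_samples: int) -> np.ndarray:
        """Window start offsets for one call; the last window is shifted to
        end exactly at the final sample so the whole call is covered."""
        w = self.window_length[call_id]
        L = self.n_windows[call_id]
        hop = w - int(round(w * self.overlap_fraction))
        starts = np.arange(L) * hop
        if L > 0:
            starts[-1] = min(starts[-1], n_samples - w)
        return starts


@dataclass(frozen=True)
class WindowedRepresentation:
    """Per-call matrix: m rows (features or frequency bins) x L windows."""

    call_id: str
    matrix: np.ndarray
    kind: Literal["features", "spectra"]
    plan: WindowPlan


@dataclass(frozen=True)
class RowMatrix:
    """N calls x M columns matrix for vector-based methods."""

    matrix: np.ndarray
    call_ids: list[str]
    column_meaning: list[tuple[int, int]] = field(default_factory=list)  # (row-dim, window)
    zscored: bool = False


def _win_count(n_samples: int) -> int:
    return (n_samples - WINDOW_SAMPLES) // (WINDOW_SAMPLES // 2) + 1


def plan_windows(vocalizations: list[Vocalization], mode: Mode) -> WindowPlan:
    """Compute per-call window lengths and counts for the requested mode.

    ``win``: every window is 2048 samples, hop 1024, L = floor((n-2048)/1024)+1.
    ``win_pct``: L is fixed to the shortest call's ``win`` window count, and
    each call's window length is w = floor(2n/(L+1)), which makes L windows at
    50% overlap span the call (shortest call: w == 2048 up to rounding).
    """
    if not vocalizations:
        raise InputError("no vocalizations supplied")
    lengths = {v.id: v.n_samples for v in vocalizations}
    if mode == "all_in_one":
        return WindowPlan(mode="all_in_one",
                          window_length=dict(lengths),
                          n_windows={cid: 1 for cid in lengths})
    too_short = [cid for cid, n in lengths.items() if n < WINDOW_SAMPLES]
    if too_short:
        raise InputError(
            f"calls shorter than one {WINDOW_SAMPLES}-sample window: {too_short}"
        )
    if mode == "win":
        return WindowPlan(mode="win",
                          window_length={cid: WINDOW_SAMPLES for cid in lengths},
                          n_windows={cid: _win_count(n) for cid, n in lengths.items()})
    if mode == "win_pct":
        L = min(_win_count(n) for n in lengths.values())
        window_length = {cid: (2 * n) // (L + 1) for cid, n in lengths.items()}
        return WindowPlan(mode="win_pct",
                          window_length=window_length,
                          n_windows={cid: L for cid in lengths})
    raise ParameterError(f"unknown transformation mode {mode!r}")


def _interp_to_grid(native_freqs: np.ndarray, values: np.ndarray,
                    sample_rate: int) -> np.ndarray:
    """Linearly interpolate a native-resolution spectrum onto the fixed grid.

    2048-sample windows cannot natively resolve the 10 Hz grid step, so the
    magnitudes are interpolated rather than zero-padded to length.
    """
    if sample_rate < 2 * FMAX_HZ:
        raise ParameterError(
            f"sample rate {sample_rate} Hz cannot represent the {FMAX_HZ:.0f} Hz "
            "frequency ceiling; lower fmax via configuration"
        )
    return np.interp(FREQ_GRID, native_freqs, values)


def all_in_one_spectrum(v: Vocalization) -> np.ndarray:
    """Magnitude spectrum of the whole call on the fixed 2000-bin grid."""
    spec = np.abs(rfft(v.samples))
    freqs = rfftfreq(v.n_samples, d=1.0 / v.sample_rate)
    return _interp_to_grid(freqs, spec, v.sample_rate)


def windowed_spectrogram(v: Vocalization, plan: WindowPlan) -> WindowedRepresentation:
    """Hamming-tapered power spectrum per window on the fixed 2000-bin grid."""
    w = plan.window_length[v.id]
    starts = plan.starts(v.id, v.n_samples)
    taper = sp_signal.get_window("hamming", w)
    freqs = rfftfreq(w, d=1.0 / v.sample_rate)
    cols = []
    for s in starts:
        seg = v.samples[s:s + w] * taper
        power = np.abs(rfft(seg)) ** 2
        cols.append(_interp_to_grid(freqs, power, v.sample_rate))
    matrix = np.column_stack(cols)
    return WindowedRepresentation(call_id=v.id, matrix=matrix, kind="spectra", plan=plan)


def zscore_columns(matrix: np.ndarray) -> np.ndarray:
    """Z-score each column; zero-variance columns are left at 0."""
    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    out = matrix - mean
    nonconst = std > 0
    out[:, nonconst] /= std[nonconst]
    out[:, ~nonconst] = 0.0
    return out


def zscore_windowed(reps: list[WindowedRepresentation]) -> list[WindowedRepresentation]:
    """Z-score each feature/bin dimension with statistics pooled over all
    windows of all calls, so per-call matrices share one common scale."""
    pooled = np.concatenate([r.matrix for r in reps], axis=1)
    mean = pooled.mean(axis=1, keepdims=True)
    std = pooled.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return [
        WindowedRepresentation(call_id=r.call_id, matrix=(r.matrix - mean) / std,
                               kind=r.kind, plan=r.plan)
        for r in reps
    ]


def reshape_to_row_matrix(reps: list[WindowedRepresentation], zscore: bool = True) -> RowMatrix:
    """Flatten per-call matrices window-by-window into an N x (m * L_max)
    matrix, zero-padding calls with fewer windows, then z-score per column."""
    kinds = {r.kind for r in reps}
    if len(kinds) != 1:
        raise InputError(f"mixed representation kinds: {sorted(kinds)}")
    m_set = {r.matrix.shape[0] for r in reps}
    if len(m_set) != 1:
        raise InputError(f"inconsistent row dimensions across calls: {sorted(m_set)}")
    m = m_set.pop()
    l_max = max(r.matrix.shape[1] for r in reps)
    rows = np.zeros((len(reps), m * l_max))
    for i, r in enumerate(reps):
        L = r.matrix.shape[1]
        rows[i, : m * L] = r.matrix.T.reshape(-1)  # window 1's m values first
    if zscore:
        rows = zscore_columns(rows)
    meaning = [(dim, win) for win in range(l_max) for dim in range(m)]
    return RowMatrix(matrix=rows, call_ids=[r.call_id for r in reps],
                     column_meaning=meaning, zscored=zscore)


def unflatten_row(row: np.ndarray, m: int) -> np.ndarray:
    """Inverse of the window-by-window flattening (pre-z-score)."""
    return row.reshape(-1, m).T
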