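"""Acoustic feature extraction.

Twenty-seven features are computed per call (all-in-one mode) or per window
(windowed modes). In ``win`` mode the window count already encodes duration,
so Duration is omitted (26 features per window); in ``win_pct`` mode every
call has the same number of windows, so the whole-call Duration is repeated
in each window (27 features per window).

Feature definitions (units in parentheses):

* F0 (Hz) — fundamental frequency by normalized autocorrelation peak picking;
  all-in-one reports the median over 2048-sample windows.
* DeltaF0 (Hz) — difference between adjacent per-window F0 values (first
  window: 0); all-in-one reports the median difference.
* DominantF (Hz) — frequency with the highest spectral amplitude.
* MinF / MaxF / Bandwidth (Hz) — bounds and width of the 99% occupied
  bandwidth (0.5% of cumulative spectral power trimmed at each side).
* Duration (s) — onset-to-offset duration of the whole call.
* Q1/Q2/Q3 (Hz) — frequencies at 25/50/75% of cumulative spectral energy.
* MaxQ1..MaxQ4 (Hz) — peak-amplitude frequency within each quartile band.
* FB1..FB3 (Hz) — the first three peaks of the LPC spectral envelope
  (order 205), ascending in frequency.
* BW_FB1..BW_FB3 (Hz) — width of each envelope peak at half prominence.
* DeltaFB1FB2 / DeltaFB2FB3 (Hz) — differences between adjacent bands.
* NumFB — number of envelope peaks with prominence >= 1% of the envelope max.
* HarmonicRatio (0-1) — maximum normalized autocorrelation over pitch lags.
* SpectralFlatness (>= 0) — geometric / arithmetic mean of spectral power.
* MFCC1 / MFCC2 — first two mel-frequency cepstral coefficients (40 mel
  bands, DCT-II, indexing after the 0th energy coefficient).

Unvoiced or unstable windows yield missing values for F0/FB features; these
are imputed with 0 so no NaN reaches the clustering stage.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal
from scipy.fft import dct, rfft, rfftfreq
from scipy.linalg import solve_toeplitz

from .audio_io import Vocalization
from .errors import DegenerateInputError, InputError
from .transform import WINDOW_SAMPLES, WindowPlan, WindowedRepresentation

FEATURE_NAMES = [
    "F0", "DeltaF0", "DominantF", "MinF", "MaxF", "Bandwidth", "Duration",
    "Q1", "Q2", "Q3", "MaxQ1", "MaxQ2", "MaxQ3", "MaxQ4",
    "FB1", "FB2", "FB3", "BW_FB1", "BW_FB2", "BW_FB3",
    "DeltaFB1FB2", "DeltaFB2FB3", "NumFB",
    "HarmonicRatio", "SpectralFlatness", "MFCC1", "MFCC2",
]

#: default pitch search band (Hz); covers tonal calls after high-pass filtering
PITCH_FMIN = 100.0
PITCH_FMAX = 4000.0
#: normalized-correlation peak below this is treated as unvoiced
NCF_THRESHOLD = 0.3
LPC_ORDER = 205
N_MELS = 40


def feature_names_for_mode(mode: str) -> list[str]:
    if mode == "win":
        return [n for n in FEATURE_NAMES if n != "Duration"]
    return list(FEATURE_NAMES)


# ---------------------------------------------------------------------------
# time-domain features

def _normalized_autocorrelation(x: np.ndarray, lag_min: int, lag_max: int) -> np.ndarray:
    """NCF(m) = sum(x[n] x[n+m]) / sqrt(sum head^2 * sum tail^2) for
    m in [lag_min, lag_max]."""
    n = x.shape[0]
    lag_max = min(lag_max, n - 2)
    if lag_max < lag_min:
        return np.empty(0)
    full = sp_signal.correlate(x, x, mode="full", method="fft")
    num = full[n - 1 + lag_min: n + lag_max]
    e = np.cumsum(x ** 2)
    lags = np.arange(lag_min, lag_max + 1)
    head = e[n - lags - 1]
    tail = e[-1] - np.concatenate(([0.0], e))[lags]
    denom = np.sqrt(head * tail)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def fundamental_frequency(window_samples: np.ndarray, sample_rate: int,
                          fmin: float = PITCH_FMIN, fmax: float = PITCH_FMAX,
                          threshold: float = NCF_THRESHOLD) -> float:
    """Pitch estimate in Hz, or NaN when the window is unvoiced.

    Picks the highest normalized-autocorrelation peak within the search band
    (ties broken toward smaller lag) and refines it by parabolic
    interpolation.
    """
    x = np.asarray(window_samples, dtype=np.float64)
    lag_min = max(2, int(np.floor(sample_rate / fmax)))
    lag_max = int(np.ceil(sample_rate / fmin))
    ncf = _normalized_autocorrelation(x, lag_min, lag_max)
    if ncf.size < 3:
        return np.nan
    peaks, _ = sp_signal.find_peaks(ncf)
    if peaks.size == 0:
        return np.nan
    best_val = np.max(ncf[peaks])
    if best_val < threshold:
        return np.nan
    # a periodic signal peaks at every multiple of its period; prefer the
    # smallest lag (highest pitch) among near-maximal peaks to avoid octave
    # errors toward subharmonics
    best = int(peaks[ncf[peaks] >= best_val - 0.025][0])
    # parabolic refinement around the peak
    if 0 < best < ncf.size - 1:
        y0, y1, y2 = ncf[best - 1], ncf[best], ncf[best + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    lag = lag_min + best + shift
    return sample_rate / lag


def harmonic_ratio(window_samples: np.ndarray, sample_rate: int,
                   fmin: float = PITCH_FMIN, fmax: float = PITCH_FMAX) -> float:
    """Maximum normalized autocorrelation over pitch lags, clipped to [0, 1]."""
    x = np.asarray(window_samples, dtype=np.float64)
    if x.size == 0:
        raise InputError("empty window")
    lag_min = max(2, int(np.floor(sample_rate / fmax)))
    lag_max = int(np.ceil(sample_rate / fmin))
    ncf = _normalized_autocorrelation(x, lag_min, lag_max)
    if ncf.size == 0:
        return 0.0
    return float(np.clip(np.max(ncf), 0.0, 1.0))


def lpc_frequency_bands(window_samples: np.ndarray, sample_rate: int,
                        order: int = LPC_ORDER, n_grid: int = 1024) -> dict[str, float]:
    """Spectral-envelope bands from a linear-predictive fit.

    The all-pole envelope of the stated order is evaluated on a frequency
    grid up to Nyquist; its peaks (prominence >= 1% of envelope max), sorted
    ascending in frequency, give FB1-FB3 with half-prominence widths.
    Missing bands and unstable solves yield NaN markers.
    """
    x = np.asarray(window_samples, dtype=np.float64)
    nan = {k: np.nan for k in ("FB1", "FB2", "FB3", "BW_FB1", "BW_FB2", "BW_FB3",
                               "DeltaFB1FB2", "DeltaFB2FB3", "NumFB")}
    order = min(order, x.size - 2)
    if order < 2 or not np.any(x):
        return nan
    full = sp_signal.correlate(x, x, mode="full", method="fft")
    r = full[x.size - 1: x.size + order]
    try:
        a = solve_toeplitz((r[:order], r[:order]), -r[1: order + 1])
    except np.linalg.LinAlgError:
        return nan
    if not np.all(np.isfinite(a)):
        return nan
    coeffs = np.concatenate(([1.0], a))
    freqs = np.linspace(0.0, sample_rate / 2, n_grid)
    _, h = sp_signal.freqz(1.0, coeffs, worN=freqs, fs=sample_rate)
    env = np.abs(h)
    if not np.all(np.isfinite(env)) or env.max() == 0:
        return nan
    df = freqs[1] - freqs[0]
    peaks, props = sp_signal.find_peaks(env, prominence=0.01 * env.max(), width=0)
    out = dict(nan)
    out["NumFB"] = float(peaks.size)
    fb = freqs[peaks]
    bw = props["widths"] * df
    for i in range(min(3, peaks.size)):
        out[f"FB{i+1}"] = float(fb[i])
        out[f"BW_FB{i+1}"] = float(bw[i])
    if peaks.size >= 2:
        out["DeltaFB1FB2"] = float(fb[1] - fb[0])
    if peaks.size >= 3:
        out["DeltaFB2FB3"] = float(fb[2] - fb[1])
    return out


def mfcc_pair(window_samples: np.ndarray, sample_rate: int,
              n_mels: int = N_MELS) -> tuple[float, float]:
    """First two mel-frequency cepstral coefficients of the window."""
    x = np.asarray(window_samples, dtype=np.float64)
    if x.size == 0:
        raise InputError("empty window")
    taper = sp_signal.get_window("hamming", x.size)
    power = np.abs(rfft(x * taper)) ** 2
    freqs = rfftfreq(x.size, d=1.0 / sample_rate)
    fb = _mel_filterbank(freqs, sample_rate, n_mels)
    energies = fb @ power
    cepstrum = dct(np.log(energies + 1e-12), type=2, norm="ortho")
    return float(cepstrum[1]), float(cepstrum[2])


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(freqs: np.ndarray, sample_rate: int, n_mels: int) -> np.ndarray:
    edges = _mel_to_hz(np.linspace(0.0, _hz_to_mel(sample_rate / 2), n_mels + 2))
    bank = np.zeros((n_mels, freqs.size))
    for i in range(n_mels):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        rising = (freqs - lo) / (mid - lo)
        falling = (hi - freqs) / (hi - mid)
        bank[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return bank


# ---------------------------------------------------------------------------
# spectrum-domain features

def occupied_bandwidth_99(spectrum: np.ndarray, freq_grid: np.ndarray) -> tuple[float, float, float]:
    """Smallest central band holding 99% of spectral power.

    Trims 0.5% of cumulative power at each side; returns (MinF, MaxF,
    Bandwidth). The input is a magnitude spectrum; power is its square.
    """
    power = np.asarray(spectrum, dtype=np.float64) ** 2
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero spectrum")
    c = np.cumsum(power)
    lo = int(np.searchsorted(c, 0.005 * total, side="left"))
    hi = int(np.searchsorted(c, 0.995 * total, side="left"))
    fmin, fmax = float(freq_grid[lo]), float(freq_grid[hi])
    return fmin, fmax, fmax - fmin


def energy_quartiles(spectrum: np.ndarray, freq_grid: np.ndarray) -> dict[str, float]:
    """Quartile frequencies of the cumulative spectral energy plus the
    peak-amplitude frequency within each quartile band."""
    power = np.asarray(spectrum, dtype=np.float64) ** 2
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero spectrum")
    c = np.cumsum(power)
    idx = [int(np.searchsorted(c, q * total, side="left")) for q in (0.25, 0.5, 0.75)]
    out = {"Q1": float(freq_grid[idx[0]]),
           "Q2": float(freq_grid[idx[1]]),
           "Q3": float(freq_grid[idx[2]])}
    bounds = [0, idx[0], idx[1], idx[2], spectrum.size - 1]
    for band in range(4):
        lo, hi = bounds[band], bounds[band + 1]
        seg = np.asarray(spectrum[lo: hi + 1])
        out[f"MaxQ{band+1}"] = float(freq_grid[lo + int(np.argmax(seg))])
    return out


def spectral_flatness(spectrum: np.ndarray) -> float:
    """Geometric over arithmetic mean of spectral power (1 = flat/noisy)."""
    power = np.asarray(spectrum, dtype=np.float64) ** 2
    if power.sum() <= 0:
        raise DegenerateInputError("all-zero spectrum")
    eps = 1e-12
    gm = np.exp(np.mean(np.log(power + eps)))
    am = np.mean(power + eps)
    return float(gm / am)


def dominant_frequency(spectrum: np.ndarray, freq_grid: np.ndarray) -> float:
    return float(freq_grid[int(np.argmax(spectrum))])


# ---------------------------------------------------------------------------
# assembly

def _window_segments(v: Vocalization, plan: WindowPlan):
    w = plan.window_length[v.id]
    for s in plan.starts(v.id, v.n_samples):
        yield v.samples[s: s + w]


def _default_segments(samples: np.ndarray):
    """2048-sample, 50%-overlap segmentation used by the all-in-one summary
    of intrinsically windowed features; short calls yield one whole-call
    segment."""
    n = samples.shape[0]
    if n < WINDOW_SAMPLES:
        yield samples
        return
    hop = WINDOW_SAMPLES // 2
    for s in range(0, n - WINDOW_SAMPLES + 1, hop):
        yield samples[s: s + WINDOW_SAMPLES]


def _segment_features(seg: np.ndarray, sample_rate: int,
                      lpc_order: int) -> dict[str, float]:
    """All per-window features for one time-domain segment."""
    spec = np.abs(rfft(seg * sp_signal.get_window("hamming", seg.size)))
    freqs = rfftfreq(seg.size, d=1.0 / sample_rate)
    out = {"F0": fundamental_frequency(seg, sample_rate)}
    out["DominantF"] = dominant_frequency(spec, freqs)
    if spec.sum() > 0:
        out["MinF"], out["MaxF"], out["Bandwidth"] = occupied_bandwidth_99(spec, freqs)
        out.update(energy_quartiles(spec, freqs))
        out["SpectralFlatness"] = spectral_flatness(spec)
    else:
        for k in ("MinF", "MaxF", "Bandwidth", "Q1", "Q2", "Q3",
                  "MaxQ1", "MaxQ2", "MaxQ3", "MaxQ4", "SpectralFlatness"):
            out[k] = np.nan
    out.update(lpc_frequency_bands(seg, sample_rate, order=lpc_order))
    out["HarmonicRatio"] = harmonic_ratio(seg, sample_rate)
    out["MFCC1"], out["MFCC2"] = mfcc_pair(seg, sample_rate)
    return out


def extract_features(v: Vocalization, plan: WindowPlan,
                     lpc_order: int = LPC_ORDER, impute: bool = True):
    """Extract the feature set for one call under a window plan.

    Returns a dict of 27 named values for ``all_in_one`` or a
    :class:`WindowedRepresentation` (kind ``features``) with 26 (``win``) or
    27 (``win_pct``) rows for the windowed modes. Missing values (unvoiced
    windows, absent LPC bands) are imputed with 0 when ``impute`` is true.
    """
    if plan.mode == "all_in_one":
        vec = _all_in_one_vector(v, lpc_order)
        if impute:
            vec = {k: (0.0 if not np.isfinite(val) else float(val)) for k, val in vec.items()}
        return vec

    names = feature_names_for_mode(plan.mode)
    per_window = [
        _segment_features(seg, v.sample_rate, lpc_order)
        for seg in _window_segments(v, plan)
    ]
    f0s = np.array([w["F0"] for w in per_window])
    deltas = np.concatenate(([0.0], np.diff(f0s)))
    matrix = np.empty((len(names), len(per_window)))
    for j, wfeat in enumerate(per_window):
        wfeat = dict(wfeat)
        wfeat["DeltaF0"] = deltas[j]
        wfeat["Duration"] = v.duration_s  # only consumed in win_pct
        matrix[:, j] = [wfeat[name] for name in names]
    if impute:
        matrix = np.nan_to_num(matrix, nan=0.0)
    return WindowedRepresentation(call_id=v.id, matrix=matrix, kind="features", plan=plan)


def _all_in_one_vector(v: Vocalization, lpc_order: int) -> dict[str, float]:
    """27-entry summary: whole-call spectrum features plus medians of the
    per-window values for intrinsically windowed features."""
    spec = np.abs(rfft(v.samples))
    freqs = rfftfreq(v.n_samples, d=1.0 / v.sample_rate)
    out: dict[str, float] = {}
    out["DominantF"] = dominant_frequency(spec, freqs)
    out["MinF"], out["MaxF"], out["Bandwidth"] = occupied_bandwidth_99(spec, freqs)
    out.update(energy_quartiles(spec, freqs))
    out["SpectralFlatness"] = spectral_flatness(spec)
    out["Duration"] = v.duration_s

    windowed = [_segment_features(seg, v.sample_rate, lpc_order)
                for seg in _default_segments(v.samples)]
    with np.errstate(all="ignore"):
        f0s = np.array([w["F0"] for w in windowed])
        out["F0"] = float(np.nanmedian(f0s)) if np.any(np.isfinite(f0s)) else np.nan
        d = np.diff(f0s)
        out["DeltaF0"] = float(np.nanmedian(d)) if d.size and np.any(np.isfinite(d)) else 0.0
        for key in ("FB1", "FB2", "FB3", "BW_FB1", "BW_FB2", "BW_FB3",
                    "DeltaFB1FB2", "DeltaFB2FB3", "NumFB",
                    "HarmonicRatio", "MFCC1", "MFCC2"):
            vals = np.array([w[key] for w in windowed])
            out[key] = float(np.nanmedian(vals)) if np.any(np.isfinite(vals)) else np.nan
    return {name: out[name] for name in FEATURE_NAMES}


def feature_table(vocalizations: list[Vocalization], plan: WindowPlan,
                  lpc_order: int = LPC_ORDER):
    """Extract features for every call; returns a list of per-call results
    in input order (dicts for all_in_one, WindowedRepresentations otherwise)."""
    return [extract_features(v, plan, lpc_order=lpc_order) for v in vocalizations]
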