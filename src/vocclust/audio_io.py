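"""Loading and preconditioning of segmented vocalization audio.

Each vocalization is a single pre-segmented call: a mono amplitude series
plus its sample rate. Preprocessing is peak normalization to 1 followed by a
zero-phase high-pass Butterworth filter (default fifth order) that removes
low-frequency background noise, then renormalization so downstream energy
features stay on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import DegenerateInputError, InputError, ParameterError


@dataclass(frozen=True)
class Vocalization:
    """One segmented call.

    Attributes
    ----------
    id : str
        Caller-chosen identifier, unique within a data set.
    samples : np.ndarray
        Real-valued amplitude series (dimensionless; peak-normalized after
        :func:`normalize_amplitude`).
    sample_rate : int
        Sampling rate in Hz.
    true_label : int, optional
        A-priori class label (positive integer) used only for evaluation.
    """

    id: str
    samples: np.ndarray
    sample_rate: int
    true_label: Optional[int] = None

    @property
    def duration_s(self) -> float:
        """Call duration in seconds (= n_samples / sample_rate)."""
        return self.samples.shape[0] / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def load_vocalization(path, id: str, true_label: Optional[int] = None) -> Vocalization:
    """Read one mono (or stereo, averaged to mono) PCM/float WAV file.

    No resampling is performed: the file's own sample rate is kept.
    """
    path = Path(path)
    try:
        sr, data = wavfile.read(path)
    except FileNotFoundError:
        raise InputError(f"cannot read audio file: {path} (not found)")
    except ValueError as exc:
        raise InputError(f"cannot read audio file: {path} ({exc})")
    if data.size == 0:
        raise InputError(f"zero-length audio in {path}")
    samples = np.asarray(data, dtype=np.float64)
    if samples.ndim == 2:  # stereo: average channels, length preserved
        samples = samples.mean(axis=1)
    # rescale integer PCM to [-1, 1]
    if np.issubdtype(data.dtype, np.integer):
        samples = samples / float(np.iinfo(data.dtype).max)
    return Vocalization(id=id, samples=samples, sample_rate=int(sr), true_label=true_label)


def read_manifest(path) -> list[Vocalization]:
    """Load a batch of calls from a manifest CSV with columns id,path[,true_label]."""
    table = pd.read_csv(path)
    if "id" not in table.columns or "path" not in table.columns:
        raise InputError(f"manifest {path} must have columns id,path[,true_label]")
    base = Path(path).parent
    calls = []
    for row in table.itertuples(index=False):
        wav = Path(row.path)
        if not wav.is_absolute():
            wav = base / wav
        label = int(row.true_label) if "true_label" in table.columns and not pd.isna(row.true_label) else None
        calls.append(load_vocalization(wav, id=str(row.id), true_label=label))
    return calls


def normalize_amplitude(v: Vocalization) -> Vocalization:
    """Peak-normalize so that max(|samples|) == 1."""
    peak = np.max(np.abs(v.samples))
    if peak == 0:
        raise DegenerateInputError(f"call {v.id!r} is silent (all-zero samples)")
    return replace(v, samples=v.samples / peak)


def highpass_filter(v: Vocalization, cutoff: float, order: int = 5) -> Vocalization:
    """Zero-phase Butterworth high-pass filter.

    Applied forward-backward (``sosfiltfilt``) to avoid phase distortion of
    frequency contours; the effective magnitude response is thus the squared
    Butterworth response, which only steepens the stop-band rejection.
    """
    nyquist = v.sample_rate / 2
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"high-pass cutoff {cutoff} Hz must lie in (0, {nyquist}) Hz for call {v.id!r}"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=v.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, v.samples)
    return replace(v, samples=filtered)


def preprocess(v: Vocalization, highpass_hz: float = 600.0, order: int = 5) -> Vocalization:
    """Standard preconditioning: normalize, high-pass, renormalize peak to 1."""
    v = normalize_amplitude(v)
    v = highpass_filter(v, highpass_hz, order=order)
    return normalize_amplitude(v)
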