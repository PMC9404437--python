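"""Synthetic labeled vocalizations for end-to-end testing.

Two study scenarios are emulated:

* **Repertoire** — several distinct vocal types of one species (tonal,
  harmonic calls differing in fundamental-frequency register, contour shape,
  duration, and harmonic content), as when establishing a species' call
  repertoire.
* **Individual signatures** — one shared call type whose frequency-modulation
  contour carries individual identity (as in cohesion/contact calls): all
  individuals share the same register, bandwidth, and duration range, so
  whole-call feature summaries are nearly identical, while the windowed
  contours differ clearly in shape.

Calls are built by additive harmonic synthesis along a piecewise-linear
fundamental-frequency contour, shaped by an attack/sustain/release envelope,
with white Gaussian noise at a target signal-to-noise ratio and per-call
multiplicative jitter on pitch, duration, and SNR. Generation is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import Vocalization
from .errors import ParameterError

#: default per-call jitter: (f0 fraction, duration fraction, SNR dB)
DEFAULT_JITTER = (0.02, 0.05, 2.0)


@dataclass(frozen=True)
class CallTemplate:
    """Parametric description of one call type (or individual signature)."""

    f0_contour: tuple  # ((time_fraction, hz), ...) piecewise-linear control points
    duration_s: float
    n_harmonics: int = 3
    harmonic_rolloff_db: float = 6.0
    amplitude_envelope: tuple = (0.1, 0.8, 0.1)  # attack/sustain/release fractions
    noise_snr_db: float = 25.0
    jitter: tuple = DEFAULT_JITTER  # (f0 fraction, duration fraction, snr dB)
    name: str = ""

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")
        if self.n_harmonics < 1:
            raise ParameterError("need at least one harmonic")
        if any(hz <= 0 for _, hz in self.f0_contour):
            raise ParameterError("contour frequencies must be positive")


def synth_call(template: CallTemplate, sample_rate: int, seed: int,
               id: str = "call", true_label: int | None = None) -> Vocalization:
    """Render one call from a template (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    jf, jd, jsnr = template.jitter
    f0_scale = 1.0 + jf * rng.standard_normal()
    duration = template.duration_s * (1.0 + jd * rng.standard_normal())
    snr_db = template.noise_snr_db + jsnr * rng.standard_normal()

    n = max(int(round(duration * sample_rate)), 16)
    t_frac = np.arange(n) / max(n - 1, 1)
    pts = np.asarray(template.f0_contour, dtype=float)
    f0 = np.interp(t_frac, pts[:, 0], pts[:, 1]) * f0_scale
    if f0.max() >= sample_rate / 2:
        raise ParameterError(
            f"contour peak {f0.max():.0f} Hz exceeds Nyquist for {sample_rate} Hz"
        )
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    sig = np.zeros(n)
    for h in range(1, template.n_harmonics + 1):
        if h * f0.max() >= 0.45 * sample_rate:
            break
        amp = 10.0 ** (-template.harmonic_rolloff_db * (h - 1) / 20.0)
        sig += amp * np.sin(h * phase)

    attack, sustain, release = template.amplitude_envelope
    env = np.ones(n)
    na, nr = int(attack * n), int(release * n)
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na)
    if nr > 0:
        env[-nr:] = np.linspace(1.0, 0.0, nr)
    sig *= env

    sig_power = np.mean(sig ** 2)
    noise_power = sig_power / (10.0 ** (snr_db / 10.0))
    sig += np.sqrt(noise_power) * rng.standard_normal(n)
    sig /= np.max(np.abs(sig))
    return Vocalization(id=id, samples=sig, sample_rate=sample_rate, true_label=true_label)


# ---------------------------------------------------------------------------
# repertoire scenario (several vocal types of one species)

def _repertoire_templates(separation: str) -> list[CallTemplate]:
    if separation == "easy":
        # types differ in register, contour, duration, and harmonic content;
        # between-type F0 separation >> within-type jitter SD
        return [
            CallTemplate(f0_contour=((0.0, 800.0), (1.0, 800.0)), duration_s=0.40,
                         n_harmonics=4, harmonic_rolloff_db=6.0, name="flat-low"),
            CallTemplate(f0_contour=((0.0, 1400.0), (1.0, 1900.0)), duration_s=0.25,
                         n_harmonics=3, harmonic_rolloff_db=8.0, name="rise-mid"),
            CallTemplate(f0_contour=((0.0, 2700.0), (1.0, 2100.0)), duration_s=0.55,
                         n_harmonics=2, harmonic_rolloff_db=10.0, name="fall-high"),
            CallTemplate(f0_contour=((0.0, 3200.0), (0.5, 3800.0), (1.0, 3200.0)),
                         duration_s=0.20, n_harmonics=1, name="peak-top"),
            CallTemplate(f0_contour=((0.0, 1050.0), (1.0, 1050.0)), duration_s=0.70,
                         n_harmonics=6, harmonic_rolloff_db=4.0, name="flat-long"),
        ]
    if separation == "hard":
        # shared register and duration; types differ only in modulation depth
        return [
            CallTemplate(f0_contour=((0.0, 1200.0), (1.0, 1200.0)), duration_s=0.4,
                         name="depth-0"),
            CallTemplate(f0_contour=((0.0, 1100.0), (0.5, 1300.0), (1.0, 1100.0)),
                         duration_s=0.4, name="depth-200"),
            CallTemplate(f0_contour=((0.0, 1000.0), (0.5, 1400.0), (1.0, 1000.0)),
                         duration_s=0.4, name="depth-400"),
            CallTemplate(f0_contour=((0.0, 900.0), (0.5, 1500.0), (1.0, 900.0)),
                         duration_s=0.4, name="depth-600"),
            CallTemplate(f0_contour=((0.0, 800.0), (0.5, 1600.0), (1.0, 800.0)),
                         duration_s=0.4, name="depth-800"),
        ]
    raise ParameterError(f"unknown separation level {separation!r}")


def generate_repertoire(n_types: int = 5, calls_per_type: int = 20,
                        separation: str = "easy", sample_rate: int = 48000,
                        seed: int = 42) -> list[Vocalization]:
    """Labeled synthetic repertoire: ``n_types`` vocal types of one species."""
    if n_types < 2:
        raise ParameterError("need at least 2 vocal types")
    templates = _repertoire_templates(separation)
    if n_types > len(templates):
        raise ParameterError(f"at most {len(templates)} built-in vocal types")
    root = np.random.default_rng(seed)
    calls = []
    for label, tpl in enumerate(templates[:n_types], start=1):
        for c in range(calls_per_type):
            call_seed = int(root.integers(0, 2**31 - 1))
            calls.append(synth_call(tpl, sample_rate, seed=call_seed,
                                    id=f"type{label}_call{c:03d}", true_label=label))
    return calls


# ---------------------------------------------------------------------------
# individual-signature scenario (one call type, per-individual FM contours)

def _phase_contour(phase: float, n_cycles: int = 2, points_per_cycle: int = 16,
                   center: float = 1350.0, depth: float = 450.0) -> tuple:
    """Whole cycles of an FM archetype, phase-shifted per individual:
    f(t) = center + depth sin(2π(n_cycles t - φ)).

    All phases share the same register, bandwidth, duration, and — crucially —
    the same distribution of instantaneous frequencies and slopes, so every
    time-invariant (whole-call) summary coincides across individuals and only
    the time course of the contour carries identity.
    """
    ts = np.linspace(0.0, 1.0, n_cycles * points_per_cycle + 1)
    return tuple(
        (float(t), float(center + depth * np.sin(2 * np.pi * (n_cycles * t - phase))))
        for t in ts)


#: per-individual FM signatures: quarter-cycle phase shifts of one archetype
_SIGNATURE_CONTOURS = (
    ("phase-0", _phase_contour(0.0)),
    ("phase-quarter", _phase_contour(0.25)),
    ("phase-half", _phase_contour(0.5)),
    ("phase-three-quarter", _phase_contour(0.75)),
)


def generate_individual_signatures(n_individuals: int = 4,
                                   calls_each: tuple = (5, 6, 7, 12),
                                   sample_rate: int = 96000,
                                   seed: int = 42) -> list[Vocalization]:
    """Labeled cohesion-call set: one shared archetype, per-individual FM
    signature contours, so all-in-one summaries are confusable while windowed
    contours separate the individuals."""
    if n_individuals < 2:
        raise ParameterError("need at least 2 individuals")
    if n_individuals > len(_SIGNATURE_CONTOURS):
        raise ParameterError(f"at most {len(_SIGNATURE_CONTOURS)} signature shapes")
    if len(calls_each) != n_individuals:
        raise ParameterError("calls_each must list one count per individual")
    root = np.random.default_rng(seed)
    calls = []
    for label, ((name, contour), count) in enumerate(
            zip(_SIGNATURE_CONTOURS[:n_individuals], calls_each), start=1):
        # brief onset/offset ramps: a long attack/release would weight the
        # whole-call spectrum by what the contour does at the call edges,
        # re-introducing the time-frequency coupling the scenario excludes
        tpl = CallTemplate(f0_contour=contour, duration_s=0.9, n_harmonics=3,
                           harmonic_rolloff_db=8.0, noise_snr_db=25.0,
                           amplitude_envelope=(0.03, 0.94, 0.03),
                           jitter=(0.02, 0.05, 2.0), name=name)
        for c in range(count):
            call_seed = int(root.integers(0, 2**31 - 1))
            calls.append(synth_call(tpl, sample_rate, seed=call_seed,
                                    id=f"ind{label}_call{c:03d}", true_label=label))
    return calls


def write_wav_set(calls: list[Vocalization], out_dir) -> "Path":
    """Write calls as 32-bit float WAVs plus a manifest CSV (id,path,true_label)."""
    from pathlib import Path

    import pandas as pd
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for v in calls:
        fname = f"{v.id}.wav"
        wavfile.write(out / fname, v.sample_rate, v.samples.astype(np.float32))
        rows.append({"id": v.id, "path": fname, "true_label": v.true_label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
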