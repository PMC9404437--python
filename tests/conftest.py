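"""Shared fixtures: deterministic synthetic signals and call sets."""

import numpy as np
import pytest

from vocclust import Vocalization, generate_individual_signatures, generate_repertoire

SR = 48000


def tone(freq_hz, duration_s=1.0, sr=SR, amplitude=1.0):
    t = np.arange(int(duration_s * sr)) / sr
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


def make_call(samples, sr=SR, id="call", label=None):
    return Vocalization(id=id, samples=np.asarray(samples, dtype=float),
                        sample_rate=sr, true_label=label)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_repertoire():
    """3 vocal types x 6 calls at 48 kHz — quick end-to-end fixture."""
    return generate_repertoire(n_types=3, calls_per_type=6, separation="easy", seed=11)


@pytest.fixture(scope="session")
def repertoire_calls():
    """The repertoire study condition: 5 vocal types x 20 calls, 48 kHz."""
    return generate_repertoire(n_types=5, calls_per_type=20, separation="easy", seed=42)


@pytest.fixture(scope="session")
def signature_calls():
    """The signature study condition: 4 individuals x {5, 6, 7, 12} cohesion
    calls at 96 kHz, confusable in whole-call summaries by design."""
    return generate_individual_signatures(seed=42)
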