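"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

import phasecode as pc


@pytest.fixture(scope="session")
def entrained_recording() -> pc.Recording:
    """One strongly entrained, strongly modulated unit (6 s, 24 trials)."""
    config = pc.GeneratorConfig(
        duration_ms=6000,
        n_trials=24,
        entrainment_kappa=8.0,
        phase_coupling=0.6,
        rate_mod_depth=0.8,
        noise_amplitude=1.5,
        seed=7,
    )
    return pc.generate_dataset(config)


@pytest.fixture(scope="session")
def theta_phase(entrained_recording) -> pc.PhaseSeries:
    return pc.extract_phase(entrained_recording.lfp, pc.FilterSpec())


def random_ensemble(
    rng: np.random.Generator,
    K: int = 3,
    n_trials: int = 4,
    dim: int = 3,
    max_count: int = 4,
) -> pc.ResponseEnsemble:
    """Small random count ensemble for decoder tests."""
    return pc.ResponseEnsemble(
        [rng.integers(0, max_count + 1, size=(n_trials, dim)) for _ in range(K)]
    )
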