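import numpy as np
import pytest
from hypothesis import settings

from acutono import calibration, pipeline, simulate
from acutono.types import SimulationConfig

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

FS = 10_000.0


@pytest.fixture(scope="session")
def make_pulse():
    """Factory for sampled damped sinusoids A*exp(-lam*t)*sin(2*pi*f*t + phase)."""

    def _make(f=450.0, lam=150.0, amp=1.0, duration=0.04, fs=FS, noise_sd=0.0,
              phase=0.0, seed=0):
        t = np.arange(int(round(duration * fs))) / fs
        x = amp * np.exp(-lam * t) * np.sin(2 * np.pi * f * t + phase)
        if noise_sd > 0:
            x = x + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
        return x

    return _make


def noiseless_config(n_subjects, seed=0, **overrides):
    """Study conditions with every stochastic disturbance switched off."""
    kwargs = dict(
        n_subjects=n_subjects,
        measurements_per_eye=1,
        noise_sd=0.0,
        drift_amplitude=0.0,
        coupling_jitter_damping=0.0,
        coupling_jitter_frequency=0.0,
        failure_probabilities={"no_start": 0.0, "movement": 0.0, "leakage": 0.0,
                               "pressure_deviation": 0.0},
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_noiseless_features():
    """Feature table from a noiseless 80-eye cohort (shared; expensive)."""
    cfg = noiseless_config(n_subjects=40)
    eyes, recs = simulate.simulate_cohort(cfg)
    feats, cats = pipeline.build_feature_table(eyes, recs)
    return feats


@pytest.fixture(scope="session")
def small_noiseless_ensemble(small_noiseless_features):
    """A modest trial ensemble trained on the noiseless cohort (shared)."""
    return calibration.run_trials(
        small_noiseless_features, n_trials=30, keep_fraction=0.2, seed=7
    )
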