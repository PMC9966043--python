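import numpy as np
import pandas as pd
import pytest

from ocutrial import biometry
from ocutrial.simulate import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """One small synthetic trial at the emulated study's size (32/32/33)."""
    return simulate_trial(SimulationConfig(seed=20190501))


@pytest.fixture(scope="session")
def averaged_table(small_trial):
    """Derived, eye-averaged per-participant per-visit table."""
    derived = biometry.derive_table(small_trial.data)
    return biometry.average_eyes_table(derived)


@pytest.fixture(scope="session")
def medium_trial_avg():
    """A larger trial (100/arm, no dropout) for model-fit tests."""
    cfg = SimulationConfig(n_per_arm=(100, 100, 100), seed=11,
                           missing_visit_prob=0.0)
    derived = biometry.derive_table(simulate_trial(cfg).data)
    return biometry.average_eyes_table(derived)


def random_panels(rng, n):
    """Random physically valid biometric panels for property tests."""
    return dict(
        se_d=rng.uniform(-8.0, 1.0, n),
        km_d=rng.uniform(40.0, 47.0, n),
        al_mm=rng.uniform(22.0, 27.0, n),
        acd_mm=rng.uniform(2.6, 4.0, n),
        cct_um=rng.uniform(450.0, 650.0, n),
        lt_mm=rng.uniform(3.0, 4.4, n),
    )
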