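"""Shared fixtures.

The heavier fixtures (converged default simulations, a synthetic
participant and its fit) are session-scoped so the cost is paid once.
"""

import numpy as np
import pandas as pd
import pytest

from hclsleep import (LightProfileSpec, ModelParams, default_coeffs,
                      diary_to_targets, fit_mu_tauc, generate_participant,
                      impute_wake_zeros, simulate_to_convergence)
from hclsleep.calibration import default_profile
from hclsleep.synth import SyntheticParticipantSpec


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def default_sim():
    """Converged default model under the default light profile."""
    return simulate_to_convergence(ModelParams(), default_profile())


@pytest.fixture(scope="session")
def sim_evening10():
    """Converged default model with the 10-lux evening profile."""
    return simulate_to_convergence(ModelParams(),
                                   default_profile(evening_level=10.0))


@pytest.fixture(scope="session")
def participant():
    """Noise-free synthetic participant with known (mu, tauc)."""
    spec = SyntheticParticipantSpec(
        participant_id="p42",
        true_params=ModelParams().replace(mu=18.5, tauc=24.25),
        light_template=LightProfileSpec(evening_level=10.0),
        diary_noise=(0.0, 0.0), n_days=10, seed=42)
    return generate_participant(spec)


@pytest.fixture(scope="session")
def participant_fit(participant):
    """(mu, tauc) fit of the synthetic participant on imputed light."""
    light = impute_wake_zeros(participant.light, participant.wake_mask)
    targets = diary_to_targets(participant.diary)
    return fit_mu_tauc(light, targets, keep_sim=True)


def make_series(lux, start="2024-03-18 00:00", freq="1min",
                participant_id="t", source="synthetic"):
    """Small helper to build a LightSeries from a lux array."""
    from hclsleep import LightSeries
    lux = np.asarray(lux, dtype=float)
    times = pd.date_range(start, periods=len(lux), freq=freq)
    return LightSeries(participant_id, times, lux, source=source)
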