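"""Shared fixtures.

The expensive end-to-end studies (null false-positive control, amplitude
sweep, classifier fixture) are session-scoped so every test that needs
them shares one run.
"""

import numpy as np
import pytest

from seeme.experiments import amplitude_sweep, classifier_experiment, null_study
from seeme.synthetic import (
    InjectedResponse,
    SceneConfig,
    build_schedule,
    simulate_session,
)


@pytest.fixture(scope="session")
def null_results():
    """200 synthetic null trials (20 sessions x 10 commands), default noise."""
    return null_study(n_videos=20, trials_per_video=10, seed=1234)


@pytest.fixture(scope="session")
def sweep_results():
    """Amplitude sweep 0.5/1/2/4 px, 10 trials per amplitude."""
    return amplitude_sweep(seed=99)


@pytest.fixture(scope="session")
def classifier_results():
    """BiLSTM on the separable fixture plus a label-shuffled control."""
    return classifier_experiment(seed=0)


@pytest.fixture(scope="module")
def short_response_session():
    """Small session: 2 trials, one 3-px eye response on trial 1."""
    cfg = SceneConfig(seed=3)
    schedule = build_schedule(n_trials=2, baseline_s=30.0, seed=1)
    responses = [
        InjectedResponse(
            roi_id="eyes", onset_s=schedule[0].onset_s, amplitude_px=3.0
        )
    ]
    return simulate_session(cfg, schedule, responses)
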