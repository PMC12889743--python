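"""Shared fixtures: simulated sessions and population studies.

The heavier simulation studies (50-neuron populations on 10-minute
sessions, the drive-coupled free-viewing session) are session-scoped so the
acceptance tests share one computation.
"""
from __future__ import annotations

import numpy as np
import pytest

from gazephys import studies, synthetic as syn
from gazephys.types import NONE_MODEL, SACCADE_LOCKED, TWO_STAGE


@pytest.fixture(scope="session")
def short_session():
    """A 60 s session for event-level tests."""
    return syn.generate_gaze_trace(syn.GazeConfig(session_length_s=60.0), seed=7)


@pytest.fixture(scope="session")
def two_stage_study():
    """50 two-stage neurons (a_sup=-0.5, a_enh=1.0, w=60/100, l=30/80,
    10 Hz baseline) sharing one 10-minute session."""
    return studies.population_study(
        seed=11, true_model=TWO_STAGE, n_neurons=50, session_length_s=600.0
    )


@pytest.fixture(scope="session")
def saccade_locked_study():
    """50 saccade-locked neurons on a 10-minute session."""
    return studies.population_study(
        seed=21, true_model=SACCADE_LOCKED, n_neurons=50, session_length_s=600.0
    )


@pytest.fixture(scope="session")
def none_study():
    """20 visually-unmodulated (homogeneous Poisson) neurons."""
    return studies.population_study(
        seed=31, true_model=NONE_MODEL, n_neurons=20, session_length_s=600.0
    )


@pytest.fixture(scope="session")
def drive_fixture():
    """30 drive-coupled neurons on a 4-minute free-viewing session; the
    first neuron prefers (90 deg, 1 cycle/deg)."""
    return studies.drive_study(
        seed=61, n_neurons=30, session_length_s=240.0,
        preferred_conditions=[(90.0, 1.0)],
    )


@pytest.fixture(scope="session")
def detection_result():
    """Event + locomotion detection scored against ground truth (10 min)."""
    return studies.event_detection_study(seed=101, session_length_s=600.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
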