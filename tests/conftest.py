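"""Shared fixtures: synthetic cohorts, model cells, conductance templates."""

from __future__ import annotations

import numpy as np
import pytest

import epikit as ek


def make_session(seed: int, duration_s: float = 1200.0, n_seizures: int = 6,
                 **gen_kwargs) -> tuple[ek.EcogRecording, ek.AnnotationSet]:
    """One synthetic telemetry session with randomly placed seizures."""
    rng = np.random.default_rng(seed)
    events = []
    t = 60.0
    for _ in range(n_seizures):
        d = float(rng.uniform(20, 40))
        if t + d > duration_s - 10:
            break
        events.append((t, d))
        t += d + float(rng.uniform(40, 80))
    params = ek.EcogGenParams(
        duration_s=duration_s, seizure_events=events, seed=seed, **gen_kwargs
    )
    return ek.generate_ecog_session(params)


def make_cohort(seeds, **kwargs):
    return [(f"session{sd}", *make_session(sd, **kwargs)) for sd in seeds]


@pytest.fixture(scope="session")
def training_library() -> ek.SeizureLibrary:
    return ek.build_library(make_cohort(range(100, 106)))


@pytest.fixture(scope="session")
def trained_detector(training_library):
    return ek.fit_detector(training_library, seed=0)


@pytest.fixture(scope="session")
def default_cell() -> ek.ModelCellParams:
    return ek.ModelCellParams()


@pytest.fixture(scope="session")
def default_template() -> ek.ConductanceTemplate:
    return ek.generate_conductance_templates(seed=0)


@pytest.fixture(scope="session")
def default_sweeps(default_cell):
    """Noise-free full step protocol on the default cell."""
    return ek.generate_current_clamp_sweeps(
        ek.StepProtocol(n_steps=25), default_cell, noise_rms_mv=0.0
    )
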