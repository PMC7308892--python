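"""Shared fixtures: cohort pipeline runs reused across test modules."""

import logging

import pytest

from pulsox import (
    PipelineConfig,
    ProcessingParams,
    SimulationConfig,
    calibration_recovery_config,
    run_pipeline,
)

logging.disable(logging.INFO)

SESSION_SEED = 1402


def noiseless_config(**overrides) -> SimulationConfig:
    """A fully deterministic, artefact-free, noise-free subject."""
    base = dict(
        spo2_plateaus=[(90.0, 400.0)],
        activity_schedule=[("sitting", 400.0)],
        motion_rate_per_min={},
        sensor_noise_sd=0.0,
        reference_noise_sd=0.0,
        abga_noise_sd=0.0,
        ambient_offset=0.0,
        ambient_drift_amplitude=0.0,
        mains_amplitude=0.0,
        jitter_perfusion_rel=0.0,
        jitter_heart_rate_bpm=0.0,
        jitter_plateau_pct=0.0,
        seed=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def small_pipeline_config(**sim_overrides) -> PipelineConfig:
    """Three-subject, two-plateau cohort for fast pipeline tests."""
    sim = dict(
        spo2_plateaus=[(95.0, 220.0), (88.0, 220.0)],
        activity_schedule=[("sitting", 220.0), ("walking", 220.0)],
        seed=0,
    )
    sim.update(sim_overrides)
    return PipelineConfig(
        simulation=SimulationConfig(**sim), n_subjects=3, seed=5
    )


@pytest.fixture(scope="session")
def params() -> ProcessingParams:
    return ProcessingParams()


@pytest.fixture(scope="session")
def patient_run():
    """Default 15-subject patient cohort, default noise, fixed seed."""
    return run_pipeline(PipelineConfig(n_subjects=15, seed=SESSION_SEED))


@pytest.fixture(scope="session")
def recovery_run():
    """15-subject low-sensor-noise cohort for calibration recovery."""
    return run_pipeline(
        PipelineConfig(
            n_subjects=15,
            seed=SESSION_SEED,
            simulation=calibration_recovery_config(),
        )
    )
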