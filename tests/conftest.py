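"""Shared fixtures: small synthetic cohorts and sweep factories."""

import numpy as np
import pytest
from hypothesis import settings

from cordmap import CohortConfig, SweepRecord, compute_features, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

FS = 6000.0
PRE_S = 0.030
POST_S = 0.100


@pytest.fixture
def make_sweep():
    """Factory: wrap an arbitrary trace (µV) into a SweepRecord."""

    def _make(trace, sampling_rate=FS, stim_onset_time=PRE_S, sweep_id=0, **kw):
        meta = dict(
            sweep_id=sweep_id,
            participant_id="P01",
            muscle="triceps",
            side="left",
            segment="C7",
            position="lateral",
            intensity=4.0,
            pulse_count=3,
            stim_onset_time=stim_onset_time,
            sampling_rate=sampling_rate,
            block="fixed",
        )
        meta.update(kw)
        return SweepRecord(trace=np.asarray(trace, dtype=float), **meta)

    return _make


@pytest.fixture
def zero_trace():
    n = int((PRE_S + POST_S) * FS)
    return np.zeros(n)


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy cohort reused by read-only tests: 3 participants,
    3 segments, 2 arm muscles, stimulated side only."""
    cfg = CohortConfig(
        n_participants=3,
        segments_per_participant=("C6", "C7", "C8"),
        arm_muscles=("biceps", "triceps"),
        leg_muscles=(),
        sides=("left",),
        ramp_intensities=(0.0, 2.0, 4.0, 6.0, 8.0),
        seed=42,
    )
    sweeps, truth = generate_cohort(cfg)
    features = compute_features(sweeps)
    return cfg, sweeps, truth, features


@pytest.fixture(scope="session")
def noiseless_cohort():
    """All noise sources off: AUC must equal the planted softplus values."""
    cfg = CohortConfig(
        n_participants=2,
        segments_per_participant=("C7", "C8"),
        arm_muscles=("biceps", "triceps"),
        leg_muscles=(),
        sides=("left",),
        ramp_intensities=(0.0, 2.0, 4.0, 6.0, 8.0),
        noise_sd=0.0,
        auc_cv=0.0,
        artifact_rate=0.0,
        seed=7,
    )
    sweeps, truth = generate_cohort(cfg)
    features = compute_features(sweeps)
    return cfg, sweeps, truth, features
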