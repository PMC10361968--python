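import numpy as np
import pytest

from v1drift.drift import fit_all_sessions
from v1drift.synthetic_data import (
    DriftSpec,
    ExperimentConfig,
    generate_experiment,
    generate_ground_truth_voxels,
    generate_multi_subject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_experiment(
    n_sessions=6,
    n_voxels=20,
    images_per_session=40,
    n_channels=10,
    noise_sd=0.0,
    drift_spec=None,
    seed=0,
    **kwargs,
):
    """Small single-subject feature-path experiment for unit tests."""
    cfg = ExperimentConfig(
        n_subjects=1,
        n_sessions=n_sessions,
        images_per_session=images_per_session,
        n_voxels=n_voxels,
        n_channels=n_channels,
        seed=seed,
    )
    gt = generate_ground_truth_voxels(n_voxels, n_channels, seed=seed)
    return generate_experiment(
        gt, cfg, drift_spec or DriftSpec(), noise_sd=noise_sd, **kwargs
    )


@pytest.fixture
def clean_experiment():
    """Noiseless, drift-free experiment: the pipeline must invert it exactly."""
    return make_experiment()


@pytest.fixture
def baseline_walk_experiment():
    """Seeded baseline-random-walk experiment with moderate noise."""
    return make_experiment(
        n_sessions=10,
        n_voxels=40,
        images_per_session=60,
        noise_sd=1.0,
        drift_spec=DriftSpec(baseline_walk_sd=0.5, baseline_corr=0.5),
        seed=21,
    )


@pytest.fixture
def fitted(clean_experiment):
    exp = clean_experiment
    fits = fit_all_sessions(exp.designs, exp.panel)
    return exp, fits


__all__ = ["make_experiment", "generate_multi_subject"]
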