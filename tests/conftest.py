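"""Shared fixtures: generator configurations and small synthetic cohorts."""

import dataclasses

import numpy as np
import pytest

from gripstiff import GeneratorConfig, PipelineConfig


@pytest.fixture(scope="session")
def gen_cfg():
    """Default study conditions."""
    return GeneratorConfig()


@pytest.fixture(scope="session")
def quiet_cfg():
    """All noise sources off; EMG carrier deterministic.

    With this configuration every trial is an exact realization of the
    generating law: force plateaus are constant, the post-perturbation
    ringing is absent, markers are exact, and the ARV is exactly
    proportional to the activation envelope.
    """
    return GeneratorConfig(
        tremor_sd=0.0, oscillation_amp=0.0, marker_noise_sd_mm=0.0,
        marker_dropout_prob=0.0, marker_swap_prob=0.0,
        wrist_pose_noise_deg=0.0, wrist_drift_amp_mm=0.0,
        wrist_drift_rot_deg=0.0, emg_gain_cv=(0.0,) * 6, cocon_cv=0.0,
        emg_carrier="sine")


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced protocol for pipeline-level tests (shorter traces, fewer
    repetitions); noise levels stay at the defaults."""
    return GeneratorConfig(pre_s=0.3, post_s=0.1, relax_s=1.0,
                           task1_reps=2, task2_reps=4)


def make_pipeline_config(gen, **kwargs):
    return PipelineConfig(generator=gen, **kwargs)


@pytest.fixture(scope="session")
def cohort_table(fast_cfg):
    """Merged per-trial table of a small analyzed cohort (4 subjects,
    reduced repetitions, default noise): stiffness estimates, normalized
    EMG activations, digit displacements."""
    from gripstiff import generate_dataset
    from gripstiff.pipeline import analyze_dataset

    ds = generate_dataset(4, fast_cfg, seed=314)
    cfg = PipelineConfig(generator=fast_cfg, n_subjects=4)
    res = analyze_dataset(ds, cfg)
    assert not res.failures
    return res.merged


@pytest.fixture(scope="session")
def identical_law_table():
    """Normalized trial table of subjects sharing one exact noiseless
    generating law (deterministic EMG carrier, zero noise everywhere)."""
    from gripstiff import generate_dataset, prepare_subject_table
    from gripstiff.pipeline import analyze_dataset

    gen = GeneratorConfig(
        mvc_force=60.0, k0=0.4, slope=0.06, index_share=0.7,
        tremor_sd=0.0, oscillation_amp=0.0, emg_gain_cv=(0.0,) * 6,
        cocon_cv=0.0, emg_carrier="sine", marker_noise_sd_mm=0.0,
        marker_dropout_prob=0.0, marker_swap_prob=0.0,
        wrist_pose_noise_deg=0.0, wrist_drift_amp_mm=0.0,
        wrist_drift_rot_deg=0.0,
        pre_s=0.3, post_s=0.1, relax_s=1.0, task1_reps=2, task2_reps=3)
    ds = generate_dataset(4, gen, seed=99)
    res = analyze_dataset(ds, PipelineConfig(generator=gen),
                          channels=("force", "emg"))
    assert not res.failures
    return prepare_subject_table(res.merged)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def replace():
    return dataclasses.replace
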