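import numpy as np
import pytest

from cuffless_bp import synthetic as syn


def make_params(
    subject_id="S001",
    sbp0=120.0,
    dbp0=80.0,
    hr0=60.0,
    amp=(20.0, 10.0, 10.0),
    noise_sd=0.0,
    hr_noise_sd=0.0,
    seed=0,
):
    return syn.SubjectParams(
        subject_id, sbp0, dbp0, hr0,
        {a: amp for a in syn.ACTIVITIES},
        noise_sd=noise_sd, hr_noise_sd=hr_noise_sd, seed=seed,
    )


@pytest.fixture(scope="session")
def rest_only_protocol():
    """A single session with no stimulus response (amplitudes set to zero
    by the caller's params)."""
    return syn.ProtocolSpec(
        sessions=(syn.SessionSpec("handgrip", 120.0, rest_s=240.0),)
    )


@pytest.fixture(scope="session")
def clean_truth():
    """Zero-noise single-session truth series with a handgrip response."""
    params = make_params()
    spec = syn.SessionSpec("handgrip", 120.0, rest_s=240.0)
    rng = np.random.default_rng(0)
    return syn.simulate_session_trajectory(params, spec, rng)


@pytest.fixture(scope="session")
def clean_waveform(clean_truth):
    return syn.simulate_waveform(clean_truth, 125.0)


@pytest.fixture(scope="session")
def default_cohort_small():
    """A 6-subject cohort at study-default noise levels."""
    return syn.simulate_cohort(n_subjects=6, seed=11)
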