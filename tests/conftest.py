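import numpy as np
import pytest

from kneegait import pipeline as pl
from kneegait import synthetic as syn


@pytest.fixture(scope="session")
def small_koa_cohort():
    """Noise-free 3-participant KOA cohort (shared across tests)."""
    spec = syn.koa_cohort_spec(n=3, seed=11, marker_noise_mm=0.0)
    return syn.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_control_cohort():
    spec = syn.control_cohort_spec(n=3, seed=12, marker_noise_mm=0.0)
    return syn.generate_cohort(spec)


@pytest.fixture(scope="session")
def one_trial(small_koa_cohort):
    """(draw, markers, angles, truth) for one noise-free trial."""
    d = small_koa_cohort.participants[0]
    mk, ang, truth = small_koa_cohort.trials[d.pid][0]
    return d, mk, ang, truth


@pytest.fixture(scope="session")
def one_trial_result(one_trial):
    d, mk, ang, truth = one_trial
    return pl.run_trial(mk, ang, pl.RunConfig(), participant=d.pid, trial="T01")


def match_errors_frames(detected, truth, frame_rate):
    """Per-truth-event distance (in frames) to the nearest detection."""
    out = []
    for t in truth:
        out.append(
            np.min(np.abs(np.asarray(detected) - t)) * frame_rate if len(detected) else np.inf
        )
    return np.asarray(out)
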