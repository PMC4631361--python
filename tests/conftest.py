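import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from depthmvpa.design import assign_timing, generate_balanced_sequence, make_conditions
from depthmvpa.psychometrics import PsychometricFunction
from depthmvpa.synthetic_data import RoiSimConfig, psychometric_coupling, simulate_experiment

settings.register_profile(
    "suite", max_examples=25, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

LEVELS = (0, 20, 40, 60, 100)


@pytest.fixture(scope="session")
def observer():
    # accuracy Phi(beta * s / sqrt(2)) with beta = 0.022711 per % signal
    return PsychometricFunction(mu=0.0, sigma=np.sqrt(2) / 0.022711, guess=0.0, lapse=0.0)


@pytest.fixture(scope="session")
def small_dataset(observer):
    """3 runs x 40 voxels of a psychometrically coupled ROI + event tables."""
    cfg = RoiSimConfig(
        n_voxels=40,
        amplitude_max=0.6,
        activation=1.0,
        noise_sd=1.0,
        coupling=psychometric_coupling(observer, max(LEVELS)),
        roi_name="roi",
    )
    runs_by_roi, events = simulate_experiment(cfg, observer, n_runs=3, seed=11, levels=LEVELS)
    return runs_by_roi["roi"], events


@pytest.fixture(scope="session")
def noiseless_dataset(observer):
    """Noise/drift-free coupled ROI: patterns are exactly separable."""
    cfg = RoiSimConfig(
        n_voxels=12,
        amplitude_max=1.0,
        activation=1.0,
        noise_sd=0.0,
        coupling=psychometric_coupling(observer, max(LEVELS)),
        roi_name="roi",
    )
    runs_by_roi, events = simulate_experiment(cfg, observer, n_runs=2, seed=7, levels=LEVELS)
    return runs_by_roi["roi"], events


@pytest.fixture()
def one_trial_events():
    """Single near trial at onset 9 s inside 9 s fixation bookends."""
    from depthmvpa.design import TrialSequence

    seq = TrialSequence(conditions=["near:100"], dummy_first=False, run_id=0)
    return assign_timing(seq, seed=0)


def balanced_events(n_runs=2, levels=LEVELS, reps=11, seed=0):
    out = []
    for r in range(n_runs):
        seq = generate_balanced_sequence(make_conditions(levels), reps, seed=seed + r, run_id=r)
        out.append(assign_timing(seq, seed=seed + r))
    return out
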