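"""Shared fixtures: the expensive simulations are run once per session.

The big full-model run doubles as the calibration acceptance check and
the substrate for the behavioural property tests, so its size (2,000
trials per interval) and seed are fixed here and nowhere else.
"""

import numpy as np
import pytest

import tempocat as tc

BIG_N = 2000
BIG_SEED = 101
REDUCED_SEED = 202
DELAY_SEED = 303


@pytest.fixture(scope="session")
def default_params():
    return tc.AttractorParams()


@pytest.fixture(scope="session")
def big_full(default_params):
    """Full model, 2,000 trials/interval, all four angles."""
    return tc.simulate_experiment(default_params, BIG_N, BIG_SEED)


@pytest.fixture(scope="session")
def big_reduced(default_params):
    """Ablated (no-memory, no-reading-area) model at the same scale."""
    return tc.simulate_reduced(default_params, BIG_N, REDUCED_SEED)


@pytest.fixture(scope="session")
def delay_predictions(default_params):
    """Generalization sweep over delays 0 / 1000 / 3000 ms."""
    return tc.predict_generalization(default_params, n_per_interval=1000,
                                     seed=DELAY_SEED)


def _recovery_benchmark(noise_sd: float, n: int = 200):
    """End-to-end kinematic recovery on a mixed synthetic population.

    Returns (binary submovement accuracy, decision-change accuracy,
    fraction of plain trials with measured RT within one 10 ms sample of
    the analytic expectation, number of plain trials).
    """
    rng = np.random.default_rng(99)
    sub_ok = chg_ok = rt_ok = n_plain = 0
    for i in range(n):
        ang = [45, 90, 135, 180][i % 4]
        n_sub = int(rng.integers(0, 3))
        chg = bool(rng.random() < 0.3)
        spec = tc.SynthTrialSpec(
            rt_true=float(rng.uniform(250, 450)),
            mt_true=float(rng.uniform(450, 800)),
            target_angle_deg=float(rng.uniform(0, 360)),
            inter_target_angle_deg=ang, n_submovements_true=n_sub,
            decision_change_true=chg, noise_sd=noise_sd, seed=10_000 + i)
        traj, truth = tc.synth_trajectory(spec)
        m = tc.analyze_trajectory(traj)
        sub_ok += (m.n_submovements > 0) == (truth["n_submovements_true"] > 0)
        chg_ok += m.decision_change == truth["decision_change_true"]
        if np.isfinite(truth["expected_rt_measured"]):
            n_plain += 1
            rt_ok += abs(m.rt_ms - truth["expected_rt_measured"]) <= 10.0 + 1e-9
    return sub_ok / n, chg_ok / n, rt_ok / max(n_plain, 1), n_plain


@pytest.fixture(scope="session")
def recovery_low_noise():
    """Recovery rates at low measurement noise (position SD 0.005 units)."""
    return _recovery_benchmark(0.005)
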