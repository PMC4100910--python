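"""Network primitives: sigmoid, fixed points, integration and readout."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import tempocat as tc
from tempocat.attractor import (_pair_fixed_point, initial_state, run_phase,
                                step_state)
from tempocat.attractor import NetworkState


# ---------------------------------------------------------------- sigmoid

def test_sigmoid_midpoint_and_limits():
    assert tc.sigmoid_output(0.0) == pytest.approx(5.0)
    assert tc.sigmoid_output(50.0) == pytest.approx(10.0)
    assert tc.sigmoid_output(-50.0) == pytest.approx(0.0, abs=1e-12)


def test_sigmoid_point_symmetry_and_monotonicity():
    x = np.linspace(-8, 8, 101)
    f = tc.sigmoid_output(x, M=10.0, beta=1.0)
    assert np.allclose(f + tc.sigmoid_output(-x), 10.0)
    assert np.all(np.diff(f) > 0)


def test_sigmoid_ceiling_and_slope_params():
    assert tc.sigmoid_output(0.0, M=4.0) == pytest.approx(2.0)
    # larger beta = steeper at the midpoint
    eps = 1e-4
    slope1 = (tc.sigmoid_output(eps) - tc.sigmoid_output(-eps)) / (2 * eps)
    slope3 = (tc.sigmoid_output(eps, beta=3.0)
              - tc.sigmoid_output(-eps, beta=3.0)) / (2 * eps)
    assert slope3 == pytest.approx(3.0 * slope1, rel=1e-6)


# ---------------------------------------------------------- parameters

def test_params_validation():
    with pytest.raises(ValueError):
        tc.AttractorParams(tau=0.0)
    with pytest.raises(ValueError):
        tc.AttractorParams(noise_sd=-0.1)
    with pytest.raises(ValueError):
        tc.AttractorParams(rt_thresholds={45: 0.5, 90: 0.6, 135: 0.56,
                                          180: 0.54})
    with pytest.raises(ValueError):
        tc.AttractorParams(move_threshold=0.6)


def test_stimulus_asymmetry_roundtrip(default_params):
    a_acc, a_mem = default_params.stimulus_asymmetry()
    assert a_acc > 0 and a_mem > a_acc     # memory pair needs a larger push
    p2 = default_params.with_stimulus_asymmetry(1.5, 2.5)
    assert p2.stimulus_asymmetry() == pytest.approx((1.5, 2.5))
    # baseline (mean) drive preserved
    el, es, *_ = p2.phase_inputs["stimulus"]
    el0, es0, *_ = default_params.phase_inputs["stimulus"]
    assert (el + es) / 2 == pytest.approx((el0 + es0) / 2)


# ------------------------------------------------------------ fixed points

def test_pair_fixed_point_solves_equations(default_params):
    el, es, *_ = default_params.phase_inputs["stimulus"]
    a, b = _pair_fixed_point(el, es, default_params)
    assert a == pytest.approx(float(tc.sigmoid_output(el - b)), abs=1e-8)
    assert b == pytest.approx(float(tc.sigmoid_output(es - a)), abs=1e-8)
    assert a > b                     # the driven unit wins


def test_initial_state_is_mirror_of_stimulus_attractor(default_params):
    el, es, eml, ems = default_params.phase_inputs["stimulus"]
    hi, lo = _pair_fixed_point(el, es, default_params)
    st = initial_state(default_params)
    assert float(st.L) == pytest.approx(lo)
    assert float(st.S) == pytest.approx(hi)
    hi_m, lo_m = _pair_fixed_point(eml, ems, default_params)
    assert float(st.M_L) == pytest.approx(lo_m)
    assert float(st.M_S) == pytest.approx(hi_m)


def test_fixed_point_is_stationary_under_euler(default_params):
    p = default_params.replace(noise_sd=0.0)
    el, es, eml, ems = p.phase_inputs["stimulus"]
    a, b = _pair_fixed_point(el, es, p)
    am, bm = _pair_fixed_point(eml, ems, p)
    st = NetworkState(L=np.float64(a), S=np.float64(b),
                      M_L=np.float64(am), M_S=np.float64(bm))
    st2 = step_state(st, p, "stimulus")
    assert float(st2.L) == pytest.approx(a, abs=1e-9)
    assert float(st2.S) == pytest.approx(b, abs=1e-9)


# ------------------------------------------------------------- integration

def test_step_state_rejects_unknown_phase_and_blowup(default_params):
    st = initial_state(default_params)
    with pytest.raises(ValueError):
        step_state(st, default_params, "bogus")
    bad = st.copy()
    bad.L = np.float64(np.inf)
    with pytest.raises(tc.NumericalBlowupError):
        step_state(bad, default_params, "stimulus")


def test_activities_stay_bounded(default_params):
    p = default_params.replace(noise_sd=0.5)       # exaggerated noise
    rng = np.random.default_rng(0)
    st = initial_state(p, n=50)
    st, _ = run_phase(st, p, "stimulus", 300.0, rng)
    for arr in (st.L, st.S, st.M_L, st.M_S):
        assert np.all(arr >= 0.0) and np.all(arr <= p.M)


def test_run_phase_records_trace(default_params):
    p = default_params.replace(noise_sd=0.0)
    st = initial_state(p)
    st2, trace = run_phase(st, p, "stimulus", 50.0, record=True)
    assert set(trace) == {"L", "S", "M_L", "M_S"}
    assert trace["L"].shape == (51,)
    assert trace["L"][-1] == pytest.approx(float(st2.L))
    with pytest.raises(ValueError):
        run_phase(st, p, "stimulus", -1.0)


def test_euler_matches_ode_oracle(default_params):
    """dt = 1 ms Euler vs an adaptive ODE solver, zero noise, 500 ms."""
    p = default_params.replace(noise_sd=0.0)
    el, es, eml, ems = p.phase_inputs["stimulus"]
    st = initial_state(p)
    y0 = [float(st.L), float(st.S), float(st.M_L), float(st.M_S)]
    f = tc.sigmoid_output

    def rhs(t, y):
        L, S, ML, MS = y
        return [(-L + f(el - S)) / p.tau, (-S + f(es - L)) / p.tau,
                (-ML + f(eml - MS)) / p.tau_mem,
                (-MS + f(ems - ML)) / p.tau_mem]

    ref = solve_ivp(rhs, (0, 500), y0, rtol=1e-10, atol=1e-12).y[:, -1]
    st2, _ = run_phase(st, p, "stimulus", 500.0)
    eul = np.array([float(st2.L), float(st2.S), float(st2.M_L), float(st2.M_S)])
    assert np.linalg.norm(eul - ref) / np.linalg.norm(ref) <= 1e-3


def test_delay_leak_decays_toward_symmetry(default_params):
    """Both pairs converge to symmetric states during the delay; the
    memory pair (tau 500 ms) decays more slowly than accumulation."""
    p = default_params.replace(noise_sd=0.0)
    st = initial_state(p)
    st, _ = run_phase(st, p, "stimulus", 900.0)      # asymmetric start
    gap_acc0 = abs(float(st.L) - float(st.S))
    gap_mem0 = abs(float(st.M_L) - float(st.M_S))
    st, _ = run_phase(st, p, "delay", 1000.0)
    gap_acc1 = abs(float(st.L) - float(st.S))
    gap_mem1 = abs(float(st.M_L) - float(st.M_S))
    assert gap_acc1 < gap_acc0 and gap_mem1 < gap_mem0
    assert gap_mem1 / max(gap_mem0, 1e-12) > gap_acc1 / max(gap_acc0, 1e-12)
    # long-delay limit: the leak is deliberately near-critical, so full
    # forgetting is slow, but the decay continues monotonically
    st, _ = run_phase(st, p, "delay", 20000.0)
    assert abs(float(st.L) - float(st.S)) < min(1e-4, gap_acc1)
    assert abs(float(st.M_L) - float(st.M_S)) < gap_mem1


def test_mirror_symmetry(default_params):
    """Swapping the drives mirrors the zero-noise trajectory L <-> S."""
    p = default_params.replace(noise_sd=0.0)
    el, es, eml, ems = p.phase_inputs["stimulus"]
    inputs = dict(p.phase_inputs)
    inputs["stimulus"] = (es, el, ems, eml)
    p_sw = p.replace(phase_inputs=inputs)
    st, _ = run_phase(initial_state(p), p, "stimulus", 400.0)
    # the swapped network starts from the mirror of the swapped FP, which
    # is the original initial state with L/S (and M_L/M_S) exchanged
    st0 = initial_state(p)
    st0_m = NetworkState(L=st0.S, S=st0.L, M_L=st0.M_S, M_S=st0.M_L)
    st_sw, _ = run_phase(st0_m, p_sw, "stimulus", 400.0)
    assert float(st_sw.L) == pytest.approx(float(st.S), abs=1e-12)
    assert float(st_sw.S) == pytest.approx(float(st.L), abs=1e-12)


# ----------------------------------------------------------------- readout

def test_dra_trace_range_and_shape():
    node = np.linspace(0, 10, 11)
    mem = np.linspace(10, 0, 11)
    d = tc.dra_trace(node, mem)
    assert np.allclose(d, 0.5)
    assert np.all((d >= 0) & (d <= 1))
    with pytest.raises(ValueError):
        tc.dra_trace(node, mem[:-1])


def test_read_rt_mt_exponential_closed_form(default_params):
    """An analytic exponential approach to the attractor has known
    threshold-crossing times: dist(t) = exp(-t/tau_r)."""
    tau_r = 400.0
    t = np.arange(0, 3001.0)
    attr = 0.9
    d0 = 0.1
    dra_L = attr - (attr - d0) * np.exp(-t / tau_r)
    dra_S = np.full_like(t, 0.05)
    r = tc.read_rt_mt(dra_L, dra_S, 90, default_params,
                      attractor_L=attr, attractor_S=0.0)
    thr = default_params.rt_thresholds[90]
    expect_rt = np.ceil(tau_r * np.log(1.0 / thr))
    expect_end = np.ceil(tau_r * np.log(1.0 / default_params.move_threshold))
    assert r["choice"] == "long"
    assert r["rt_ms"] == pytest.approx(expect_rt, abs=1.0)
    assert r["mt_ms"] == pytest.approx(expect_end - expect_rt, abs=2.0)


def test_read_rt_mt_threshold_ordering(default_params):
    """Lower thresholds (larger angles) are crossed later on one trace."""
    t = np.arange(0, 3001.0)
    dra_L = 1.0 - np.exp(-t / 500.0)
    dra_S = np.zeros_like(t)
    rts = [tc.read_rt_mt(dra_L, dra_S, a, default_params,
                         attractor_L=1.0, attractor_S=0.0)["rt_ms"]
           for a in (45, 90, 135, 180)]
    assert rts == sorted(rts)
    assert rts[0] < rts[-1]


def test_read_rt_mt_timeout_and_tie(default_params):
    t = np.arange(0, 501.0)
    flat = np.full_like(t, 0.3)
    r = tc.read_rt_mt(flat, flat, 90, default_params)
    assert r["choice"] == "none"
    assert np.isnan(r["rt_ms"])
    slow = 0.3 + 0.0001 * t / t[-1]          # never near the attractor
    r2 = tc.read_rt_mt(slow, np.zeros_like(t), 90, default_params,
                       attractor_L=1.0, attractor_S=0.0)
    assert r2["choice"] == "none"


def test_read_rt_mt_unknown_angle(default_params):
    t = np.arange(0, 100.0)
    with pytest.raises(KeyError):
        tc.read_rt_mt(t / 99, np.zeros_like(t), 60, default_params)


def test_read_rt_mt_affine_map(default_params):
    p = default_params.replace(rt_offset_ms=100.0, rt_gain=2.0,
                               mt_offset_ms=50.0, mt_gain=0.5)
    t = np.arange(0, 3001.0)
    dra_L = 1.0 - np.exp(-t / 400.0)
    dra_S = np.zeros_like(t)
    base = tc.read_rt_mt(dra_L, dra_S, 90, default_params,
                         attractor_L=1.0, attractor_S=0.0)
    mapped = tc.read_rt_mt(dra_L, dra_S, 90, p,
                           attractor_L=1.0, attractor_S=0.0)
    assert mapped["rt_ms"] == pytest.approx(100.0 + 2.0 * base["rt_ms"])
    assert mapped["mt_ms"] == pytest.approx(50.0 + 0.5 * base["mt_ms"])


def test_read_rt_mt_2d_matches_1d(default_params):
    t = np.arange(0, 3001.0)
    a = 1.0 - np.exp(-t / 300.0)
    b = 1.0 - np.exp(-t / 600.0)
    two = tc.read_rt_mt(np.column_stack([a, b]), np.zeros((len(t), 2)), 90,
                        default_params, attractor_L=1.0, attractor_S=0.0)
    one = tc.read_rt_mt(b, np.zeros_like(t), 90, default_params,
                        attractor_L=1.0, attractor_S=0.0)
    assert two["rt_ms"][1] == pytest.approx(one["rt_ms"])
    assert two["choice"][1] == one["choice"]


# -------------------------------------------------------------- trial level

def test_simulate_trial_determinism(default_params):
    a = tc.simulate_trial(709.0, 90, default_params, seed=5)
    b = tc.simulate_trial(709.0, 90, default_params, seed=5)
    c = tc.simulate_trial(709.0, 90, default_params, seed=6)
    assert (a.choice, a.rt_ms, a.mt_ms) == (b.choice, b.rt_ms, b.mt_ms)
    assert (a.choice, a.rt_ms) != (c.choice, c.rt_ms) or a.mt_ms != c.mt_ms


def test_simulate_trial_traces_and_validation(default_params):
    r = tc.simulate_trial(500.0, 90, default_params, seed=1,
                          record_traces=True)
    assert set(r.traces) >= {"stimulus", "delay", "response_dra_L"}
    assert r.traces["stimulus"]["L"].shape == (501,)
    assert len(r.traces["response_dra_L"]) == 3001
    with pytest.raises(ValueError):
        tc.simulate_trial(0.0, 90, default_params, seed=1)


def test_zero_noise_extremes_are_correct(default_params):
    p = default_params.replace(noise_sd=0.0)
    short = tc.simulate_trial(450.0, 90, p, seed=0)
    long_ = tc.simulate_trial(920.0, 90, p, seed=0)
    assert short.choice == "short" and short.correct
    assert long_.choice == "long" and long_.correct


def test_zero_noise_diagonal_crossing_separates_choices(default_params):
    """Zero-noise choice flips across the deterministic diagonal crossing."""
    p = default_params.replace(noise_sd=0.0)
    cross = tc.diagonal_crossing_time(p)
    assert 600.0 < cross < 800.0
    below = tc.simulate_trial(cross - 15.0, 90, p, seed=0)
    above = tc.simulate_trial(cross + 15.0, 90, p, seed=0)
    assert below.choice == "short"
    assert above.choice == "long"
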