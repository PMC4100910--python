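"""Mutual-inhibition attractor network for temporal categorization.

Two node pairs, each a winner-take-all circuit of rate units:

* an accumulation pair (L, S) with time constant ``tau`` that represents
  elapsed time, the delay-period trace and the categorical competition, and
* a memory pair (M_L, M_S) with the slower ``tau_mem`` that holds a
  parametric trace of the interval across the delay.

Each unit follows  ``tau * dx/dt = -x + f(E_x - w * x_opp) + noise``  with
``f`` a sigmoid saturating at ``M``.  Only the excitatory drives ``E``
change between task phases; the connectivity never does.

A trial walks through three phases.  During the *stimulus* phase the drives
are asymmetric (E_L > E_S) and the network, started in the mirror image of
the stimulus-phase fixed point (the short-category prototype state), drifts
slowly through the saddle-node bottleneck towards the long-category state;
the moment its trajectory crosses the L = S diagonal is the implicit
category boundary, and the calibration places that crossing at the
configured boundary (687.5 ms by default).  During the *delay* both pairs
receive weak symmetric drive and leak towards a common symmetric state, the
memory pair much more slowly -- a correlate of forgetting.  At *response*
onset the accumulation pair is driven into a strongly bistable regime and
falls into the attractor on its side of the diagonal, which is the choice.

Two downstream reading areas average each category's accumulation and
memory activity.  Reaction time is the moment the winning reading area has
covered enough of its remaining distance to the attractor -- a fraction set
per target-separation angle -- and movement time ends when that distance
falls below a final threshold close to the attractor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .task_design import CATEGORY_BOUNDARY_MS, DEFAULT_INTERVALS

PHASES = ("stimulus", "delay", "response")

#: Movement-onset thresholds per target-separation angle (fraction of the
#: reading area's normalized distance to its attractor) and the final
#: movement-end threshold.
DEFAULT_RT_THRESHOLDS = {45: 0.61, 90: 0.59, 135: 0.56, 180: 0.54}
DEFAULT_MOVE_THRESHOLD = 0.04

# Shipped calibration (see AttractorParams docstring): baseline drive and
# stimulus-phase asymmetries for the accumulation and memory pairs, frozen
# from calibrate(n_refine=2000, seed=11) at the default noise level.
_E0_STIM = 3.0
_A_LS = 1.8899602712264219
_A_MEM = 3.2408094001425285
_E_DELAY = -1.2
_E_RESPONSE = 5.0


class NumericalBlowupError(RuntimeError):
    """Raised when a network state stops being finite."""


class CalibrationError(RuntimeError):
    """Raised when calibration cannot satisfy its ordering constraints."""


def sigmoid_output(x, M: float = 10.0, beta: float = 1.0):
    """Sigmoid rate function: 0 at -inf, ``M`` at +inf, ``M/2`` at x = 0.

    Point-symmetric about the midpoint: f(x) + f(-x) = M.
    """
    return M / (1.0 + np.exp(-beta * np.asarray(x, dtype=float)))


@dataclass
class AttractorParams:
    """All constants of the network and its readout.

    The drives ``phase_inputs`` and the noise level are calibrated
    constants (the shipped defaults place the simulated point of
    subjective equality at ``boundary_ms``); the time constants, the
    sigmoid ceiling and the readout thresholds are fixed design values.

    Parameters
    ----------
    tau, tau_mem : float
        Accumulation / memory time constants, ms.
    M, beta : float
        Sigmoid ceiling and slope.
    w_inh : float
        Mutual-inhibition weight within each pair.
    noise_sd : float
        SD of the additive white noise per unit (Euler-Maruyama, scaled
        by sqrt(dt)).
    dt : float
        Integration step, ms.
    phase_inputs : dict
        phase -> (E_L, E_S, E_ML, E_MS).  During the response phase the
        memory pair keeps its delay-phase drive (maintenance).
    rt_thresholds, move_threshold
        Readout thresholds on the winner's normalized distance to its
        attractor, per angle / for movement end.
    delay_ms, max_response_ms : float
        Default delay duration and cap on the simulated response phase.
    boundary_ms : float
        Category boundary the calibration targets.
    rt_offset_ms, rt_gain, mt_offset_ms, mt_gain : float
        Affine map from simulated to behavioural ms (identity by default).
    """

    tau: float = 155.0
    tau_mem: float = 500.0
    M: float = 10.0
    beta: float = 1.0
    w_inh: float = 1.0
    noise_sd: float = 0.015
    dt: float = 1.0
    phase_inputs: dict = field(
        default_factory=lambda: {
            "stimulus": (_E0_STIM + _A_LS, _E0_STIM - _A_LS,
                         _E0_STIM + _A_MEM, _E0_STIM - _A_MEM),
            "delay": (_E_DELAY, _E_DELAY, _E_DELAY, _E_DELAY),
            "response": (_E_RESPONSE, _E_RESPONSE, _E_DELAY, _E_DELAY),
        }
    )
    rt_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_RT_THRESHOLDS))
    move_threshold: float = DEFAULT_MOVE_THRESHOLD
    delay_ms: float = 1000.0
    max_response_ms: float = 3000.0
    boundary_ms: float = CATEGORY_BOUNDARY_MS
    rt_offset_ms: float = 0.0
    rt_gain: float = 1.0
    mt_offset_ms: float = 0.0
    mt_gain: float = 1.0

    def __post_init__(self) -> None:
        # normalise container types so that equal parameter sets hash
        # identically regardless of provenance (constructor vs YAML)
        self.rt_thresholds = {float(k): float(v)
                              for k, v in self.rt_thresholds.items()}
        self.phase_inputs = {k: tuple(float(x) for x in v)
                             for k, v in self.phase_inputs.items()}
        self.validate()

    def validate(self) -> None:
        for name in ("tau", "tau_mem", "M", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        angles = sorted(self.rt_thresholds)
        thr = [self.rt_thresholds[a] for a in angles]
        if any(b >= a for a, b in zip(thr, thr[1:])):
            raise ValueError("rt_thresholds must be strictly decreasing in angle")
        if self.move_threshold >= min(thr):
            raise ValueError("move_threshold must be below every rt threshold")
        for phase in PHASES:
            if phase not in self.phase_inputs:
                raise ValueError(f"phase_inputs missing phase {phase!r}")

    def replace(self, **kw) -> "AttractorParams":
        return dataclasses.replace(self, **kw)

    def stimulus_asymmetry(self) -> tuple[float, float]:
        """(accumulation, memory) half-difference of the stimulus drives."""
        el, es, eml, ems = self.phase_inputs["stimulus"]
        return (el - es) / 2.0, (eml - ems) / 2.0

    def with_stimulus_asymmetry(self, a_acc: float, a_mem: float | None = None
                                ) -> "AttractorParams":
        el, es, eml, ems = self.phase_inputs["stimulus"]
        e0_acc = (el + es) / 2.0
        e0_mem = (eml + ems) / 2.0
        if a_mem is None:
            a_mem = (eml - ems) / 2.0
        inputs = dict(self.phase_inputs)
        inputs["stimulus"] = (e0_acc + a_acc, e0_acc - a_acc,
                              e0_mem + a_mem, e0_mem - a_mem)
        return self.replace(phase_inputs=inputs)


@dataclass
class NetworkState:
    """Activities of the four units (scalars or aligned arrays)."""

    L: np.ndarray
    S: np.ndarray
    M_L: np.ndarray
    M_S: np.ndarray
    t: float = 0.0
    phase: str = "stimulus"

    def copy(self) -> "NetworkState":
        return NetworkState(
            np.array(self.L, dtype=float, copy=True),
            np.array(self.S, dtype=float, copy=True),
            np.array(self.M_L, dtype=float, copy=True),
            np.array(self.M_S, dtype=float, copy=True),
            self.t, self.phase,
        )


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    interval_ms: float
    angle_deg: float
    choice: str               # 'short' | 'long' | 'none'
    correct: bool
    rt_ms: float
    mt_ms: float
    traces: dict | None = None


def _pair_fixed_point(e_self: float, e_opp: float, params: AttractorParams
                      ) -> tuple[float, float]:
    """Fixed point of one mutually inhibiting pair under drives (e_self, e_opp)."""
    M, beta, w = params.M, params.beta, params.w_inh

    def eqs(v):
        a, b = v
        return [a - float(sigmoid_output(e_self - w * b, M, beta)),
                b - float(sigmoid_output(e_opp - w * a, M, beta))]

    # seed on the side favoured by the larger drive
    x0 = (0.9 * M, 0.1 * M) if e_self >= e_opp else (0.1 * M, 0.9 * M)
    sol = fsolve(eqs, x0, full_output=False)
    return float(sol[0]), float(sol[1])


def initial_state(params: AttractorParams, n: int | None = None) -> NetworkState:
    """Network state at trial start: mirror image of the stimulus attractor.

    Training installs the short prototype as the default state, so each
    trial begins with the short-preferring units at the level the
    long-preferring units would reach after full accumulation.
    """
    el, es, eml, ems = params.phase_inputs["stimulus"]
    Ls, Ss = _pair_fixed_point(el, es, params)
    Lm, Sm = _pair_fixed_point(eml, ems, params)
    shape = () if n is None else (n,)
    return NetworkState(
        L=np.full(shape, Ss), S=np.full(shape, Ls),
        M_L=np.full(shape, Sm), M_S=np.full(shape, Lm),
        t=0.0, phase="stimulus",
    )


def step_state(state: NetworkState, params: AttractorParams, phase: str,
               rng: np.random.Generator | None = None) -> NetworkState:
    """One Euler-Maruyama step of both pairs under the given phase's drives.

    The accumulation and memory pairs are not cross-coupled; each unit
    relaxes towards the sigmoid of (its drive minus the inhibition from
    its partner), with its pair's time constant.  Activities are kept in
    [0, M].
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if not (np.all(np.isfinite(state.L)) and np.all(np.isfinite(state.S))
            and np.all(np.isfinite(state.M_L)) and np.all(np.isfinite(state.M_S))):
        raise NumericalBlowupError("non-finite network state")
    p = params
    el, es, eml, ems = p.phase_inputs[phase]
    f = sigmoid_output
    dt, w, M, beta = p.dt, p.w_inh, p.M, p.beta

    def noise(shape):
        if rng is None or p.noise_sd == 0:
            return 0.0
        return rng.standard_normal(shape) * p.noise_sd * np.sqrt(dt)

    shape = np.shape(state.L)
    L = state.L + dt / p.tau * (-state.L + f(el - w * state.S, M, beta)) + noise(shape)
    S = state.S + dt / p.tau * (-state.S + f(es - w * state.L, M, beta)) + noise(shape)
    ML = state.M_L + dt / p.tau_mem * (-state.M_L + f(eml - w * state.M_S, M, beta)) + noise(shape)
    MS = state.M_S + dt / p.tau_mem * (-state.M_S + f(ems - w * state.M_L, M, beta)) + noise(shape)
    return NetworkState(
        L=np.clip(L, 0, M), S=np.clip(S, 0, M),
        M_L=np.clip(ML, 0, M), M_S=np.clip(MS, 0, M),
        t=state.t + dt, phase=phase,
    )


def run_phase(state: NetworkState, params: AttractorParams, phase: str,
              duration_ms: float, rng: np.random.Generator | None = None,
              record: bool = False):
    """Integrate one task phase for ``duration_ms``.

    Returns ``(state, trace)``; ``trace`` is a dict of (steps+1, ...)
    arrays for L, S, M_L, M_S when ``record`` is true, else None.
    """
    if duration_ms < 0:
        raise ValueError("duration_ms must be >= 0")
    n_steps = int(round(duration_ms / params.dt))
    trace = None
    if record:
        trace = {k: [np.array(getattr(state, a), dtype=float, copy=True)]
                 for k, a in (("L", "L"), ("S", "S"), ("M_L", "M_L"), ("M_S", "M_S"))}
    for _ in range(n_steps):
        state = step_state(state, params, phase, rng)
        if record:
            for k, a in (("L", "L"), ("S", "S"), ("M_L", "M_L"), ("M_S", "M_S")):
                trace[k].append(np.array(getattr(state, a), copy=True))
    if record:
        trace = {k: np.stack(v) for k, v in trace.items()}
    return state, trace


def dra_trace(node_trace: np.ndarray, memory_trace: np.ndarray,
              M: float = 10.0) -> np.ndarray:
    """Downstream reading area: mean of a node and its memory partner, in [0, 1]."""
    node_trace = np.asarray(node_trace, dtype=float)
    memory_trace = np.asarray(memory_trace, dtype=float)
    if node_trace.shape != memory_trace.shape:
        raise ValueError("node and memory traces must have the same shape")
    return (node_trace + memory_trace) / (2.0 * M)


def read_rt_mt(dra_L: np.ndarray, dra_S: np.ndarray, angle: float,
               params: AttractorParams,
               attractor_L: float | np.ndarray | None = None,
               attractor_S: float | np.ndarray | None = None) -> dict:
    """Choice, RT and MT from a pair of response-phase reading-area traces.

    The winner is the reading area that leads at the end of the response
    window.  Its distance to its attractor value, normalized to 1 at
    response onset, defines the decision variable: RT is the first time
    it falls below the angle's threshold and MT the further time until it
    falls below the movement-end threshold.  Traces may be 1-D (time,) or
    2-D (time, trials).
    """
    if angle not in params.rt_thresholds:
        raise KeyError(f"no RT threshold for angle {angle!r}")
    dra_L = np.asarray(dra_L, dtype=float)
    dra_S = np.asarray(dra_S, dtype=float)
    squeeze = dra_L.ndim == 1
    if squeeze:
        dra_L = dra_L[:, None]
        dra_S = dra_S[:, None]
    n = dra_L.shape[1]

    attr_L = dra_L[-1] if attractor_L is None else np.broadcast_to(
        np.asarray(attractor_L, dtype=float), (n,))
    attr_S = dra_S[-1] if attractor_S is None else np.broadcast_to(
        np.asarray(attractor_S, dtype=float), (n,))

    win_long = dra_L[-1] > dra_S[-1]
    tie = dra_L[-1] == dra_S[-1]
    dw = np.where(win_long[None, :], dra_L, dra_S)
    attr = np.where(win_long, attr_L, attr_S)
    span = attr - dw[0]
    degenerate = tie | (span <= 0)
    span = np.where(degenerate, 1.0, span)
    dist = (attr[None, :] - dw) / span[None, :]

    thr = params.rt_thresholds[angle]
    below_rt = dist < thr
    has_rt = below_rt.any(axis=0)
    rt_idx = np.argmax(below_rt, axis=0).astype(float)
    below_mv = dist < params.move_threshold
    has_mv = below_mv.any(axis=0)
    mv_idx = np.argmax(below_mv, axis=0).astype(float)

    ok = has_rt & ~degenerate
    rt = np.where(ok, rt_idx * params.dt, np.nan)
    mt = np.where(ok & has_mv, (mv_idx - rt_idx) * params.dt, np.nan)
    rt = params.rt_offset_ms + params.rt_gain * rt
    mt = params.mt_offset_ms + params.mt_gain * mt
    choice = np.where(ok, np.where(win_long, "long", "short"), "none")

    if squeeze:
        return {"choice": str(choice[0]), "rt_ms": float(rt[0]), "mt_ms": float(mt[0])}
    return {"choice": choice, "rt_ms": rt, "mt_ms": mt}


def _response_phase_batch(state: NetworkState, params: AttractorParams,
                          rng: np.random.Generator | None, reduced: bool):
    """Run the response phase recording reading-area traces (float32)."""
    n = state.L.shape[0]
    steps = int(round(params.max_response_ms / params.dt))
    draL = np.empty((steps + 1, n), dtype=np.float32)
    draS = np.empty((steps + 1, n), dtype=np.float32)

    def readout(st):
        if reduced:
            return st.L / params.M, st.S / params.M
        return (dra_trace(st.L, st.M_L, params.M),
                dra_trace(st.S, st.M_S, params.M))

    a, b = readout(state)
    draL[0], draS[0] = a, b
    for k in range(steps):
        state = step_state(state, params, "response", rng)
        a, b = readout(state)
        draL[k + 1], draS[k + 1] = a, b
    return state, draL, draS


def _simulate_batch(params: AttractorParams, interval_ms: float, n: int,
                    seed: int | np.random.Generator, reduced: bool = False,
                    delay_ms: float | None = None,
                    angles: tuple | None = None) -> dict:
    """Simulate ``n`` trials of one interval; RT/MT for every angle.

    The target angle affects only the readout thresholds, so RT and MT
    for all angles are read from the same response-phase trace.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rng = rng if params.noise_sd > 0 else None
    if delay_ms is None:
        delay_ms = params.delay_ms
    if angles is None:
        angles = tuple(sorted(params.rt_thresholds))

    state = initial_state(params, n)
    state, _ = run_phase(state, params, "stimulus", interval_ms, rng)
    state.phase = "delay"
    state, _ = run_phase(state, params, "delay", delay_ms, rng)
    state.phase = "response"
    _, draL, draS = _response_phase_batch(state, params, rng, reduced)

    out = {"interval_ms": interval_ms}
    for ang in angles:
        r = read_rt_mt(draL, draS, ang, params)
        out[ang] = r
    first = out[angles[0]]
    out["choice"] = first["choice"]        # choice is angle-independent
    out["is_long"] = first["choice"] == "long"
    out["none"] = first["choice"] == "none"
    out["correct"] = np.where(
        out["none"], False, out["is_long"] == (interval_ms > params.boundary_ms))
    return out


def simulate_trial(interval_ms: float, angle: float, params: AttractorParams,
                   seed: int, record_traces: bool = False,
                   delay_ms: float | None = None) -> TrialResult:
    """Simulate a single trial through stimulus, delay and response phases."""
    if interval_ms <= 0:
        raise ValueError("interval_ms must be > 0")
    rng = np.random.default_rng(seed) if params.noise_sd > 0 else None
    if delay_ms is None:
        delay_ms = params.delay_ms

    state = initial_state(params)
    state, tr_stim = run_phase(state, params, "stimulus", interval_ms, rng,
                               record=record_traces)
    state.phase = "delay"
    state, tr_delay = run_phase(state, params, "delay", delay_ms, rng,
                                record=record_traces)
    state.phase = "response"
    state_arr = NetworkState(np.atleast_1d(state.L), np.atleast_1d(state.S),
                             np.atleast_1d(state.M_L), np.atleast_1d(state.M_S),
                             state.t, "response")
    _, draL, draS = _response_phase_batch(state_arr, params, rng, reduced=False)
    r = read_rt_mt(draL[:, 0], draS[:, 0], angle, params)

    choice = r["choice"]
    correct = (choice != "none") and (
        (choice == "long") == (interval_ms > params.boundary_ms))
    traces = None
    if record_traces:
        traces = {
            "stimulus": tr_stim, "delay": tr_delay,
            "response_dra_L": draL[:, 0].astype(float),
            "response_dra_S": draS[:, 0].astype(float),
        }
    return TrialResult(interval_ms=interval_ms, angle_deg=angle, choice=choice,
                       correct=bool(correct), rt_ms=r["rt_ms"], mt_ms=r["mt_ms"],
                       traces=traces)


@dataclass
class ExperimentSummary:
    """Summary tables of a simulated experiment.

    ``cells``: one row per interval x angle x outcome with n, error rate
    and RT/MT moments.  ``psychometric``: per-interval choice proportions.
    """

    cells: "object"
    psychometric: "object"
    n_per_interval: int
    seed: int
    reduced: bool = False

    def p_long(self) -> np.ndarray:
        return self.psychometric["p_long"].to_numpy()


def simulate_experiment(params: AttractorParams, n_per_interval: int, seed: int,
                        intervals=DEFAULT_INTERVALS, reduced: bool = False,
                        delay_ms: float | None = None,
                        angles: tuple | None = None) -> ExperimentSummary:
    """Simulate ``n_per_interval`` trials for every interval and summarise.

    Per-trial RT/MT are read at every requested angle from the same
    network trajectory (the angle only moves the readout thresholds).
    """
    import pandas as pd

    if n_per_interval < 1:
        raise ValueError("n_per_interval must be >= 1")
    if angles is None:
        angles = tuple(sorted(params.rt_thresholds))
    cells = []
    psych = []
    for i, interval in enumerate(intervals):
        b = _simulate_batch(params, float(interval), n_per_interval,
                            seed + 7919 * i, reduced=reduced,
                            delay_ms=delay_ms, angles=angles)
        valid = ~b["none"]
        psych.append({
            "interval_ms": float(interval),
            "n": int(valid.sum()),
            "n_long": int(b["is_long"][valid].sum()),
            "p_long": float(b["is_long"][valid].mean()) if valid.any() else np.nan,
            "n_none": int(b["none"].sum()),
        })
        for ang in angles:
            rt, mt = b[ang]["rt_ms"], b[ang]["mt_ms"]
            for outcome, mask in (("correct", b["correct"] & valid),
                                  ("error", ~b["correct"] & valid)):
                cells.append({
                    "interval_ms": float(interval), "angle_deg": float(ang),
                    "outcome": outcome, "n": int(mask.sum()),
                    "error_rate": float((~b["correct"])[valid].mean()) if valid.any() else np.nan,
                    "rt_mean": float(np.nanmean(rt[mask])) if mask.any() else np.nan,
                    "rt_sd": float(np.nanstd(rt[mask])) if mask.any() else np.nan,
                    "mt_mean": float(np.nanmean(mt[mask])) if mask.any() else np.nan,
                    "mt_sd": float(np.nanstd(mt[mask])) if mask.any() else np.nan,
                })
    return ExperimentSummary(cells=pd.DataFrame(cells),
                             psychometric=pd.DataFrame(psych),
                             n_per_interval=n_per_interval, seed=seed,
                             reduced=reduced)


def simulate_reduced(params: AttractorParams, n_per_interval: int, seed: int,
                     intervals=DEFAULT_INTERVALS,
                     delay_ms: float | None = None,
                     angles: tuple | None = None) -> ExperimentSummary:
    """Ablated variant: no memory pair, no reading areas.

    The readout thresholds are applied to the winning accumulation
    node's own normalized distance to its attractor.
    """
    return simulate_experiment(params, n_per_interval, seed,
                               intervals=intervals, reduced=True,
                               delay_ms=delay_ms, angles=angles)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def diagonal_crossing_time(params: AttractorParams, pair: str = "accumulation",
                           t_max_ms: float = 8000.0) -> float:
    """Zero-noise time at which the pair's trajectory crosses its diagonal.

    Integrates the noise-free stimulus-phase dynamics from the mirrored
    fixed point and returns the first time the long-preferring unit
    overtakes its partner (inf if it never does within ``t_max_ms``).
    """
    p = params.replace(noise_sd=0.0)
    el, es, eml, ems = p.phase_inputs["stimulus"]
    if pair == "accumulation":
        e_hi, e_lo, tau = el, es, p.tau
    elif pair == "memory":
        e_hi, e_lo, tau = eml, ems, p.tau_mem
    else:
        raise ValueError("pair must be 'accumulation' or 'memory'")
    hi, lo = _pair_fixed_point(e_hi, e_lo, p)
    a, b = lo, hi            # mirrored start
    f = sigmoid_output
    n_steps = int(t_max_ms / p.dt)
    for k in range(n_steps):
        if a >= b:
            return k * p.dt
        a2 = a + p.dt / tau * (-a + float(f(e_hi - p.w_inh * b, p.M, p.beta)))
        b2 = b + p.dt / tau * (-b + float(f(e_lo - p.w_inh * a, p.M, p.beta)))
        a, b = a2, b2
    return float("inf")


def _bisect_asymmetry(params: AttractorParams, pair: str, target_ms: float,
                      lo: float = 0.3, hi: float = 8.0, iters: int = 50) -> float:
    """Asymmetry whose zero-noise diagonal crossing equals ``target_ms``.

    Crossing time decreases with asymmetry (it is infinite below the
    saddle-node), so plain bisection applies.
    """
    def crossing(a):
        if pair == "accumulation":
            p = params.with_stimulus_asymmetry(a)
        else:
            acc = params.stimulus_asymmetry()[0]
            p = params.with_stimulus_asymmetry(acc, a)
        return diagonal_crossing_time(p, pair)

    if not crossing(hi) <= target_ms:
        raise CalibrationError(
            f"{pair} pair: even asymmetry {hi} crosses later than {target_ms} ms")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if crossing(mid) > target_ms:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_pse(params: AttractorParams, n_per_interval: int, seed: int,
                 intervals=DEFAULT_INTERVALS) -> float:
    """Simulated point of subjective equality from a logistic psychometric fit."""
    from .psychometrics import fit_psychometric

    summary = simulate_experiment(params, n_per_interval, seed,
                                  intervals=intervals, angles=(90,))
    fit = fit_psychometric(summary.psychometric, boundary_ms=params.boundary_ms)
    return fit.pse_ms


def calibrate(params: AttractorParams, targets: dict | None = None,
              n_refine: int = 0, seed: int = 0, check_ordering: bool = False,
              ordering_n: int = 500) -> dict:
    """Calibrate the stimulus-phase drive asymmetries to the category boundary.

    Stage 1 (deterministic): bisect each pair's asymmetry so that the
    zero-noise diagonal crossing equals ``targets['boundary_ms']``.
    Stage 2 (optional, ``n_refine`` > 0): secant refinement of the
    accumulation asymmetry against the *simulated* PSE at the default
    noise, the quantity the published procedure minimised.
    Stage 3 (optional): verify the RT/MT orderings over angles on a
    simulation of ``ordering_n`` trials/interval; failures raise
    CalibrationError naming the violated constraint.

    Returns {'params': AttractorParams, 'report': dict}.
    """
    targets = dict(targets or {})
    boundary = float(targets.get("boundary_ms", params.boundary_ms))
    report = {"boundary_ms": boundary}

    a_acc = _bisect_asymmetry(params, "accumulation", boundary)
    p1 = params.with_stimulus_asymmetry(a_acc)
    a_mem = _bisect_asymmetry(p1, "memory", boundary)
    fitted = p1.with_stimulus_asymmetry(a_acc, a_mem).replace(boundary_ms=boundary)
    report["a_accumulation"] = a_acc
    report["a_memory"] = a_mem
    report["zero_noise_crossing_ms"] = diagonal_crossing_time(fitted)

    if n_refine > 0 and fitted.noise_sd > 0:
        a0, a1 = a_acc, a_acc * 0.995
        pse0 = estimate_pse(fitted.with_stimulus_asymmetry(a0, a_mem),
                            n_refine, seed)
        history = [(a0, pse0)]
        for _ in range(5):
            pse1 = estimate_pse(fitted.with_stimulus_asymmetry(a1, a_mem),
                                n_refine, seed)
            history.append((a1, pse1))
            if abs(pse1 - boundary) < 2.0 or pse1 == pse0:
                break
            a2 = a1 + (boundary - pse1) * (a1 - a0) / (pse1 - pse0)
            a0, pse0, a1 = a1, pse1, float(np.clip(a2, 0.5 * a_acc, 2.0 * a_acc))
        fitted = fitted.with_stimulus_asymmetry(a1, a_mem)
        report["refined_a_accumulation"] = a1
        report["refined_pse_ms"] = history[-1][1]
        report["refinement_history"] = history

    if check_ordering:
        angles = tuple(sorted(fitted.rt_thresholds))
        s = simulate_experiment(fitted, ordering_n, seed + 1, angles=angles)
        cc = s.cells[s.cells["outcome"] == "correct"]
        rt = cc.groupby("angle_deg")["rt_mean"].mean()
        mt = cc.groupby("angle_deg")["mt_mean"].mean()
        failures = []
        if not rt.loc[list(angles)].is_monotonic_increasing:
            failures.append("RT not increasing with angle")
        if not mt.loc[list(angles)].is_monotonic_decreasing:
            failures.append("MT not decreasing with angle")
        if failures:
            raise CalibrationError("; ".join(failures))
        report["ordering_checked"] = True

    return {"params": fitted, "report": report}


def predict_generalization(params: AttractorParams,
                           delays=(0.0, 1000.0, 3000.0),
                           angles=(45, 90, 135, 180),
                           intervals=DEFAULT_INTERVALS,
                           n_per_interval: int = 1000, seed: int = 0) -> dict:
    """Predicted performance / RT / MT for untested delays, angles, intervals.

    Returns {'by_interval': DataFrame(delay_ms, interval_ms, error_rate,
    p_long, rt/mt of correct trials at 90 deg), 'by_angle':
    DataFrame(delay_ms, angle_deg, rt_mean, mt_mean over correct trials)}.
    """
    import pandas as pd

    rows_i, rows_a = [], []
    for d in delays:
        s = simulate_experiment(params, n_per_interval, seed,
                                intervals=intervals, delay_ms=float(d),
                                angles=tuple(angles))
        ref_ang = 90 if 90 in angles else angles[0]
        cc = s.cells[(s.cells["outcome"] == "correct")
                     & (s.cells["angle_deg"] == ref_ang)]
        for _, r in s.psychometric.iterrows():
            c = cc[cc["interval_ms"] == r["interval_ms"]]
            rows_i.append({
                "delay_ms": float(d), "interval_ms": r["interval_ms"],
                "p_long": r["p_long"],
                "error_rate": abs((r["interval_ms"] > params.boundary_ms)
                                  - r["p_long"]),
                "rt_correct_ms": float(c["rt_mean"].iloc[0]) if len(c) else np.nan,
                "mt_correct_ms": float(c["mt_mean"].iloc[0]) if len(c) else np.nan,
            })
        corr = s.cells[s.cells["outcome"] == "correct"]
        g = corr.groupby("angle_deg").apply(
            lambda x: pd.Series({
                "rt_mean": np.average(x["rt_mean"], weights=x["n"]),
                "mt_mean": np.average(x["mt_mean"], weights=x["n"]),
            }), include_groups=False)
        for ang, r in g.iterrows():
            rows_a.append({"delay_ms": float(d), "angle_deg": float(ang),
                           "rt_mean": r["rt_mean"], "mt_mean": r["mt_mean"]})
    return {"by_interval": pd.DataFrame(rows_i), "by_angle": pd.DataFrame(rows_a)}
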