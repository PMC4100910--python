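"""Synthetic joystick behaviour with controllable ground truth.

Trajectories are built from the standard quintic minimum-jerk profile
(zero velocity and acceleration at both ends, single-peaked bell speed),
optionally composed with a change of mind (an initial minimum-jerk
segment towards the non-chosen target blended smoothly into a corrective
segment), brief out-and-back pulses that create extra jerk peaks
(submovements), and additive Gaussian position noise.  Whole sessions
draw choices from a configurable logistic psychometric curve and RT/MT
from interval- and angle-dependent means shaped like the empirical
pattern: RT is an inverted U over intervals and grows with target
separation, MT shrinks with separation.

Every generator is fully deterministic under its seed and always emits
the ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .task_design import CATEGORY_BOUNDARY_MS, SessionDesign


def _quintic_step(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk unit step 0 -> 1 on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _quintic_boundary(p0, v0, a0, p1, v1, a1, T):
    """Quintic polynomial coefficients matching pos/vel/acc at both ends."""
    A = np.array([
        [1, 0, 0, 0, 0, 0],
        [0, 1, 0, 0, 0, 0],
        [0, 0, 2, 0, 0, 0],
        [1, T, T ** 2, T ** 3, T ** 4, T ** 5],
        [0, 1, 2 * T, 3 * T ** 2, 4 * T ** 3, 5 * T ** 4],
        [0, 0, 2, 6 * T, 12 * T ** 2, 20 * T ** 3],
    ])
    return np.linalg.solve(A, np.array([p0, v0, a0, p1, v1, a1], dtype=float))


#: Fractions of movement duration at which a noise-free minimum-jerk speed
#: profile crosses 10% of its peak (roots of 30 s^2 (1-s)^2 = 0.1875).
MIN_JERK_ONSET_FRAC = 0.0863311
MIN_JERK_OFFSET_FRAC = 1.0 - MIN_JERK_ONSET_FRAC

#: Peak of the unit minimum-jerk speed profile: vmax = 1.875 * d / T.
MIN_JERK_PEAK_FACTOR = 1.875


def min_jerk_path(amplitude: float, duration_ms: float, rate_hz: float,
                  angle_deg: float = 0.0, inter_target_angle_deg: float = 90.0
                  ) -> Trajectory:
    """Straight minimum-jerk reach from the origin to the target.

    Peak speed is 1.875 x amplitude / duration, reached at mid-movement;
    velocity and acceleration vanish at both endpoints.
    """
    dt = 1000.0 / rate_hz
    n = int(round(duration_ms / dt))
    if n < 10:
        raise ValueError("duration must span at least 10 samples")
    t = np.arange(n + 1) * dt
    s = _quintic_step(t / duration_ms)
    th = np.deg2rad(angle_deg)
    return Trajectory(t_ms=t, x=amplitude * s * np.cos(th),
                      y=amplitude * s * np.sin(th), sampling_rate_hz=rate_hz,
                      target_angle_deg=angle_deg,
                      inter_target_angle_deg=inter_target_angle_deg)


@dataclass
class SynthTrialSpec:
    """Ground-truth recipe for one synthetic trial."""

    rt_true: float = 300.0           # ms from target onset to movement start
    mt_true: float = 600.0           # ms movement duration
    amplitude: float = 10.0          # units, centre to target
    target_angle_deg: float = 0.0
    inter_target_angle_deg: float = 90.0
    n_submovements_true: int = 0
    decision_change_true: bool = False
    switch_frac: float = 0.3         # change-of-mind switch point
    noise_sd: float = 0.0            # units, additive position noise
    sampling_rate_hz: float = 100.0
    pre_hold_ms: float = 100.0       # recorded hold before target onset
    post_hold_ms: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_true <= 0 or self.mt_true <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.switch_frac < 1:
            raise ValueError("switch_frac must lie in (0, 1)")
        if self.n_submovements_true > 3:
            raise ValueError("at most 3 inserted submovements")


def _movement_xy(spec: SynthTrialSpec, t_move: np.ndarray) -> np.ndarray:
    """Noise-free movement displacement at times t_move (0 = movement start)."""
    T = spec.mt_true
    th = np.deg2rad(spec.target_angle_deg)
    target = spec.amplitude * np.array([np.cos(th), np.sin(th)])

    if not spec.decision_change_true:
        s = _quintic_step(t_move / T)
        xy = np.outer(s, target)
    else:
        # first head to the non-chosen target, then blend into a
        # corrective quintic with matched position/velocity/acceleration
        th2 = np.deg2rad(spec.target_angle_deg + spec.inter_target_angle_deg)
        wrong = spec.amplitude * np.array([np.cos(th2), np.sin(th2)])
        t_sw = spec.switch_frac * T
        xy = np.zeros((len(t_move), 2))
        early = t_move <= t_sw
        s = _quintic_step(t_move[early] / T)
        xy[early] = np.outer(s, wrong)
        tau = t_sw / T
        s_sw = _quintic_step(tau)
        ds = 30 * tau ** 2 * (1 - tau) ** 2 / T
        dds = (60 * tau - 180 * tau ** 2 + 120 * tau ** 3) / T ** 2
        rem = T - t_sw
        coef = [
            _quintic_boundary(s_sw * wrong[k], ds * wrong[k], dds * wrong[k],
                              target[k], 0.0, 0.0, rem)
            for k in range(2)
        ]
        late = ~early
        tt = t_move[late] - t_sw
        for k in range(2):
            xy[late, k] = sum(c * tt ** i for i, c in enumerate(coef[k]))

    n_p = spec.n_submovements_true
    if n_p > 0:
        # out-and-back pulses along the chord: each adds a brief
        # deceleration-reacceleration and hence extra jerk peaks.  The
        # pulse amplitude is set so its peak jerk is a fixed multiple of
        # the base movement's interior jerk peak (30 d / T^3): strong
        # enough to survive the smoothing stage and small measurement
        # noise, while the implied speed dip stays far above the 10%
        # movement-bound threshold.
        th = np.deg2rad(spec.target_angle_deg)
        u = np.array([np.cos(th), np.sin(th)])
        width = min(0.30, 0.70 / n_p) * T
        jerk_ratio = 40.0
        amp = jerk_ratio * 30.0 * spec.amplitude * (width / 2) ** 3 \
            / (60.0 * T ** 3)
        centers = (np.array([0.62]) if n_p == 1
                   else np.linspace(0.35, 0.78, n_p)) * T
        for c in centers:
            tau = (t_move - (c - width / 2)) / width
            w = np.where(tau < 0.5, _quintic_step(2 * tau),
                         _quintic_step(2 - 2 * tau))
            xy -= amp * np.outer(w, u)
    return xy


def synth_trajectory(spec: SynthTrialSpec) -> tuple[Trajectory, dict]:
    """Build one synthetic trajectory and its ground truth.

    The recorded window runs from ``pre_hold_ms`` before target onset
    (t = 0) to ``post_hold_ms`` after movement end.  Ground truth includes
    the analytically expected measured RT/MT for a plain minimum-jerk
    reach (the 10%-of-peak-speed crossings fall strictly inside the
    movement, at fixed fractions of its duration).
    """
    if spec.decision_change_true and spec.switch_frac >= 1.0:
        raise ValueError("switch later than movement end")
    dt = 1000.0 / spec.sampling_rate_hz
    t0 = -spec.pre_hold_ms
    t1 = spec.rt_true + spec.mt_true + spec.post_hold_ms
    t = np.arange(t0, t1 + dt / 2, dt)
    xy = np.zeros((len(t), 2))
    moving = t >= spec.rt_true
    xy[moving] = _movement_xy(spec, np.minimum(t[moving] - spec.rt_true,
                                               spec.mt_true))
    def make_traj(arr):
        return Trajectory(t_ms=t, x=arr[:, 0], y=arr[:, 1],
                          sampling_rate_hz=spec.sampling_rate_hz,
                          target_angle_deg=spec.target_angle_deg,
                          inter_target_angle_deg=spec.inter_target_angle_deg,
                          target_onset_ms=0.0, trial_id=spec.seed)

    # the jerk-peak ground truth is the ideal (noise-free) measurement: a
    # compact velocity perturbation necessarily contributes several jerk
    # lobes, so the inserted-pulse count and the peak count differ by a
    # construction-dependent factor
    from .kinematics import analyze_trajectory
    ideal = analyze_trajectory(make_traj(xy))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        xy = xy + rng.normal(0.0, spec.noise_sd, xy.shape)

    traj = make_traj(xy)
    plain = not spec.decision_change_true and spec.n_submovements_true == 0
    truth = {
        "rt_true": spec.rt_true, "mt_true": spec.mt_true,
        "amplitude": spec.amplitude,
        "n_pulses_true": spec.n_submovements_true,
        "n_submovements_true": ideal.n_submovements,
        "decision_change_true": spec.decision_change_true,
        # analytic 10%-of-peak crossing expectations hold for the plain
        # minimum-jerk speed profile only; changes of mind and inserted
        # pulses reshape the profile, so no closed form for those trials
        "expected_rt_measured": (spec.rt_true + MIN_JERK_ONSET_FRAC * spec.mt_true
                                 if plain else np.nan),
        "expected_mt_measured": ((MIN_JERK_OFFSET_FRAC - MIN_JERK_ONSET_FRAC)
                                 * spec.mt_true if plain else np.nan),
        "expected_vmax": (MIN_JERK_PEAK_FACTOR * spec.amplitude / spec.mt_true
                          if plain else np.nan),
    }
    return traj, truth


@dataclass
class BehaviorParams:
    """Group-level generative parameters for synthetic sessions.

    Defaults are one fixed, realistic operating point: a logistic choice
    curve centred on the category boundary with a ~50 ms difference
    threshold; RT around 420 ms with an inverted-U difficulty bump and a
    linear increase with target separation; MT around 650 ms decreasing
    with separation.
    """

    pse_ms: float = CATEGORY_BOUNDARY_MS
    slope_per_ms: float = 0.022
    rt_base_ms: float = 380.0
    rt_difficulty_ms: float = 90.0       # bump height at the boundary
    rt_difficulty_width_ms: float = 120.0
    rt_angle_gain_ms: float = 60.0       # RT(180) - RT(45)
    rt_sd_ms: float = 60.0
    mt_base_ms: float = 700.0
    mt_difficulty_ms: float = 50.0
    mt_angle_gain_ms: float = 100.0      # MT(45) - MT(180)
    mt_sd_ms: float = 70.0
    amplitude: float = 10.0
    sampling_rate_hz: float = 100.0
    noise_sd: float = 0.05
    p_decision_change: dict = field(
        default_factory=lambda: {45: 0.10, 90: 0.06, 135: 0.04, 180: 0.03})
    p_submovement: tuple = (0.70, 0.25, 0.05)   # P(0), P(1), P(2)

    def p_long(self, interval_ms) -> np.ndarray:
        x = np.asarray(interval_ms, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.slope_per_ms * (x - self.pse_ms)))

    def rt_mean(self, interval_ms, angle_deg) -> np.ndarray:
        bump = np.exp(-0.5 * ((np.asarray(interval_ms, float) - self.pse_ms)
                              / self.rt_difficulty_width_ms) ** 2)
        ang = (np.asarray(angle_deg, float) - 45.0) / 135.0
        return self.rt_base_ms + self.rt_difficulty_ms * bump \
            + self.rt_angle_gain_ms * ang

    def mt_mean(self, interval_ms, angle_deg) -> np.ndarray:
        bump = np.exp(-0.5 * ((np.asarray(interval_ms, float) - self.pse_ms)
                              / self.rt_difficulty_width_ms) ** 2)
        ang = (np.asarray(angle_deg, float) - 45.0) / 135.0
        return self.mt_base_ms + self.mt_difficulty_ms * bump \
            - self.mt_angle_gain_ms * ang


def synth_session(design: SessionDesign, behavior: BehaviorParams | None = None,
                  seed: int = 0, trajectories: bool = True,
                  subject: int = 1) -> dict:
    """Generate one synthetic session from a trial design.

    Returns {'behavior': DataFrame, 'truth': DataFrame,
    'trajectories': list[Trajectory] | None}.  The behavioural table uses
    the layout subject, session, trial, interval_ms, angle_deg, choice,
    outcome, rt_ms, mt_ms.
    """
    behavior = behavior or BehaviorParams()
    rng = np.random.default_rng(seed)
    rows, truths, trajs = [], [], [] if trajectories else None
    testing = design.testing.reset_index(drop=True)
    for i, tr in testing.iterrows():
        interval = float(tr["interval_ms"])
        angle = float(tr["angle_deg"])
        choose_long = rng.random() < behavior.p_long(interval)
        is_long = bool(tr["is_long"])
        target = float(tr["pos_long_deg"] if choose_long else tr["pos_short_deg"])
        rt = max(float(rng.normal(behavior.rt_mean(interval, angle),
                                  behavior.rt_sd_ms)), 120.0)
        mt = max(float(rng.normal(behavior.mt_mean(interval, angle),
                                  behavior.mt_sd_ms)), 250.0)
        change = rng.random() < behavior.p_decision_change.get(int(angle), 0.05)
        n_sub = int(rng.choice(len(behavior.p_submovement),
                               p=behavior.p_submovement))
        rows.append({
            "subject": subject, "session": int(tr["session"]),
            "trial": int(tr["trial"]), "interval_ms": interval,
            "angle_deg": angle, "choice": "long" if choose_long else "short",
            "outcome": "correct" if choose_long == is_long else "error",
            "rt_ms": rt, "mt_ms": mt,
        })
        if trajectories:
            spec = SynthTrialSpec(
                rt_true=rt, mt_true=mt, amplitude=behavior.amplitude,
                target_angle_deg=target, inter_target_angle_deg=angle,
                n_submovements_true=n_sub, decision_change_true=change,
                noise_sd=behavior.noise_sd,
                sampling_rate_hz=behavior.sampling_rate_hz,
                seed=int(rng.integers(2 ** 31)))
            traj, truth = synth_trajectory(spec)
            traj.trial_id = int(tr["trial"])
            trajs.append(traj)
            truth.update({"trial": int(tr["trial"]),
                          "target_angle_deg": target, "angle_deg": angle})
            truths.append(truth)
        else:
            truths.append({"trial": int(tr["trial"]),
                           "decision_change_true": change,
                           "n_submovements_true": n_sub})
    return {"behavior": pd.DataFrame(rows), "truth": pd.DataFrame(truths),
            "trajectories": trajs}
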