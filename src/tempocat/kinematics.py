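"""Reach-trajectory kinematics: projection, smoothing and derived measures.

The analysis chain mirrors standard joystick/cursor processing: every
trajectory is rotated so its chosen target lies at 0 degrees, low-pass
filtered (zero-phase Butterworth, 20 Hz) and Kalman-smoothed; movement
onset and offset are the crossings of 10% of peak speed around the
global speed peak; submovements are counted from extra jerk peaks inside
the movement; curvature is summarised by the area between the path and
its straight chord (100 arc-length-equidistant points) and by the polar
angle of the point of maximum perpendicular deviation, which also
classifies decision changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks


class NoMovementError(ValueError):
    """Raised when a speed trace never rises above the numerical floor."""


@dataclass
class Trajectory:
    """Uniformly sampled 2-D cursor path for one trial.

    ``t_ms`` must be strictly increasing with a uniform step; positions
    are in screen/joystick units.  ``target_angle_deg`` is the chosen
    response circle's direction and ``inter_target_angle_deg`` the
    separation of the two circles (45/90/135/180).
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate_hz: float
    target_angle_deg: float = 0.0
    inter_target_angle_deg: float = 90.0
    target_onset_ms: float = 0.0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t_ms) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t_ms) < 10:
            raise ValueError("need at least 10 samples")
        dt = np.diff(self.t_ms)
        if np.any(dt <= 0):
            raise ValueError("t_ms must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
            raise ValueError("sampling must be uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def replace_xy(self, x, y) -> "Trajectory":
        return Trajectory(self.t_ms.copy(), np.asarray(x, float),
                          np.asarray(y, float), self.sampling_rate_hz,
                          self.target_angle_deg, self.inter_target_angle_deg,
                          self.target_onset_ms, self.trial_id)


@dataclass
class KinematicSummary:
    """All trajectory-derived measures for one trial."""

    trial_id: int
    rt_ms: float
    mt_ms: float
    vmax: float                      # units per ms
    n_submovements: int
    area: float                      # units^2
    max_deviation_angle_deg: float
    decision_change: bool
    anticipation: bool = False       # movement onset before target onset
    extra: dict = field(default_factory=dict)


def project_to_common_direction(traj: Trajectory) -> Trajectory:
    """Rotate the path about the origin so the chosen target lies at 0 deg.

    A pure rotation: sample radii are preserved.
    """
    th = -np.deg2rad(traj.target_angle_deg)
    c, s = np.cos(th), np.sin(th)
    out = traj.replace_xy(c * traj.x - s * traj.y, s * traj.x + c * traj.y)
    out.target_angle_deg = 0.0
    return out


def _kalman_cv_smooth(z: np.ndarray, dt: float, r_var: float,
                      q_scale: float) -> np.ndarray:
    """Constant-velocity Kalman filter + RTS smoother for one coordinate.

    ``r_var`` is the measurement-noise variance, ``q_scale`` the process
    noise spectral density (units^2 / ms^3).
    """
    n = len(z)
    F = np.array([[1.0, dt], [0.0, 1.0]])
    Q = q_scale * np.array([[dt ** 3 / 3.0, dt ** 2 / 2.0],
                            [dt ** 2 / 2.0, dt]])
    H = np.array([1.0, 0.0])
    xs = np.zeros((n, 2))
    Ps = np.zeros((n, 2, 2))
    xp = np.zeros((n, 2))
    Pp = np.zeros((n, 2, 2))

    xf = np.array([z[0], 0.0])
    P = np.diag([r_var, 1e-2])
    for k in range(n):
        if k > 0:
            xf = F @ xf
            P = F @ P @ F.T + Q
        xp[k], Pp[k] = xf, P
        S = H @ P @ H + r_var
        K = (P @ H) / S
        xf = xf + K * (z[k] - H @ xf)
        P = P - np.outer(K, H @ P)
        xs[k], Ps[k] = xf, P

    # Rauch-Tung-Striebel backward pass
    out = xs.copy()
    for k in range(n - 2, -1, -1):
        C = Ps[k] @ F.T @ np.linalg.inv(Pp[k + 1])
        out[k] = xs[k] + C @ (out[k + 1] - xp[k + 1])
    return out[:, 0]


def smooth(traj: Trajectory, cutoff_hz: float = 20.0, order: int = 4,
           kalman_hz: float = 10.0) -> Trajectory:
    """Zero-phase Butterworth low-pass followed by Kalman smoothing.

    The measurement-noise variance of the Kalman stage is estimated from
    the residual between the raw and Butterworth-filtered signals; the
    process noise is set generously so genuine movement is tracked and
    only measurement-scale jitter is removed.
    """
    fs = traj.sampling_rate_hz
    if fs <= 2.0 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {cutoff_hz} Hz cutoff")
    b, a = butter(order, cutoff_hz / (fs / 2.0), btype="low")
    pad = min(3 * max(len(b), len(a)), len(traj.x) - 1)
    xf = filtfilt(b, a, traj.x, padlen=pad)
    yf = filtfilt(b, a, traj.y, padlen=pad)

    dt = traj.dt_ms
    r_var = max(np.var(traj.x - xf) + np.var(traj.y - yf), 1e-12) / 2.0
    # process noise tied to the measurement noise so the smoother's
    # characteristic frequency sits near kalman_hz: in-band noise the
    # Butterworth passes is attenuated further while movement content
    # (a few Hz) is tracked.  Third derivatives amplify noise as f^3, so
    # this second stage is what makes jerk-based measures usable.
    omega0 = 2.0 * np.pi * kalman_hz / 1000.0          # rad per ms
    q_scale = r_var * omega0 ** 3
    xs = _kalman_cv_smooth(xf, dt, r_var, q_scale)
    ys = _kalman_cv_smooth(yf, dt, r_var, q_scale)
    return traj.replace_xy(xs, ys)


def speed_profile(traj: Trajectory) -> np.ndarray:
    """Speed (units/ms) from central differences of the positions."""
    vx = np.gradient(traj.x, traj.t_ms)
    vy = np.gradient(traj.y, traj.t_ms)
    return np.hypot(vx, vy)


def movement_bounds(speed: np.ndarray, t_ms: np.ndarray,
                    target_onset_ms: float = 0.0) -> dict:
    """Movement onset/offset: 10%-of-peak-speed crossings around the peak.

    Onset is the last upward crossing of 0.10 x vmax before the global
    speed peak; offset the first downward crossing after it.
    """
    speed = np.asarray(speed, dtype=float)
    vmax = float(speed.max(initial=0.0))
    if vmax <= 1e-12:
        raise NoMovementError("speed never exceeds the numerical floor")
    thr = 0.10 * vmax
    peak = int(np.argmax(speed))
    below_before = np.flatnonzero(speed[:peak + 1] < thr)
    onset_idx = int(below_before[-1] + 1) if below_before.size else 0
    after = np.flatnonzero(speed[peak:] < thr)
    offset_idx = int(peak + after[0] - 1) if after.size else len(speed) - 1
    return {"onset_t": float(t_ms[onset_idx]), "offset_t": float(t_ms[offset_idx]),
            "onset_idx": onset_idx, "offset_idx": offset_idx,
            "peak_idx": peak, "vmax": vmax}


def rt_mt_vmax(traj: Trajectory, bounds: dict | None = None) -> dict:
    """RT, MT and peak speed from a (projected, smoothed) trajectory.

    RT runs from target onset to movement onset; negative RT flags an
    anticipation but is reported, not dropped.
    """
    speed = speed_profile(traj)
    if bounds is None:
        bounds = movement_bounds(speed, traj.t_ms, traj.target_onset_ms)
    rt = bounds["onset_t"] - traj.target_onset_ms
    mt = bounds["offset_t"] - bounds["onset_t"]
    vmax = float(speed[bounds["onset_idx"]:bounds["offset_idx"] + 1].max())
    return {"rt_ms": float(rt), "mt_ms": float(mt), "vmax": vmax,
            "anticipation": bool(rt < 0)}


def count_submovements(traj: Trajectory, bounds: dict | None = None,
                       prominence_frac: float = 0.05,
                       baseline_factor: float = 2.0) -> int:
    """Extra jerk peaks within the movement window.

    Jerk is the magnitude of the third time-derivative of position; local
    maxima above a prominence floor are counted and one peak is the
    signature of a single smooth movement, so submovements =
    max(peaks - 1, 0).  The floor is the larger of ``prominence_frac``
    of the window's peak jerk and ``baseline_factor`` times the largest
    jerk seen before target onset: the pre-target hold contains only
    measurement noise, which pins down the scale below which jerk
    structure is not distinguishable from noise.
    """
    if bounds is None:
        bounds = movement_bounds(speed_profile(traj), traj.t_ms,
                                 traj.target_onset_ms)
    i0, i1 = bounds["onset_idx"], bounds["offset_idx"]
    if i1 - i0 + 1 < 5:
        raise ValueError("movement window shorter than 5 samples")
    t = traj.t_ms
    jx = np.gradient(np.gradient(np.gradient(traj.x, t), t), t)
    jy = np.gradient(np.gradient(np.gradient(traj.y, t), t), t)
    jerk_full = np.hypot(jx, jy)
    jerk = jerk_full[i0:i1 + 1]
    floor = prominence_frac * jerk.max()
    baseline = jerk_full[2:min(np.searchsorted(t, traj.target_onset_ms), i0)]
    if baseline.size >= 5:
        floor = max(floor, baseline_factor * float(baseline.max()))
    peaks, _ = find_peaks(jerk, prominence=floor)
    return max(int(len(peaks)) - 1, 0)


def curvature_measures(traj: Trajectory, n_points: int = 100,
                       bounds: dict | None = None,
                       min_deviation_frac: float = 0.01) -> dict:
    """Area between the path and its chord, and the max-deviation angle.

    The projected path (restricted to the movement window when ``bounds``
    is given) is resampled to ``n_points`` arc-length-equidistant points;
    the chord joins its first and last point.  ``area`` integrates the
    absolute perpendicular deviation along the chord; the returned angle
    is the (absolute) polar angle of the sample where the deviation is
    largest.  When the largest deviation is below ``min_deviation_frac``
    of the chord length the path counts as straight and the angle is 0
    (the polar angle of a near-zero deviation is numerically meaningless).
    """
    xy = np.column_stack([traj.x, traj.y])
    if bounds is not None:
        xy = xy[bounds["onset_idx"]:bounds["offset_idx"] + 1]
    if np.allclose(xy[0], xy[-1]):
        raise ValueError("start and end coincide; curvature undefined")
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    su = np.linspace(0.0, s[-1], n_points)
    xr = np.interp(su, s, xy[:, 0])
    yr = np.interp(su, s, xy[:, 1])

    p0 = np.array([xr[0], yr[0]])
    p1 = np.array([xr[-1], yr[-1]])
    chord = p1 - p0
    clen = np.linalg.norm(chord)
    u_hat = chord / clen
    rel = np.column_stack([xr, yr]) - p0
    u = rel @ u_hat                          # along-chord coordinate
    v = rel[:, 0] * u_hat[1] * -1 + rel[:, 1] * u_hat[0]   # perpendicular
    area = float(np.trapezoid(np.abs(v), u))
    k = int(np.argmax(np.abs(v)))
    if np.abs(v[k]) < min_deviation_frac * clen:
        angle = 0.0
    else:
        angle = float(np.degrees(np.arctan2(yr[k], xr[k])))
    return {"area": area, "max_deviation_angle_deg": abs(angle),
            "max_deviation_signed_deg": angle, "max_deviation": float(np.abs(v).max())}


def detect_decision_change(traj: Trajectory, measures: dict | None = None,
                           bounds: dict | None = None) -> bool:
    """Classify a change of mind from the projected trajectory.

    For separations of 45/90/135 degrees the criterion is a maximum
    deviation angle above half the inter-target angle; opposite targets
    (180 deg) use the sign of the first five samples after movement onset
    along the chosen-target axis instead.
    """
    if traj.inter_target_angle_deg == 180:
        if bounds is None:
            bounds = movement_bounds(speed_profile(traj), traj.t_ms,
                                     traj.target_onset_ms)
        i0 = bounds["onset_idx"]
        first5 = traj.x[i0:i0 + 5]
        return bool(np.all(first5 < 0))
    if measures is None:
        measures = curvature_measures(traj)
    return bool(measures["max_deviation_angle_deg"]
                > traj.inter_target_angle_deg / 2.0)


def analyze_trajectory(traj: Trajectory, cutoff_hz: float = 20.0,
                       presmoothed: bool = False) -> KinematicSummary:
    """Full pipeline: project, smooth, then compute every measure."""
    proj = project_to_common_direction(traj)
    sm_traj = proj if presmoothed else smooth(proj, cutoff_hz=cutoff_hz)
    speed = speed_profile(sm_traj)
    bounds = movement_bounds(speed, sm_traj.t_ms, sm_traj.target_onset_ms)
    core = rt_mt_vmax(sm_traj, bounds)
    n_sub = count_submovements(sm_traj, bounds)
    curv = curvature_measures(sm_traj, bounds=bounds)
    change = detect_decision_change(sm_traj, curv, bounds)
    return KinematicSummary(
        trial_id=traj.trial_id, rt_ms=core["rt_ms"], mt_ms=core["mt_ms"],
        vmax=core["vmax"], n_submovements=n_sub, area=curv["area"],
        max_deviation_angle_deg=curv["max_deviation_angle_deg"],
        decision_change=change, anticipation=core["anticipation"],
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_trajectories_csv(trajectories: list[Trajectory], path) -> None:
    """Raw-trajectory CSV: trial_id, t_ms, x, y with a JSON metadata header."""
    meta = {
        "sampling_rate_hz": trajectories[0].sampling_rate_hz,
        "trials": {
            str(tr.trial_id): {
                "target_angle_deg": tr.target_angle_deg,
                "inter_target_angle_deg": tr.inter_target_angle_deg,
                "target_onset_ms": tr.target_onset_ms,
            } for tr in trajectories
        },
    }
    frames = [pd.DataFrame({"trial_id": tr.trial_id, "t_ms": tr.t_ms,
                            "x": tr.x, "y": tr.y}) for tr in trajectories]
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("# tempocat trajectories\n")
        fh.write("# meta: " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_trajectories_csv(path) -> list[Trajectory]:
    """Read the raw-trajectory CSV written by write_trajectories_csv."""
    meta = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:"):])
            elif not line.startswith("#"):
                break
    if meta is None:
        raise ValueError(f"{path}: missing '# meta:' header")
    df = pd.read_csv(path, comment="#")
    need = {"trial_id", "t_ms", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        m = meta["trials"][str(int(tid))]
        out.append(Trajectory(
            t_ms=g["t_ms"].to_numpy(), x=g["x"].to_numpy(), y=g["y"].to_numpy(),
            sampling_rate_hz=meta["sampling_rate_hz"],
            target_angle_deg=m["target_angle_deg"],
            inter_target_angle_deg=m["inter_target_angle_deg"],
            target_onset_ms=m["target_onset_ms"], trial_id=int(tid)))
    return out


def summaries_to_frame(summaries: list[KinematicSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": s.trial_id, "rt_ms": s.rt_ms, "mt_ms": s.mt_ms,
        "vmax": s.vmax, "n_submovements": s.n_submovements, "area": s.area,
        "max_deviation_angle_deg": s.max_deviation_angle_deg,
        "decision_change": s.decision_change, "anticipation": s.anticipation,
    } for s in summaries])
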