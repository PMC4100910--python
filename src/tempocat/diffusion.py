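"""Random-walk (diffusion) baseline for the categorization task.

Evidence accumulates during the stimulus with constant drift and
diffusion, is frozen during the delay, and after target onset drifts
freely (zero drift by default) between two absorbing bounds; absorption
at the lower bound means a 'short' choice.  With zero post-onset drift
the hitting probability is the gambler's-ruin linear form, so the
predicted psychometric function is exactly affine in the interval --
which is why this baseline cannot reproduce a sigmoidal choice curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DiffusionParams:
    """Random-walk model constants.

    drift: mean accumulation rate per ms during the stimulus.
    sigma: diffusion SD per sqrt(ms).
    bound_short, bound_long: absorbing bounds (bound_short < bound_long).
    delay_ms: hold period during which the mean is maintained.
    post_drift: drift after target onset (0 gives the linear psychometric).
    """

    drift: float = 1.0
    sigma: float = 1.0
    bound_short: float = 0.0
    bound_long: float = 1000.0
    delay_ms: float = 1000.0
    post_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.bound_short >= self.bound_long:
            raise ValueError("bound_short must be < bound_long")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def accumulate_state(interval_ms: float, params: DiffusionParams) -> dict:
    """Mean and SD of the accumulated evidence at stimulus end.

    The mean grows linearly (drift x interval) and the SD diffusively
    (sigma x sqrt(interval)); both are held through the delay.
    """
    if interval_ms <= 0:
        raise ValueError("interval_ms must be > 0")
    return {"mean": params.drift * interval_ms,
            "sd": params.sigma * np.sqrt(interval_ms)}


def p_short_choice(start, bound_short: float, bound_long: float,
                   post_drift: float = 0.0, sigma: float = 1.0):
    """Probability of absorbing at the lower (short) bound.

    With zero post-onset drift this is the gambler's-ruin form
    (bound_long - start) / (bound_long - bound_short), linear in the
    start position.  For nonzero drift the exponential form is used.
    """
    x = np.asarray(start, dtype=float)
    if np.any(x < bound_short) or np.any(x > bound_long):
        raise ValueError("start must lie within the bounds")
    if post_drift == 0.0:
        p = (bound_long - x) / (bound_long - bound_short)
    else:
        k = 2.0 * post_drift / sigma ** 2
        num = np.exp(-k * x) - np.exp(-k * bound_long)
        den = np.exp(-k * bound_short) - np.exp(-k * bound_long)
        p = num / den
    return p if p.ndim else float(p)


def simulate_walk_choices(start, bound_short: float, bound_long: float,
                          n_walks: int, seed: int, sigma: float = 1.0,
                          post_drift: float = 0.0, dt_ms: float = 1.0,
                          max_steps: int = 2_000_000) -> float:
    """Monte-Carlo fraction of walks absorbed at the lower bound.

    Discrete 1 ms Gaussian-increment walks from ``start``; walks still
    unabsorbed after ``max_steps`` are excluded (none at sane settings).
    """
    rng = np.random.default_rng(seed)
    x = np.full(n_walks, float(start))
    alive = np.ones(n_walks, dtype=bool)
    hit_short = np.zeros(n_walks, dtype=bool)
    step_sd = sigma * np.sqrt(dt_ms)
    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x[idx] += post_drift * dt_ms + rng.standard_normal(idx.size) * step_sd
        lo = x[idx] <= bound_short
        hi = x[idx] >= bound_long
        hit_short[idx[lo]] = True
        alive[idx[lo | hi]] = False
    done = ~alive
    if not done.any():
        raise RuntimeError("no walk was absorbed")
    return float(hit_short[done].mean())


def psychometric_prediction(params: DiffusionParams, intervals) -> dict:
    """Predicted P(long) per interval: an exactly affine function.

    Returns the per-interval table plus the affine coefficients; intervals
    whose accumulated mean falls outside the bounds are flagged (their
    hitting probability saturates at 0/1).
    """
    intervals = np.asarray(intervals, dtype=float)
    means = params.drift * intervals
    inside = (means >= params.bound_short) & (means <= params.bound_long)
    clipped = np.clip(means, params.bound_short, params.bound_long)
    p_short = p_short_choice(clipped, params.bound_short, params.bound_long,
                             post_drift=params.post_drift, sigma=params.sigma)
    p_long = 1.0 - np.asarray(p_short)
    span = params.bound_long - params.bound_short
    slope = params.drift / span
    intercept = -params.bound_short / span
    table = pd.DataFrame({
        "interval_ms": intervals, "mean_evidence": means,
        "p_long": p_long, "within_bounds": inside,
    })
    return {"table": table, "slope_per_ms": float(slope),
            "intercept": float(intercept)}
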