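"""Trial structure of the temporal-bisection session.

Eight response-circle positions sit 45 degrees apart around a central
origin.  On every trial two of them are shown, and only position pairs
subtending 45, 90 or 180 degrees at the centre are admissible, which
yields 20 distinct pairs.  A session opens with a short training block
that presents only the two extreme intervals, followed by a testing
block in which each of the eight intervals appears once with each of
the 20 pairs, in a seeded random order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight stimulus intervals presented during testing, in ms.
DEFAULT_INTERVALS: tuple[float, ...] = (450, 500, 619, 669, 709, 756, 870, 920)

#: Angular separations (deg) that a response-circle pair may subtend.
ADMISSIBLE_SEPARATIONS: tuple[int, ...] = (45, 90, 180)

#: Implicit category boundary used throughout the package, in ms.  This is
#: the constant the published calibration targets; note that the arithmetic
#: mean of DEFAULT_INTERVALS is 686.625 ms and the midpoint of its extremes
#: is 685 ms (see interval_statistics), so the three do not coincide.
CATEGORY_BOUNDARY_MS: float = 687.5

N_POSITIONS = 8
TRAINING_TRIALS = 24


def target_positions() -> np.ndarray:
    """The eight response-circle positions in degrees (0 = right, CCW)."""
    return np.arange(N_POSITIONS) * 45.0


def angular_separation(a: float, b: float) -> float:
    """Minimal absolute circular difference between two angles in degrees."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class TargetLayout:
    """An unordered pair of response-circle positions.

    Attributes
    ----------
    pair
        The two positions in degrees, stored sorted.
    separation
        Their angular separation in degrees; one of 45, 90 or 180.
    """

    pair: tuple[float, float]
    separation: float = field(init=False)

    def __post_init__(self) -> None:
        a, b = sorted(self.pair)
        object.__setattr__(self, "pair", (float(a), float(b)))
        sep = angular_separation(a, b)
        object.__setattr__(self, "separation", float(sep))
        if sep not in ADMISSIBLE_SEPARATIONS:
            raise ValueError(
                f"pair {self.pair} subtends {sep} deg; admissible separations "
                f"are {ADMISSIBLE_SEPARATIONS}"
            )


def enumerate_target_pairs(
    separations: tuple[int, ...] = ADMISSIBLE_SEPARATIONS,
) -> list[TargetLayout]:
    """All admissible unordered position pairs.

    Returns the pairs sorted by separation then by first position.  With
    the default separations this is 20 pairs: 8 at 45 deg, 8 at 90 deg
    and 4 at 180 deg (each 180-deg pair is counted once).
    """
    pos = target_positions()
    out = []
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            sep = angular_separation(pos[i], pos[j])
            if sep in separations:
                out.append(TargetLayout(pair=(pos[i], pos[j])))
    out.sort(key=lambda t: (t.separation, t.pair[0]))
    return out


@dataclass
class SessionDesign:
    """One session's ordered trial table.

    ``trials`` has columns: session, trial, phase, interval_ms,
    pos_short_deg, pos_long_deg, angle_deg, seed.
    """

    trials: pd.DataFrame
    seed: int

    @property
    def testing(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "testing"]

    @property
    def training(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "training"]

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionDesign":
        df = pd.read_csv(path)
        seed = int(df["seed"].iloc[0]) if len(df) else 0
        return cls(trials=df, seed=seed)


def build_session(
    seed: int,
    intervals: tuple[float, ...] | list[float] = DEFAULT_INTERVALS,
    session: int = 1,
) -> SessionDesign:
    """Build one session: 24 training trials + (#intervals x 20) testing trials.

    Training presents only the shortest and longest intervals, in random
    order.  Testing presents every (interval, pair) combination exactly
    once, in a seeded random permutation.  Which pair member plays the
    short-category target is randomised per trial.
    """
    intervals = tuple(float(v) for v in intervals)
    if not intervals:
        raise ValueError("interval list is empty")
    if len(set(intervals)) != len(intervals):
        raise ValueError("duplicate intervals in interval list")

    rng = np.random.default_rng(seed)
    pairs = enumerate_target_pairs()
    boundary = interval_statistics(intervals)["boundary"]

    rows = []
    extremes = (min(intervals), max(intervals))
    for _ in range(TRAINING_TRIALS):
        interval = extremes[rng.integers(2)]
        layout = pairs[rng.integers(len(pairs))]
        a, b = layout.pair
        if rng.integers(2):
            a, b = b, a
        rows.append(("training", interval, a, b, layout.separation))

    combos = [(iv, layout) for iv in intervals for layout in pairs]
    order = rng.permutation(len(combos))
    for idx in order:
        interval, layout = combos[idx]
        a, b = layout.pair
        if rng.integers(2):
            a, b = b, a
        rows.append(("testing", interval, a, b, layout.separation))

    df = pd.DataFrame(
        rows,
        columns=["phase", "interval_ms", "pos_short_deg", "pos_long_deg", "angle_deg"],
    )
    df.insert(0, "trial", np.arange(len(df)))
    df.insert(0, "session", session)
    df["seed"] = seed
    df["is_long"] = df["interval_ms"] > boundary
    return SessionDesign(trials=df, seed=seed)


def build_sessions(
    seed: int,
    n_sessions: int = 3,
    intervals: tuple[float, ...] | list[float] = DEFAULT_INTERVALS,
) -> SessionDesign:
    """Concatenate independent sessions (default 3, i.e. 480 testing trials)."""
    parts = []
    for s in range(n_sessions):
        sd = build_session(seed + s, intervals=intervals, session=s + 1)
        parts.append(sd.trials)
    df = pd.concat(parts, ignore_index=True)
    return SessionDesign(trials=df, seed=seed)


def interval_statistics(
    intervals: tuple[float, ...] | list[float] = DEFAULT_INTERVALS,
) -> dict:
    """Mean, extreme-midpoint and the configured boundary for an interval set.

    ``mean`` is the arithmetic mean, ``boundary`` the midpoint of the
    extremes, and ``calibration_boundary`` the published constant
    (CATEGORY_BOUNDARY_MS) that the model calibration targets when the
    default interval set is used.
    """
    if not len(intervals):
        raise ValueError("interval list is empty")
    arr = np.asarray(intervals, dtype=float)
    return {
        "mean": float(arr.mean()),
        "boundary": float((arr.min() + arr.max()) / 2.0),
        "calibration_boundary": CATEGORY_BOUNDARY_MS,
    }
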