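"""Psychometric fitting and model-vs-data comparison statistics.

The choice curve P(long | interval) is fitted with a maximum-likelihood
logistic (location/scale form, no lapse parameter).  From the fit we
report the point of subjective equality (PSE, the 50% point), the
difference threshold (half the 25%-75% spread, a sensitivity index) and
the constant error (PSE minus the true category boundary, a bias index).
Degenerate data -- all-identical responses, or a perfect step that
separates the classes -- are flagged rather than regularised; for a
perfect step the PSE falls back to linear interpolation of the raw
proportions and the threshold to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task_design import CATEGORY_BOUNDARY_MS

#: log(3): logit distance between the 25% and 75% points of a logistic.
_LOG3 = float(np.log(3.0))


@dataclass
class PsychometricFit:
    """Fitted logistic choice curve and its derived indices (ms units)."""

    pse_ms: float
    slope_per_ms: float
    difference_threshold_ms: float
    constant_error_ms: float
    deviance: float
    degenerate: bool
    degenerate_reason: str | None = None

    def predict(self, interval_ms) -> np.ndarray:
        """P(long) at the given intervals under the fitted curve."""
        x = np.asarray(interval_ms, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.slope_per_ms * (x - self.pse_ms)))


def _as_choice_table(data) -> pd.DataFrame:
    """Normalise input to columns interval_ms, n_long, n."""
    df = pd.DataFrame(data).copy()
    if "n_long" not in df.columns and "p_long" in df.columns:
        df["n_long"] = (df["p_long"] * df["n"]).round().astype(int)
    need = {"interval_ms", "n_long", "n"}
    if not need.issubset(df.columns):
        raise ValueError(f"choice table needs columns {sorted(need)}")
    df = df.groupby("interval_ms", as_index=False)[["n_long", "n"]].sum()
    if (df["n"] <= 0).any():
        raise ValueError("every interval needs at least one trial")
    return df.sort_values("interval_ms").reset_index(drop=True)


def _interpolated_pse(x: np.ndarray, p: np.ndarray) -> float:
    """PSE by linear interpolation of raw proportions at 0.5."""
    for i in range(len(x) - 1):
        lo, hi = p[i], p[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            return float(x[i] + (0.5 - lo) / (hi - lo) * (x[i + 1] - x[i]))
        if lo < 0.5 <= hi or hi < 0.5 <= lo:
            return float(0.5 * (x[i] + x[i + 1]))
    return float(np.nan)


def fit_psychometric(choice_table, boundary_ms: float = CATEGORY_BOUNDARY_MS
                     ) -> PsychometricFit:
    """Maximum-likelihood logistic fit of P(long) against interval.

    ``choice_table`` is a DataFrame (or dict of columns) with
    ``interval_ms``, ``n`` and either ``n_long`` or ``p_long``.  The fit
    is invariant to trial order and to scaling all counts by a common
    factor (the likelihood maximiser does not move).
    """
    df = _as_choice_table(choice_table)
    if len(df) < 2:
        raise ValueError("need at least two intervals")
    x = df["interval_ms"].to_numpy(dtype=float)
    n_long = df["n_long"].to_numpy(dtype=float)
    n = df["n"].to_numpy(dtype=float)
    p = n_long / n

    if np.all(n_long == 0) or np.all(n_long == n):
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               degenerate=True,
                               degenerate_reason="all responses identical")

    X = sm.add_constant(x)
    endog = np.column_stack([n_long, n - n_long])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=200)
            b0, b1 = float(res.params[0]), float(res.params[1])
            deviance = float(res.deviance)
            converged = bool(res.converged) and np.isfinite([b0, b1]).all()
        except Exception:
            converged = False

    # perfect separation: the MLE slope diverges; fall back to interpolation
    separated = converged and abs(b1) * (x.max() - x.min()) > 100.0
    if not converged or separated or (converged and b1 == 0.0):
        pse = _interpolated_pse(x, p)
        reason = "perfect separation (step data)" if (not converged or separated) \
            else "zero slope"
        thr = 0.0 if separated or not converged else np.nan
        return PsychometricFit(
            pse_ms=pse, slope_per_ms=np.inf if separated else 0.0,
            difference_threshold_ms=thr,
            constant_error_ms=pse - boundary_ms if np.isfinite(pse) else np.nan,
            deviance=np.nan, degenerate=True, degenerate_reason=reason)

    pse = -b0 / b1
    threshold = _LOG3 / abs(b1)
    degenerate = not (x.min() <= pse <= x.max()) and not (
        np.all(np.diff(p) >= 0) or np.all(np.diff(p) <= 0))
    return PsychometricFit(
        pse_ms=float(pse), slope_per_ms=b1,
        difference_threshold_ms=float(threshold),
        constant_error_ms=float(pse - boundary_ms),
        deviance=deviance, degenerate=degenerate,
        degenerate_reason="PSE outside tested range" if degenerate else None)


def error_rate_curve(summary) -> pd.DataFrame:
    """Percentage of categorization errors per interval.

    Accepts an ExperimentSummary (uses its psychometric table and the
    boundary implied by p_long) or a DataFrame with interval_ms and
    either error_rate or (p_long + is_long / boundary inference).
    """
    if hasattr(summary, "psychometric"):
        df = summary.psychometric.copy()
        boundary = CATEGORY_BOUNDARY_MS
        df["error_rate"] = np.where(df["interval_ms"] > boundary,
                                    1.0 - df["p_long"], df["p_long"])
    else:
        df = pd.DataFrame(summary).copy()
        if "error_rate" not in df.columns:
            boundary = CATEGORY_BOUNDARY_MS
            df["error_rate"] = np.where(df["interval_ms"] > boundary,
                                        1.0 - df["p_long"], df["p_long"])
    out = df[["interval_ms", "error_rate"]].copy()
    out["error_pct"] = 100.0 * out["error_rate"]
    return out.reset_index(drop=True)


def chi_square_compare(model_curve, reference_curve) -> dict:
    """Pearson chi-square of a reference curve against model expectations.

    ``statistic`` = sum (obs - exp)^2 / exp with df = bins - 1.  Used
    descriptively to score agreement between a simulated curve and a
    behavioural one.
    """
    exp = np.asarray(model_curve, dtype=float)
    obs = np.asarray(reference_curve, dtype=float)
    if exp.shape != obs.shape:
        raise ValueError("curves must have equal length")
    if np.any(exp <= 0):
        raise ValueError("expected values must be positive")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return {"statistic": stat, "df": int(exp.size - 1)}


def regression_compare(model_values, reference_values) -> dict:
    """OLS of reference on model with the overall F test.

    Returns F, p, slope, intercept and R^2; raises on fewer than three
    pairs or zero variance in the model values.
    """
    xm = np.asarray(model_values, dtype=float)
    yr = np.asarray(reference_values, dtype=float)
    if xm.shape != yr.shape or xm.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.allclose(xm, xm[0]):
        raise ValueError("zero variance in model values")
    res = sm.OLS(yr, sm.add_constant(xm)).fit()
    return {"F": float(res.fvalue), "p": float(res.f_pvalue),
            "slope": float(res.params[1]), "intercept": float(res.params[0]),
            "R2": float(res.rsquared)}
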