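"""Two-stage regression statistic for metacognitive choice-history bias.

Stage 1: within each previous-rating bin (trials preceded, at the given
lag, by a confidence rating r in {1, 2, 3, 4}), regress confidence on the
absolute stimulus orientation and keep the intercept — the confidence the
observer reports when the stimulus carries no evidence. Stage 2: regress
those intercepts on the previous rating r. A positive stage-2 slope means
high/low ratings are more likely after high/low ratings (repetition bias
of confidence), independently of the current evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RATING_VALUES = (1, 2, 3, 4)


class UndefinedSlopeError(ValueError):
    """Fewer than two previous-rating bins were usable for stage 2."""


@dataclass(frozen=True)
class ConfHistorySlope:
    lag: int
    slope: float
    intercepts: dict  # previous rating -> stage-1 intercept
    n_per_bin: dict  # previous rating -> trial count
    degraded_bins: tuple = ()  # bins with a single |orientation| value


@dataclass(frozen=True)
class SlopeTest:
    t: float
    p: float
    df: int
    flagged: bool = False  # zero-variance input


def _stage1_intercept(sub: pd.DataFrame, per_trial: bool) -> tuple[float, bool]:
    """OLS intercept of confidence on |orientation| for one bin.

    Default regresses the per-|orientation| mean confidence on |orientation|;
    ``per_trial`` uses raw trials instead. A bin with a single distinct
    |orientation| contributes its mean confidence, flagged as degraded.
    """
    abs_theta = sub["orientation"].abs()
    if per_trial:
        x, y = abs_theta.to_numpy(float), sub["confidence"].to_numpy(float)
    else:
        means = sub.groupby(abs_theta)["confidence"].mean()
        x, y = means.index.to_numpy(float), means.to_numpy(float)
    if len(np.unique(x)) < 2:
        return float(np.mean(y)), True
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), False


def conf_history_slope(
    trials: pd.DataFrame, lag: int = 1, per_trial: bool = False
) -> ConfHistorySlope:
    """Two-stage regression slope at a given trial lag (single participant)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if trials["participant"].nunique() > 1:
        raise ValueError("conf_history_slope operates on a single participant")
    prev = trials["confidence"].shift(lag)
    intercepts: dict[int, float] = {}
    n_per_bin: dict[int, int] = {}
    degraded = []
    for r in RATING_VALUES:
        sub = trials[prev == r]
        if len(sub) == 0:
            continue
        intercept, is_degraded = _stage1_intercept(sub, per_trial)
        intercepts[r] = intercept
        n_per_bin[r] = len(sub)
        if is_degraded:
            degraded.append(r)
    if len(intercepts) < 2:
        raise UndefinedSlopeError(f"only {len(intercepts)} usable previous-rating bins at lag {lag}")
    r_vals = np.array(sorted(intercepts), dtype=float)
    icpt = np.array([intercepts[int(r)] for r in r_vals])
    slope = float(np.polyfit(r_vals, icpt, 1)[0])
    return ConfHistorySlope(
        lag=lag,
        slope=slope,
        intercepts=intercepts,
        n_per_bin=n_per_bin,
        degraded_bins=tuple(degraded),
    )


def conf_history_profile(
    trials: pd.DataFrame, max_lag: int = 25, per_trial: bool = False
) -> pd.DataFrame:
    """Per-participant two-stage slopes for lags 1..max_lag (cohort table)."""
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        sub = sub.reset_index(drop=True)
        for lag in range(1, max_lag + 1):
            try:
                res = conf_history_slope(sub, lag=lag, per_trial=per_trial)
            except UndefinedSlopeError:
                continue
            rows.append({"participant": pid, "lag": lag, "slope": res.slope})
    return pd.DataFrame(rows)


def group_slope_test(slopes) -> SlopeTest:
    """One-sample t test of regression slopes against zero."""
    s = np.asarray(slopes, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 slopes")
    if np.std(s, ddof=1) == 0:
        mean = s.mean()
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        return SlopeTest(t=float(t), p=float(np.nan if mean == 0 else 0.0), df=len(s) - 1, flagged=True)
    t, p = stats.ttest_1samp(s, 0.0)
    return SlopeTest(t=float(t), p=float(p), df=len(s) - 1)
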