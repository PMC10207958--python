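"""Psychometric-function fitting and perceptual choice-history bias.

The psychometric function (PF) is a cumulative logistic with fixed lapse
and guess rates:

    P(right | x) = gamma + (1 - gamma - lambda) / (1 + exp(-slope * (x - threshold)))

where ``threshold`` is the 50% point in degrees and ``slope`` the logistic
steepness in degrees^-1 (both lapse parameters fixed at 0.02 by default).
Perceptual choice-history bias is the difference in PF threshold between
trials following a "left" vs a "right" response at a given lag: positive
values index attraction toward repeating the previous choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

_THRESHOLD_BOUNDS = (-40.0, 40.0)
_SLOPE_BOUNDS = (1e-4, 10.0)
_START_THRESHOLDS = np.linspace(-18.0, 18.0, 7)
_START_SLOPES = (0.05, 0.15, 0.4, 1.0, 3.0)


@dataclass(frozen=True)
class PsychometricFit:
    threshold: float
    slope: float
    lapse: float
    guess: float
    loglik: float
    n_trials: int
    converged: bool


@dataclass(frozen=True)
class HistoryBiasPF:
    """PF thresholds conditioned on the response ``lag`` trials back.

    ``bias`` = threshold_post_left - threshold_post_right; positive values
    mean the PF shifted toward the previous choice (repetition bias).
    """

    lag: int
    threshold_post_left: float
    threshold_post_right: float
    bias: float
    fit_post_left: PsychometricFit
    fit_post_right: PsychometricFit


class BinTooSmallError(ValueError):
    """A conditioned trial bin has too few orientation levels to fit."""


def pf_probability(x, threshold, slope, lapse=0.02, guess=0.02):
    """Cumulative-logistic PF evaluated at orientations ``x``."""
    return guess + (1.0 - guess - lapse) * expit(slope * (np.asarray(x, float) - threshold))


def _binned(orientations, responses):
    x = np.asarray(orientations, dtype=float)
    r = np.asarray(responses)
    if r.dtype.kind in "OU":
        r = (r == "right").astype(int)
    r = r.astype(int)
    levels, inverse = np.unique(x, return_inverse=True)
    n = np.bincount(inverse)
    k = np.bincount(inverse, weights=r)
    return levels, k, n


def fit_pf(orientations, responses, lapse: float = 0.02, guess: float = 0.02) -> PsychometricFit:
    """Maximum-likelihood cumulative-logistic PF fit.

    ``responses`` may be binary (1 = "right") or the strings "left"/"right".
    Multi-start bounded optimization over (threshold, slope); the
    ``converged`` flag is False for degenerate data (single response type)
    or solutions stuck at the parameter bounds.
    """
    levels, k, n = _binned(orientations, responses)
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct orientation levels")
    n_trials = int(n.sum())

    def nll(params):
        p = pf_probability(levels, params[0], params[1], lapse, guess)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()

    degenerate = k.sum() == 0 or k.sum() == n.sum()
    best = None
    for t0 in _START_THRESHOLDS:
        for s0 in _START_SLOPES:
            res = minimize(
                nll,
                x0=np.array([t0, s0]),
                method="L-BFGS-B",
                bounds=[_THRESHOLD_BOUNDS, _SLOPE_BOUNDS],
            )
            if best is None or res.fun < best.fun:
                best = res
    threshold, slope = best.x
    at_bound = (
        abs(threshold - _THRESHOLD_BOUNDS[0]) < 1e-6
        or abs(threshold - _THRESHOLD_BOUNDS[1]) < 1e-6
        or abs(slope - _SLOPE_BOUNDS[0]) < 1e-8
        or abs(slope - _SLOPE_BOUNDS[1]) < 1e-6
    )
    return PsychometricFit(
        threshold=float(threshold),
        slope=float(slope),
        lapse=lapse,
        guess=guess,
        loglik=float(-best.fun),
        n_trials=n_trials,
        converged=bool(best.success and not degenerate and not at_bound),
    )


def fit_pf_trials(trials: pd.DataFrame, lapse: float = 0.02, guess: float = 0.02) -> PsychometricFit:
    """Fit the PF to a single participant's trial table."""
    return fit_pf(trials["orientation"], trials["response"], lapse=lapse, guess=guess)


def pf_history_bias(trials: pd.DataFrame, lag: int = 1) -> HistoryBiasPF:
    """Threshold difference between post-left and post-right trials at ``lag``.

    Conditions each trial on the response exactly ``lag`` trials back
    (single-participant table; the first ``lag`` trials are dropped).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if trials["participant"].nunique() > 1:
        raise ValueError("pf_history_bias operates on a single participant")
    prev = trials["response"].shift(lag)
    usable = trials[prev.notna()]
    prev = prev[prev.notna()]
    fits = {}
    for side in ("left", "right"):
        sub = usable[prev == side]
        if sub["orientation"].nunique() < 2:
            raise BinTooSmallError(f"post-{side} bin has < 2 orientation levels at lag {lag}")
        fits[side] = fit_pf_trials(sub)
    return HistoryBiasPF(
        lag=lag,
        threshold_post_left=fits["left"].threshold,
        threshold_post_right=fits["right"].threshold,
        bias=fits["left"].threshold - fits["right"].threshold,
        fit_post_left=fits["left"],
        fit_post_right=fits["right"],
    )


def mad_outlier_flags(values, k: float = 3.0) -> np.ndarray:
    """Flag values more than ``k`` median absolute deviations from the median.

    Edge rule: when the MAD is exactly 0 (over half the values identical),
    everything not equal to the median is flagged.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values for MAD outlier detection")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return v != med
    return np.abs(v - med) > k * mad


def mad_exclusions(fits: pd.DataFrame, k: float = 3.0) -> pd.Series:
    """Participant exclusion mask from overall-PF threshold and slope.

    ``fits`` needs columns ``threshold`` and ``slope`` (one row per
    participant); a participant is excluded if flagged on either parameter.
    """
    return pd.Series(
        mad_outlier_flags(fits["threshold"], k) | mad_outlier_flags(fits["slope"], k),
        index=fits.index,
        name="excluded",
    )
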