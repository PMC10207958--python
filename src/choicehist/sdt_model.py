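"""Normative SDT confidence model and its simulation-based predictions.

On each simulated trial a decision variable dv is drawn from a Gaussian
with mean +d'/2 (one stimulus class suffices by symmetry) and unit SD, and
compared with the criterion c. Confidence is the probability of being
correct implied by the distance of dv from c,

    f(x) = (1 + erf(x / (sigma * sqrt(2)))) / 2,   confidence = f(|dv - c|),

so confidence is 0.5 at the criterion and grows monotonically with
distance. Averaging f over correct and error trials at several evidence
levels reproduces the canonical predictions: accuracy rises with evidence,
confidence rises with evidence on correct trials but *falls* on error
trials, confidence stays above 0.5 even with no evidence, and a high- vs
low-confidence split steepens the evidence-accuracy relationship. A
response-time proxy is the inversion of predicted confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf
from scipy.stats import norm

DEFAULT_D_LEVELS = (0.1, 1.58, 3.17)  # none / weak / strong evidence


@dataclass(frozen=True)
class ModelConfig:
    d_levels: tuple = DEFAULT_D_LEVELS
    criterion: float = 0.0
    sigma: float = 1.0
    n_sim: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if any(d < 0 for d in self.d_levels):
            raise ValueError("d_levels must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def predicted_confidence(dv, c: float = 0.0, sigma: float = 1.0):
    """Probability-correct read-out f(|dv - c|) of the distance from criterion."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.abs(np.asarray(dv, dtype=float) - c)
    return 0.5 * (1.0 + erf(x / (sigma * np.sqrt(2.0))))


def simulate_predictions(config: ModelConfig = ModelConfig()) -> pd.DataFrame:
    """Monte-Carlo prediction curves over the configured evidence levels.

    Returns one row per d' level with overall accuracy, accuracy within the
    high- and low-confidence halves (split at the pooled median predicted
    confidence), mean confidence for correct and error trials, and the
    response-time proxy (1 - confidence) for both. Cells with no trials
    (e.g. no errors at huge d') hold NaN.
    """
    rng = np.random.default_rng(config.seed)
    sims = []
    for d in config.d_levels:
        dv = rng.normal(d / 2.0, config.sigma, size=config.n_sim)
        correct = dv > config.criterion  # simulated class has mu > 0
        conf = predicted_confidence(dv, config.criterion, config.sigma)
        sims.append((d, correct, conf))
    pooled_median = float(np.median(np.concatenate([conf for _, _, conf in sims])))

    rows = []
    for d, correct, conf in sims:
        high = conf > pooled_median
        def _mean(mask, values=None):
            if mask.sum() == 0:
                return np.nan
            return float(values[mask].mean()) if values is not None else float(mask.mean())
        rows.append(
            {
                "d_prime": d,
                "accuracy": float(correct.mean()),
                "accuracy_high_conf": _mean(high, correct.astype(float)),
                "accuracy_low_conf": _mean(~high, correct.astype(float)),
                "confidence_correct": _mean(correct, conf),
                "confidence_error": _mean(~correct, conf),
                "rt_proxy_correct": 1.0 - _mean(correct, conf),
                "rt_proxy_error": 1.0 - _mean(~correct, conf),
                "n_correct": int(correct.sum()),
                "n_error": int((~correct).sum()),
            }
        )
    return pd.DataFrame(rows)


def theoretical_accuracy(d_prime: float, criterion: float = 0.0, sigma: float = 1.0) -> float:
    """Closed-form accuracy Phi((d'/2 - c)/sigma) for the simulated class."""
    return float(norm.cdf((d_prime / 2.0 - criterion) / sigma))
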