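"""Population prevalence of within-participant effects.

Given k of n participants individually significant at false-positive rate
alpha, and assuming within-participant power 1 for detectable effects, the
maximum-likelihood estimate of the population prevalence is

    gamma_hat = clip((k/n - alpha) / (1 - alpha), 0, 1)

with a percentile-bootstrap confidence interval obtained by resampling the
binary significance indicators with replacement. Because the bootstrap
distribution of gamma_hat is discrete (k* is binomial), the interval uses
the inverse-empirical-CDF quantile convention: lower bound from the largest
order statistic at or below the target probability mass ("lower"), upper
bound from the smallest at or above ("higher").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int
    alpha: float
    gamma_hat: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int


def prevalence_mle(k: int, n: int, alpha: float = 0.05) -> float:
    """MLE of population prevalence from k significant of n participants."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.clip((k / n - alpha) / (1.0 - alpha), 0.0, 1.0))


def prevalence_bootstrap_ci(
    indicators,
    alpha: float = 0.05,
    n_boot: int = 10_000,
    level: float = 95.0,
    seed: int = 0,
) -> PrevalenceEstimate:
    """Percentile-bootstrap interval for the prevalence MLE.

    ``indicators`` is a binary per-participant significance vector. Each
    bootstrap replicate resamples participants with replacement and
    recomputes the clipped MLE; the interval takes the (1 - level)/2 and
    (1 + level)/2 empirical quantiles.
    """
    ind = np.asarray(indicators, dtype=int)
    if ind.ndim != 1 or len(ind) < 2:
        raise ValueError("need at least 2 participant indicators")
    if not set(np.unique(ind)) <= {0, 1}:
        raise ValueError("indicators must be binary")
    n = len(ind)
    k = int(ind.sum())
    gamma = prevalence_mle(k, n, alpha)
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, n, size=(n_boot, n))
    k_star = ind[resamples].sum(axis=1)
    gamma_star = np.clip((k_star / n - alpha) / (1.0 - alpha), 0.0, 1.0)
    lo_q = (100.0 - level) / 2.0
    hi_q = 100.0 - lo_q
    ci_low = float(np.percentile(gamma_star, lo_q, method="lower"))
    ci_high = float(np.percentile(gamma_star, hi_q, method="higher"))
    return PrevalenceEstimate(
        k=k,
        n=n,
        alpha=alpha,
        gamma_hat=gamma,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        n_boot=n_boot,
        seed=seed,
    )
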