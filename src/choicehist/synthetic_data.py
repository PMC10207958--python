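"""Synthetic 2-AFC orientation-discrimination observers with history biases.

The generator emulates the design of a Gabor tilt-discrimination session —
13 signed orientations from -18 to +18 degrees in 3-degree steps, each shown
32 times in random order (416 trials) — and an equal-variance
signal-detection observer whose internal evidence is Gaussian around a mean
proportional to the stimulus tilt. Two generative "history knobs" inject the
biases the analysis stages are built to detect:

* ``hist_resp_weight`` attracts the type-1 decision criterion toward the
  previous response (positive = tendency to repeat the previous choice);
* ``hist_conf_weight`` shifts the type-2 (confidence) criteria with the
  previous rating (positive = a high previous rating makes high confidence
  easier to reach on the current trial).

Both are zero for a bias-free (null) observer. Confidence arises from the
distance of a (possibly extra-noisy) copy of the decision variable from the
current criterion, compared against three ordered criterion distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_LEVELS: tuple[float, ...] = tuple(float(v) for v in range(-18, 21, 3))
"""The 13 signed orientations (degrees): -18, -15, ..., 0, ..., +15, +18."""

DEFAULT_N_REPS = 32


class InvalidDesignError(ValueError):
    """Raised for unusable experiment designs (e.g. no orientation levels)."""


@dataclass(frozen=True)
class DesignSequence:
    """A randomized trial-order sequence of signed orientations."""

    orientations: np.ndarray
    levels: tuple[float, ...]
    n_reps: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.orientations)


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic signal-detection observer.

    Attributes
    ----------
    sensitivity : float
        Scaling k (degrees^-1) from signed orientation to the mean of the
        internal decision variable. The default 0.09 puts d' near 3.2 at the
        largest tilt (18 degrees), a realistic psychophysical range.
    noise_sd : float
        SD of the type-1 evidence noise (evidence units; the model's unit).
    base_criterion : float
        Type-1 criterion c0 with no history (0 = unbiased).
    hist_resp_weight : float
        Criterion attraction toward the previous response, in evidence
        units; positive values produce choice repetition.
    conf_criteria : tuple
        Three strictly increasing nonnegative criterion distances that cut
        |dv - c| into the four confidence ratings. Either one triple shared
        by both response sides, or a pair of triples (left side, right side).
    hist_conf_weight : float
        Shift of the criterion distances per unit of the centered previous
        rating (previous rating minus 2.5); positive values make high
        confidence more likely after high confidence.
    lapse_rate : float
        Probability that the type-1 response is replaced by a fair coin flip.
    conf_noise_sd : float
        SD of extra Gaussian noise added to the decision variable at the
        type-2 stage only; degrades metacognitive (but not perceptual)
        sensitivity, so meta-d' falls below d'.
    """

    sensitivity: float = 0.09
    noise_sd: float = 1.0
    base_criterion: float = 0.0
    hist_resp_weight: float = 0.0
    conf_criteria: tuple = (0.5, 1.0, 1.8)
    hist_conf_weight: float = 0.0
    lapse_rate: float = 0.02
    conf_noise_sd: float = 0.5

    def __post_init__(self):
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if self.conf_noise_sd < 0:
            raise ValueError("conf_noise_sd must be >= 0")
        c2 = np.asarray(self.conf_criteria, dtype=float)
        if c2.shape not in ((3,), (2, 3)):
            raise ValueError("conf_criteria must be 3 distances or a (2, 3) pair")
        sides = c2[None, :] if c2.ndim == 1 else c2
        if (sides < 0).any():
            raise ValueError("conf_criteria distances must be nonnegative")
        # non-decreasing (ties allowed: collapsed criteria yield degenerate
        # ratings, which downstream fits flag as unidentifiable)
        if not (np.diff(sides, axis=-1) >= 0).all():
            raise ValueError("conf_criteria distances must be non-decreasing")
        for name in ("sensitivity", "base_criterion", "hist_resp_weight", "hist_conf_weight"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def criteria_for(self, side: int) -> np.ndarray:
        """Criterion distances for a response side (-1 left, +1 right)."""
        c2 = np.asarray(self.conf_criteria, dtype=float)
        if c2.ndim == 1:
            return c2
        return c2[0] if side < 0 else c2[1]


def generate_design(
    n_reps: int = DEFAULT_N_REPS,
    levels=DEFAULT_LEVELS,
    seed: int = 0,
) -> DesignSequence:
    """Uniformly random permutation of ``n_reps`` repeats of each level.

    With the defaults this yields the canonical 13 x 32 = 416-trial session.
    """
    levels = tuple(float(v) for v in levels)
    if len(levels) == 0:
        raise InvalidDesignError("levels must be non-empty")
    if len(set(levels)) != len(levels):
        raise InvalidDesignError("levels must be distinct")
    if n_reps < 1:
        raise InvalidDesignError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    sequence = np.repeat(np.asarray(levels, dtype=float), n_reps)
    rng.shuffle(sequence)
    return DesignSequence(orientations=sequence, levels=levels, n_reps=n_reps, seed=seed)


def _rating_from_distance(distance: float, distances: np.ndarray) -> int:
    """Rating 1-4 from |dv' - c| against ordered criterion distances."""
    return 1 + int(np.sum(distance > distances))


def simulate_observer(
    design: DesignSequence,
    params: ObserverParams,
    seed: int,
    participant: str = "p01",
    emit_rt: bool = True,
) -> pd.DataFrame:
    """Simulate one observer over a design sequence.

    Per trial t: dv = k*theta + noise; the effective criterion is
    c_t = c0 - w_resp * r_{t-1} (r in {-1 left, +1 right}; trial 1 uses c0);
    the response is "right" iff dv > c_t (tie resolved as "right"); with
    probability ``lapse_rate`` the response is replaced by a fair coin flip.
    The rating compares |dv + type-2 noise - c_t| with the criterion
    distances shifted by the previous rating, floored at 0 and re-sorted.
    """
    rng = np.random.default_rng(seed)
    theta = design.orientations
    n = len(theta)
    dv = params.sensitivity * theta + rng.normal(0.0, params.noise_sd, size=n)
    t2_noise = (
        rng.normal(0.0, params.conf_noise_sd, size=n) if params.conf_noise_sd > 0 else np.zeros(n)
    )
    lapse_mask = rng.random(n) < params.lapse_rate
    lapse_flip = rng.random(n) < 0.5

    responses = np.empty(n, dtype=object)
    ratings = np.zeros(n, dtype=int)
    pred_conf = np.zeros(n)
    r_prev = 0  # no history on trial 1
    conf_prev: int | None = None
    for t in range(n):
        c_t = params.base_criterion - params.hist_resp_weight * r_prev
        r = 1 if dv[t] >= c_t else -1
        if lapse_mask[t]:
            r = 1 if lapse_flip[t] else -1
        distances = params.criteria_for(r).copy()
        if conf_prev is not None:
            distances = distances - params.hist_conf_weight * (conf_prev - 2.5)
        distances = np.sort(np.maximum(distances, 0.0))
        dist_t2 = abs(dv[t] + t2_noise[t] - c_t)
        rating = _rating_from_distance(dist_t2, distances)
        responses[t] = "right" if r > 0 else "left"
        ratings[t] = rating
        pred_conf[t] = norm.cdf(abs(dv[t] - c_t) / params.noise_sd)
        r_prev = r
        conf_prev = rating

    resp_sign = np.where(responses == "right", 1, -1)
    correct = np.where(theta == 0, np.nan, (np.sign(theta) == resp_sign).astype(float))
    table = pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(1, n + 1),
            "orientation": theta,
            "response": responses,
            "confidence": ratings,
            "correct": correct,
        }
    )
    if emit_rt:
        # monotone-decreasing transform of predicted confidence; qualitative only
        table["rt"] = np.maximum(0.2 + (1.0 - pred_conf) + rng.normal(0, 0.1, size=n), 0.05)
    return table


def simulate_ideal_confidence_observer(
    design: DesignSequence,
    sensitivity: float,
    noise_sd: float = 1.0,
    base_criterion: float = 0.0,
    conf_criteria=(0.5, 1.0, 1.8),
    seed: int = 0,
    participant: str = "p01",
) -> pd.DataFrame:
    """Observer whose ratings derive deterministically from the decision dv.

    No history weights, no lapses, no type-2 noise: confidence carries all
    the information in the decision variable, so fitted meta-d' should match
    d' (the metacognitively ideal case).
    """
    params = ObserverParams(
        sensitivity=sensitivity,
        noise_sd=noise_sd,
        base_criterion=base_criterion,
        hist_resp_weight=0.0,
        conf_criteria=conf_criteria,
        hist_conf_weight=0.0,
        lapse_rate=0.0,
        conf_noise_sd=0.0,
    )
    return simulate_observer(design, params, seed=seed, participant=participant, emit_rt=False)


def simulate_cohort(
    n_participants: int = 37,
    params: ObserverParams | None = None,
    n_reps: int = DEFAULT_N_REPS,
    levels=DEFAULT_LEVELS,
    seed: int = 0,
    heterogeneity: dict | None = None,
    emit_rt: bool = True,
) -> pd.DataFrame:
    """Simulate a cohort of observers, one randomized design each.

    ``heterogeneity`` maps ObserverParams field names to between-participant
    Gaussian SDs; per-participant values are drawn around the shared
    ``params`` (sensitivity truncated to stay positive). Participant ids are
    "p01", "p02", ... and all per-participant randomness derives from
    ``seed`` via a spawned seed sequence, so the output is reproducible.
    """
    params = params or ObserverParams()
    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(n_participants)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    tables = []
    width = max(2, len(str(n_participants)))
    for i, child in enumerate(child_seeds):
        p_params = params
        if heterogeneity:
            updates = {}
            for name, sd in heterogeneity.items():
                value = draw_rng.normal(getattr(params, name), sd)
                if name in ("sensitivity", "noise_sd"):
                    value = max(value, 1e-3)
                updates[name] = value
            p_params = replace(params, **updates)
        design_seed, sim_seed = np.random.default_rng(child).integers(0, 2**31 - 1, size=2)
        design = generate_design(n_reps=n_reps, levels=levels, seed=int(design_seed))
        tables.append(
            simulate_observer(
                design,
                p_params,
                seed=int(sim_seed),
                participant=f"p{i + 1:0{width}d}",
                emit_rt=emit_rt,
            )
        )
    return pd.concat(tables, ignore_index=True)
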