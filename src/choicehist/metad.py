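"""Type-1 and type-2 signal-detection fitting (d', c, meta-d', meta-c).

Equal-variance Gaussian SDT for a 2-AFC tilt discrimination with a K-point
confidence scale. Type-1 sensitivity and bias come from the hit and
false-alarm rates,

    d' = z(HR) - z(FAR),      c = -(z(HR) + z(FAR)) / 2,

and type-2 (metacognitive) sensitivity is fitted by maximum likelihood as
meta-d': the d' a metacognitively ideal observer with the same *relative*
type-1 criterion (c' = c / d', held fixed) would need to produce the
observed response-conditional rating counts. The 2(K-1) free type-2
criteria (meta-c) are response conditional and kept ordered. Derived
metrics: meta-d' - d' (efficiency difference), meta-d'/d' (efficiency
ratio) and the mean |meta-c - c| distance per response side (lower = more
liberal confidence).

The estimator is the classical maximum-likelihood fit; a Bayesian
single-subject backend could be slotted behind :func:`fit_metad` but is not
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

SDT_LEVELS = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0)

_META_D_BOUNDS = (-5.0, 5.0)
_INC_BOUNDS = (1e-4, 10.0)


class InsufficientDataError(ValueError):
    """A stimulus class has no (or too few) trials for SDT fitting."""


@dataclass(frozen=True)
class ResponseCountTable:
    """Response x rating counts for the two stimulus classes.

    ``counts_s1``/``counts_s2`` have length 2K, ordered: response "left"
    with confidence K..1, then response "right" with confidence 1..K.
    S1 = left tilt (negative orientation), S2 = right tilt. ``pad`` is the
    constant added to every cell (1/(2K) by default) to avoid empty cells.
    """

    K: int
    counts_s1: np.ndarray
    counts_s2: np.ndarray
    pad: float = 0.0

    def __post_init__(self):
        for name in ("counts_s1", "counts_s2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (2 * self.K,):
                raise ValueError(f"{name} must have length 2K = {2 * self.K}")
            if (arr < 0).any():
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        if self.counts_s1.sum() <= 0 or self.counts_s2.sum() <= 0:
            raise InsufficientDataError("each stimulus class needs positive total count")

    @property
    def raw_s1(self) -> np.ndarray:
        return self.counts_s1 - self.pad

    @property
    def raw_s2(self) -> np.ndarray:
        return self.counts_s2 - self.pad


@dataclass(frozen=True)
class MetaDFit:
    d_prime: float
    criterion: float
    meta_d: float
    meta_c: np.ndarray  # 2(K-1) fitted type-2 criteria, ascending, meta-model units
    m_diff: float
    m_ratio: float
    metac_dist_left: float  # mean |meta-c - t1c| over the K-1 "left" criteria
    metac_dist_right: float
    loglik_type2: float
    converged: bool
    unidentifiable: bool = False


def counts_from_trials(
    trials: pd.DataFrame, level: float, K: int = 4, pad: bool = True
) -> ResponseCountTable:
    """Tabulate response x rating counts at one absolute orientation level.

    0 degrees is rejected: with no veridical response there is no
    signal/noise assignment and the SDT model does not apply.
    """
    if level == 0:
        raise ValueError("SDT counts are undefined at 0 degrees (no veridical response)")
    sub = trials[trials["orientation"].abs() == level]
    pad_value = 1.0 / (2 * K) if pad else 0.0
    counts = {}
    for name, sign in (("s1", -1), ("s2", 1)):
        cls = sub[np.sign(sub["orientation"]) == sign]
        if len(cls) == 0:
            raise InsufficientDataError(f"no {name} (tilt sign {sign}) trials at {level} degrees")
        conf = cls["confidence"].to_numpy(int)
        is_left = (cls["response"] == "left").to_numpy()
        cells = np.where(is_left, K - conf, K - 1 + conf)
        counts[name] = np.bincount(cells, minlength=2 * K).astype(float) + pad_value
    return ResponseCountTable(K=K, counts_s1=counts["s1"], counts_s2=counts["s2"], pad=pad_value)


def fit_type1(counts: ResponseCountTable) -> tuple[float, float]:
    """(d', c) from the padded hit and false-alarm rates."""
    K = counts.K
    hr = counts.counts_s2[K:].sum() / counts.counts_s2.sum()
    far = counts.counts_s1[K:].sum() / counts.counts_s1.sum()
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return float(z_hr - z_far), float(-0.5 * (z_hr + z_far))


def cell_probabilities(
    meta_d: float, t1c: float, left_dists: np.ndarray, right_dists: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cell probabilities (length 2K, count-table order) for each stimulus.

    ``left_dists``/``right_dists`` are the K-1 positive distances of the
    type-2 criteria from the type-1 criterion ``t1c`` (cumulative, i.e.
    already ordered); evidence means sit at -/+ meta_d / 2.
    """
    left_dists = np.asarray(left_dists, dtype=float)
    right_dists = np.asarray(right_dists, dtype=float)
    bounds = np.concatenate(
        ([-np.inf], (t1c - left_dists)[::-1], [t1c], t1c + right_dists, [np.inf])
    )
    out = []
    for mu in (-meta_d / 2.0, meta_d / 2.0):
        out.append(np.diff(norm.cdf(bounds - mu)))
    return out[0], out[1]


def _type2_nll(x: np.ndarray, obs: np.ndarray, K: int, c_prime: float) -> float:
    meta_d = x[0]
    left = np.cumsum(x[1:K])
    right = np.cumsum(x[K : 2 * K - 1])
    t1c = c_prime * meta_d
    inner = np.concatenate(((t1c - left)[::-1], [t1c], t1c + right))  # 2K-1 boundaries
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    cdf = ndtr(inner[None, :] - mus[:, None])  # (stimulus, boundary)
    cells = np.diff(np.concatenate((np.zeros((2, 1)), cdf, np.ones((2, 1))), axis=1), axis=1)
    p_left = cdf[:, K - 1 : K]
    p_resp = np.concatenate((np.repeat(p_left, K, 1), np.repeat(1.0 - p_left, K, 1)), axis=1)
    cond = np.clip(cells / np.clip(p_resp, 1e-12, None), 1e-12, 1.0)
    return -float((obs * np.log(cond)).sum())


def fit_metad(counts: ResponseCountTable) -> MetaDFit:
    """Maximum-likelihood meta-d' with response-conditional type-2 criteria.

    The type-1 relative criterion c' = c / d' is held at its observed value
    while meta-d' and the 2(K-1) criterion increments are free (ordered by
    construction). Multi-start bounded optimization; ``converged`` is
    honest, and single-rating data are flagged unidentifiable.
    """
    K = counts.K
    d_prime, criterion = fit_type1(counts)
    raw_ratings = np.zeros(K)
    for vec in (counts.raw_s1, counts.raw_s2):
        raw_ratings += vec[:K][::-1] + vec[K:]
    if np.count_nonzero(raw_ratings > 1e-9) < 2:
        return MetaDFit(
            d_prime=d_prime,
            criterion=criterion,
            meta_d=np.nan,
            meta_c=np.full(2 * (K - 1), np.nan),
            m_diff=np.nan,
            m_ratio=np.nan,
            metac_dist_left=np.nan,
            metac_dist_right=np.nan,
            loglik_type2=np.nan,
            converged=False,
            unidentifiable=True,
        )
    c_prime = criterion / d_prime if abs(d_prime) > 1e-9 else 0.0

    best = None
    obs = np.stack((counts.counts_s1, counts.counts_s2))
    md_starts = {float(np.clip(d_prime, *_META_D_BOUNDS)), float(np.clip(0.4 * d_prime, *_META_D_BOUNDS))}
    for md0 in md_starts:
        for inc0 in (0.4, 0.15):
            x0 = np.concatenate(([md0], np.full(2 * (K - 1), inc0)))
            res = minimize(
                _type2_nll,
                x0,
                args=(obs, K, c_prime),
                method="L-BFGS-B",
                bounds=[_META_D_BOUNDS] + [_INC_BOUNDS] * (2 * (K - 1)),
            )
            if best is None or res.fun < best.fun:
                best = res
    meta_d = float(best.x[0])
    left = np.cumsum(best.x[1:K])
    right = np.cumsum(best.x[K : 2 * K - 1])
    t1c_meta = c_prime * meta_d
    meta_c = np.concatenate(((t1c_meta - left)[::-1], t1c_meta + right))
    at_bound = abs(abs(meta_d) - _META_D_BOUNDS[1]) < 1e-6
    return MetaDFit(
        d_prime=d_prime,
        criterion=criterion,
        meta_d=meta_d,
        meta_c=meta_c,
        m_diff=meta_d - d_prime,
        m_ratio=meta_d / d_prime if abs(d_prime) > 1e-9 else np.nan,
        metac_dist_left=float(left.mean()),
        metac_dist_right=float(right.mean()),
        loglik_type2=float(-best.fun),
        converged=bool(best.success and not at_bound),
    )


def _bin_masks(trials: pd.DataFrame, binner: str, confidence_cut: int | None):
    prev_resp = trials["response"].shift(1)
    if binner == "prev-response":
        return {"post-left": prev_resp == "left", "post-right": prev_resp == "right"}
    if binner == "prev-confidence":
        if confidence_cut is None:
            raise ValueError("prev-confidence binning needs a confidence_cut (see pipeline.split_confidence_bins)")
        prev_conf = trials["confidence"].shift(1)
        return {
            "post-low": prev_conf.notna() & (prev_conf <= confidence_cut),
            "post-high": prev_conf > confidence_cut,
        }
    if binner == "repetition":
        same = trials["response"] == prev_resp
        return {"repetition": prev_resp.notna() & same, "alternation": prev_resp.notna() & ~same}
    raise ValueError(f"unknown binner {binner!r}")


def binned_sdt_analysis(
    trials: pd.DataFrame,
    binner: str,
    levels=SDT_LEVELS,
    K: int = 4,
    min_trials: int = 10,
    confidence_cut: int | None = None,
) -> pd.DataFrame:
    """Per-bin, per-level SDT parameters for one participant.

    ``binner`` is one of "prev-response", "prev-confidence", "repetition";
    binning always conditions on the immediately preceding trial (lag 1).
    Bins with fewer than ``min_trials`` raw trials in either stimulus class
    at a level are dropped (row retained with ``dropped=True``).
    """
    if trials["participant"].nunique() > 1:
        raise ValueError("binned_sdt_analysis operates on a single participant")
    trials = trials.reset_index(drop=True)
    rows = []
    for bin_name, mask in _bin_masks(trials, binner, confidence_cut).items():
        sub = trials[mask]
        for level in levels:
            row = {"bin": bin_name, "level": level, "dropped": False}
            try:
                counts = counts_from_trials(sub, level, K=K)
            except InsufficientDataError:
                row["dropped"] = True
                rows.append(row)
                continue
            n_s1, n_s2 = counts.raw_s1.sum(), counts.raw_s2.sum()
            row["n_s1"], row["n_s2"] = n_s1, n_s2
            if n_s1 < min_trials or n_s2 < min_trials:
                row["dropped"] = True
                rows.append(row)
                continue
            fit = fit_metad(counts)
            row.update(
                d_prime=fit.d_prime,
                c=fit.criterion,
                meta_d=fit.meta_d,
                m_diff=fit.m_diff,
                m_ratio=fit.m_ratio,
                metac_dist_left=fit.metac_dist_left,
                metac_dist_right=fit.metac_dist_right,
                converged=fit.converged,
            )
            rows.append(row)
    return pd.DataFrame(rows)
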