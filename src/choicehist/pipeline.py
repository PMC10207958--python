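"""Cohort-level orchestration of the full choice-history analysis.

Order of stages: outlier exclusion (3-MAD rule on overall PF threshold and
slope) -> perceptual history bias (PF threshold differences, lags 1-3) ->
metacognitive history bias (two-stage confidence regression, lags to 25) ->
mutual-information suite with permutation inference and population
prevalence -> binned meta-d' analyses (three binners x six evidence levels)
-> group statistics (paired t tests and 2 x 6 repeated-measures ANOVAs).
Every group summary is traceable to per-participant rows, and all outputs
are plain delimited text plus one JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from . import __version__
from . import confidence_regression as creg
from . import metad as md
from . import mutual_information as mi
from . import prevalence as prev
from . import psychometric as pf
from .io import read_trials, validate_trials

logger = logging.getLogger("choicehist.pipeline")

BINNERS = ("prev-response", "prev-confidence", "repetition")
SDT_PARAMS = ("d_prime", "meta_d", "m_diff", "c", "metac_dist_left", "metac_dist_right")


class NoSplitError(ValueError):
    """A participant used a single confidence rating; no high/low split exists."""


class ImbalancedDesignError(ValueError):
    """Missing cells in a repeated-measures design."""


@dataclass(frozen=True)
class ConfidenceSplit:
    """Participant-specific high/low confidence cut.

    ``cut`` is the rating value such that low = ratings <= cut and
    high = ratings > cut, chosen (over cuts 1, 2, 3) to minimize the
    difference in the number of trials *following* low vs high ratings;
    ties break toward the larger low bin.
    """

    participant: str
    cut: int
    n_low: int
    n_high: int


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    df: int
    flagged: bool = False


def split_confidence_bins(trials: pd.DataFrame) -> ConfidenceSplit:
    """Balanced high/low split from post-rating trial counts (one participant)."""
    pid = trials["participant"].iloc[0]
    prev = trials["confidence"].shift(1).dropna()
    if trials["confidence"].nunique() < 2:
        raise NoSplitError(f"participant {pid!r} used a single rating value")
    counts = prev.value_counts().reindex([1, 2, 3, 4], fill_value=0)
    best = None
    for cut in (1, 2, 3):
        n_low = int(counts.loc[:cut].sum())
        n_high = int(counts.loc[cut + 1 :].sum())
        diff = abs(n_low - n_high)
        # ties break toward the larger low bin, i.e. the larger cut wins
        if best is None or diff < best[0] or (diff == best[0] and n_low > best[2]):
            best = (diff, cut, n_low, n_high)
    _, cut, n_low, n_high = best
    return ConfidenceSplit(participant=str(pid), cut=cut, n_low=n_low, n_high=n_high)


def classify_repetition(trials: pd.DataFrame) -> pd.Series:
    """Per-trial 'repetition'/'alternation' labels (first trial NaN)."""
    prev = trials.groupby("participant", sort=False)["response"].shift(1)
    labels = np.where(trials["response"] == prev, "repetition", "alternation").astype(object)
    labels[prev.isna().to_numpy()] = np.nan
    return pd.Series(labels, index=trials.index, name="hysteresis")


def paired_t(a, b) -> TestResult:
    """Paired (repeated-measures) t test; zero-variance differences flagged."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        m = d.mean()
        t = 0.0 if m == 0 else np.inf * np.sign(m)
        return TestResult(t=float(t), p=float(np.nan if m == 0 else 0.0), df=len(d) - 1, flagged=True)
    t, p = stats.ttest_rel(a, b)
    return TestResult(t=float(t), p=float(p), df=len(d) - 1)


def rm_anova_2xJ(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    within: tuple[str, str] = ("bin", "level"),
) -> dict:
    """Two-way fully within-subject ANOVA (classical SS partition).

    ``data`` is long-format with one observation per subject x cell of the
    complete 2 x J design. Returns F, dfs and p for both main effects and
    the interaction. Zero error variance yields non-finite F, flagged.
    """
    f1, f2 = within
    cells = data.groupby([subject, f1, f2], observed=True).size()
    if (cells != 1).any():
        raise ImbalancedDesignError("design must have exactly one observation per subject x cell")
    n_cells = data[f1].nunique() * data[f2].nunique()
    per_subject = data.groupby(subject, observed=True).size()
    if (per_subject != n_cells).any():
        raise ImbalancedDesignError("every subject must contribute every cell")
    table = AnovaRM(data, depvar=dv, subject=subject, within=list(within)).fit().anova_table
    out = {}
    keys = {f1: "main_1", f2: "main_2", f"{f1}:{f2}": "interaction"}
    for row_name, key in keys.items():
        row = table.loc[row_name]
        F = float(row["F Value"])
        out[key] = {
            "F": F,
            "df_num": float(row["Num DF"]),
            "df_den": float(row["Den DF"]),
            "p": float(row["Pr > F"]),
            # degenerate designs (e.g. zero error variance) yield non-finite
            # or negative F from the SS partition; neither is interpretable
            "flagged": (not np.isfinite(F)) or F < 0,
        }
    return out


def filter_post_correct(trials: pd.DataFrame, lag: int = 1) -> pd.DataFrame:
    """Keep trials whose lag-1 predecessor was a correct response.

    Predecessors at 0 degrees have undefined correctness and never qualify;
    current-trial orientation is irrelevant.
    """
    prev_correct = trials.groupby("participant", sort=False)["correct"].shift(lag)
    return trials[prev_correct == 1.0]


@dataclass
class PipelineConfig:
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 10_000
    pf_lags: tuple = (1, 2, 3)
    max_conf_lag: int = 25
    binners: tuple = BINNERS
    levels: tuple = md.SDT_LEVELS
    min_trials: int = 10
    apply_exclusion: bool = True


@dataclass
class CohortResults:
    tables: dict
    summary: dict
    provenance: dict
    failures: list


def _group_sdt_anovas(binned: pd.DataFrame, binner: str) -> dict:
    """2 x 6 rm-ANOVAs per SDT parameter, complete participants only."""
    sub = binned[(binned["binner"] == binner) & (~binned["dropped"])]
    out = {}
    n_cells = sub["bin"].nunique() * sub["level"].nunique()
    complete = sub.groupby("participant").size()
    keep = complete[complete == n_cells].index
    sub = sub[sub["participant"].isin(keep)]
    out["n_complete_participants"] = int(len(keep))
    if len(keep) < 3:
        out["skipped"] = "fewer than 3 complete participants"
        return out
    for param in SDT_PARAMS:
        long = sub[["participant", "bin", "level", param]].rename(columns={param: "value"})
        try:
            out[param] = rm_anova_2xJ(long)
        except (ImbalancedDesignError, ValueError) as exc:
            out[param] = {"error": str(exc)}
    return out


def run_pipeline(
    trials: pd.DataFrame | str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> CohortResults:
    """Execute the full cohort analysis; optionally write tables to ``out_dir``.

    Stage failures are logged and recorded in ``failures`` (dependent stages
    are skipped), never raised, so partial results remain inspectable.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)
    else:
        validate_trials(trials)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}
    failures: list[str] = []

    # --- stage 1: overall PF fits and MAD exclusion -------------------------
    fits_rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        fit = pf.fit_pf_trials(sub)
        fits_rows.append(
            {
                "participant": pid,
                "threshold": fit.threshold,
                "slope": fit.slope,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    fits = pd.DataFrame(fits_rows).set_index("participant")
    excluded = pf.mad_exclusions(fits) if config.apply_exclusion else pd.Series(False, index=fits.index)
    fits["excluded"] = excluded
    tables["pf_fits"] = fits.reset_index()
    keep_ids = fits.index[~excluded]
    data = trials[trials["participant"].isin(keep_ids)]
    summary["n_participants"] = int(len(fits))
    summary["n_excluded"] = int(excluded.sum())
    logger.info("exclusion: %d of %d participants flagged", excluded.sum(), len(fits))

    # --- stage 2: perceptual history bias (PF thresholds by previous response)
    try:
        rows = []
        for pid, sub in data.groupby("participant", sort=True):
            sub = sub.reset_index(drop=True)
            for lag in config.pf_lags:
                try:
                    hb = pf.pf_history_bias(sub, lag=lag)
                except pf.BinTooSmallError as exc:
                    logger.warning("pf bias %s lag %d: %s", pid, lag, exc)
                    continue
                rows.append(
                    {
                        "participant": pid,
                        "lag": lag,
                        "threshold_post_left": hb.threshold_post_left,
                        "threshold_post_right": hb.threshold_post_right,
                        "bias": hb.bias,
                    }
                )
        pf_bias = pd.DataFrame(rows)
        tables["pf_history_bias"] = pf_bias
        summary["pf_history_bias"] = {}
        for lag in config.pf_lags:
            sub = pf_bias[pf_bias["lag"] == lag]
            if len(sub) >= 2:
                res = paired_t(sub["threshold_post_left"], sub["threshold_post_right"])
                summary["pf_history_bias"][str(lag)] = {
                    "mean_bias_deg": float(sub["bias"].mean()),
                    "t": res.t,
                    "p": res.p,
                    "df": res.df,
                }
    except Exception as exc:  # pragma: no cover - defensive
        logger.exception("perceptual history bias stage failed")
        failures.append(f"pf_history_bias: {exc}")

    # --- stage 3: metacognitive history bias (two-stage regression) ---------
    try:
        profile = creg.conf_history_profile(data, max_lag=config.max_conf_lag)
        tables["conf_history_slopes"] = profile
        summary["conf_history_bias"] = {}
        for lag, sub in profile.groupby("lag"):
            if len(sub) >= 2:
                res = creg.group_slope_test(sub["slope"])
                summary["conf_history_bias"][str(lag)] = {
                    "mean_slope": float(sub["slope"].mean()),
                    "t": res.t,
                    "p": res.p,
                    "df": res.df,
                }
    except Exception as exc:
        logger.exception("confidence regression stage failed")
        failures.append(f"conf_history_bias: {exc}")

    # --- stage 4: MI suite + population prevalence --------------------------
    try:
        mi_table = mi.mi_suite_cohort(data, n_perm=config.n_perm, seed=int(seeds[0] % 2**31))
        tables["mi_suite"] = mi_table
        summary["prevalence"] = {}
        for quantity, label in (("resp1_resp", "perceptual"), ("conf1_conf", "metacognitive")):
            ind = (
                mi_table[mi_table["quantity"] == quantity]
                .sort_values("participant")["significant"]
                .astype(int)
                .to_numpy()
            )
            est = prev.prevalence_bootstrap_ci(
                ind,
                alpha=config.alpha,
                n_boot=config.n_boot,
                seed=int(seeds[1] % 2**31),
            )
            summary["prevalence"][label] = {
                "k": est.k,
                "n": est.n,
                "gamma_hat": est.gamma_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
    except Exception as exc:
        logger.exception("MI / prevalence stage failed")
        failures.append(f"mi_prevalence: {exc}")

    # --- stage 5: binned meta-d' analyses -----------------------------------
    try:
        rows = []
        for pid, sub in data.groupby("participant", sort=True):
            sub = sub.reset_index(drop=True)
            cut = None
            if "prev-confidence" in config.binners:
                try:
                    cut = split_confidence_bins(sub).cut
                except NoSplitError:
                    logger.warning("participant %s: no confidence split", pid)
            for binner in config.binners:
                if binner == "prev-confidence" and cut is None:
                    continue
                res = md.binned_sdt_analysis(
                    sub,
                    binner,
                    levels=config.levels,
                    min_trials=config.min_trials,
                    confidence_cut=cut,
                )
                res.insert(0, "participant", pid)
                res.insert(1, "binner", binner)
                rows.append(res)
        binned = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        tables["sdt_binned"] = binned
        summary["sdt_anova"] = {
            binner: _group_sdt_anovas(binned, binner) for binner in config.binners
        }
    except Exception as exc:
        logger.exception("binned SDT stage failed")
        failures.append(f"sdt_binned: {exc}")

    provenance = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "excluded_participants": list(map(str, fits.index[excluded])),
        "failures": failures,
    }
    results = CohortResults(tables=tables, summary=summary, provenance=provenance, failures=failures)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"summary": summary, "provenance": provenance}, fh, indent=2, default=float)
        logger.info("wrote %d tables to %s", len(tables), out)
    return results
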