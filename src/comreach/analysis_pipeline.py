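"""Statistical analyses of trial tables (measured or simulated).

Implements the study's behavioral analyses: per-subject residual-error
baselines, uncorrected-fraction slopes (regression of residual error on
perturbation size), per-condition variability and score summaries,
counterfactual rescoring of baseline responses under alternative correction
strategies, the ideal-observer score benchmark, residual-error bias curves
versus target location, and data-versus-model slope agreement.

Group summaries are always computed subject-level first and reported as
mean +- SE between subjects.  High-uncertainty trials are pooled across
sides by mirroring left-target trials (sign flip of target position,
perturbation and residual error) onto right-target trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observer_core import ObserverParams, expected_score
from .task_synthetic import ScoreConfig, score as score_fn

__all__ = [
    "SlopeResult",
    "pool_sides",
    "baseline_subtract",
    "slope_regression",
    "subject_slopes",
    "condition_summaries",
    "hypothetical_rescoring",
    "ideal_observer_benchmark",
    "bias_curve",
    "slope_agreement",
]


@dataclass(frozen=True)
class SlopeResult:
    subject_id: str
    uncertainty: str  # 'low' | 'high'
    slope: float
    intercept: float
    n_trials: int


def _se(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def pool_sides(records: pd.DataFrame) -> pd.DataFrame:
    """Mirror high-left trials onto high-right and collapse to low/high.

    Flips the signs of target position, perturbation (level and draw),
    response and residual error for left-target trials, then labels trials
    with a two-level ``uncertainty`` factor.  Sign-symmetric analyses are
    invariant under this pooling; it matches the side-collapsed reporting of
    the behavioral summaries.
    """
    df = records.copy()
    left = df["uncertainty_class"] == "high-left"
    for col in ("s_true_cm", "b_cm", "perturbation_level", "r_cm", "delta_s_cm", "rho"):
        if col in df:
            df.loc[left, col] = -df.loc[left, col]
    df["uncertainty"] = np.where(df["uncertainty_class"] == "low", "low", "high")
    return df


def baseline_subtract(records: pd.DataFrame) -> pd.DataFrame:
    """Remove each subject's unperturbed-trial mean residual error.

    The baseline is computed per subject and per stimulus class from the
    zero-perturbation trials and subtracted from every trial of that class,
    *before* any side pooling -- so a constant response bias is removed
    exactly.  A constant shift per (subject, class) cannot change regression
    slopes on perturbation size.
    """
    key = "uncertainty_class" if "uncertainty_class" in records else "uncertainty"
    df = records.copy()
    out = []
    for (sid, unc), grp in df.groupby(["subject_id", key], sort=False):
        base_rows = grp[grp["perturbation_level"] == 0.0]
        if base_rows.empty:
            raise ValueError(
                f"subject {sid} has no unperturbed {unc} trials"
            )
        grp = grp.copy()
        grp["delta_s_cm"] = grp["delta_s_cm"] - base_rows["delta_s_cm"].mean()
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def slope_regression(
    records: pd.DataFrame, uncertainty: str, subject_id: str | None = None
) -> SlopeResult:
    """OLS of baseline-subtracted residual error on continuous perturbation.

    The slope is the fraction of the perturbation *not* corrected for
    (0 = full correction, 1 = no correction).  Left/right trials are pooled
    by mirroring before the regression.
    """
    df = records if "uncertainty" in records.columns else pool_sides(records)
    df = df[df["uncertainty"] == uncertainty]
    if subject_id is not None:
        df = df[df["subject_id"] == subject_id]
    b = df["b_cm"].to_numpy(float)
    if len(np.unique(np.round(b, 9))) < 2:
        raise ValueError("need >= 2 distinct perturbation values for a slope")
    y = df["delta_s_cm"].to_numpy(float)
    X = [np.ones(len(df)), b]
    # Side-specific intercept for the mirrored high class, so that the slope
    # is exactly invariant to any per-(subject, side) constant -- e.g. the
    # baseline means removed before pooling.
    sides = df["uncertainty_class"].to_numpy()
    if len(np.unique(sides)) > 1:
        X.insert(1, (sides == "high-left").astype(float))
    fit = sm.OLS(y, np.column_stack(X)).fit()
    sid = subject_id if subject_id is not None else str(df["subject_id"].iloc[0])
    return SlopeResult(
        subject_id=sid,
        uncertainty=uncertainty,
        slope=float(fit.params[-1]),
        intercept=float(fit.params[0]),
        n_trials=len(df),
    )


def subject_slopes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-uncertainty-level uncorrected-fraction slopes."""
    df = baseline_subtract(records)
    df = pool_sides(df)
    rows = []
    for sid, grp in df.groupby("subject_id", sort=True):
        for unc in ("low", "high"):
            res = slope_regression(grp, unc, subject_id=sid)
            rows.append(
                dict(
                    subject_id=sid, uncertainty=unc, slope=res.slope,
                    intercept=res.intercept, n_trials=res.n_trials,
                )
            )
    return pd.DataFrame(rows)


def condition_summaries(
    records: pd.DataFrame, score_cfg: ScoreConfig = ScoreConfig()
) -> dict:
    """Per-uncertainty-level variability, score and balance-rate summaries.

    Subject-level statistics (SD of residual error, mean score recomputed
    from the scoring rule on every trial, fraction of trials with a nonzero
    score i.e. the object balanced) aggregated as group mean +- SE.  Scores
    are also split by unperturbed versus all trials, since the two
    aggregations differ slightly in the presence of partial correction.
    """
    df = pool_sides(records)
    df = df.copy()
    df["score_all"] = score_fn(df["delta_s_cm"].to_numpy(float), score_cfg)
    per_subject = []
    for (sid, unc), grp in df.groupby(["subject_id", "uncertainty"], sort=True):
        unpert = grp[grp["perturbation_level"] == 0.0]
        per_subject.append(
            dict(
                subject_id=sid,
                uncertainty=unc,
                sd=float(grp["delta_s_cm"].std(ddof=1)),
                mean_score=float(grp["score_all"].mean()),
                mean_score_unperturbed=float(unpert["score_all"].mean()),
                balance_rate=float((grp["score_all"] >= 1).mean()),
            )
        )
    tab = pd.DataFrame(per_subject)
    group = (
        tab.groupby("uncertainty")
        .agg(
            sd_mean=("sd", "mean"),
            sd_se=("sd", _se),
            score_mean=("mean_score", "mean"),
            score_se=("mean_score", _se),
            score_unpert_mean=("mean_score_unperturbed", "mean"),
            score_unpert_se=("mean_score_unperturbed", _se),
            balance_mean=("balance_rate", "mean"),
            balance_se=("balance_rate", _se),
        )
        .reset_index()
    )
    return dict(per_subject=tab, group=group)


def hypothetical_rescoring(
    records: pd.DataFrame,
    strategy_bias_table: dict[str, dict[float, float]],
    score_cfg: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Rescore baseline responses under counterfactual correction strategies.

    For each strategy, the tabulated mean residual bias per absolute
    perturbation level (e.g. ``slope * level``) is added to every subject's
    unperturbed low-uncertainty residual errors and the trials are rescored.
    Returns group mean +- SE per (strategy, level), plus the actual baseline.
    """
    df = pool_sides(records)
    base = df[(df["uncertainty"] == "low") & (df["perturbation_level"] == 0.0)]
    if base.empty:
        raise ValueError("no unperturbed low-uncertainty baseline trials")
    rows = []
    for sid, grp in base.groupby("subject_id", sort=True):
        ds = grp["delta_s_cm"].to_numpy(float)
        rows.append(
            dict(strategy="baseline", level=0.0, subject_id=sid,
                 mean_score=float(score_fn(ds, score_cfg).mean()))
        )
        for strategy, biases in strategy_bias_table.items():
            for level, bias in biases.items():
                if bias is None or not np.isfinite(bias):
                    raise ValueError(f"missing bias for {strategy} at level {level}")
                rows.append(
                    dict(
                        strategy=strategy, level=float(level), subject_id=sid,
                        mean_score=float(score_fn(ds + bias, score_cfg).mean()),
                    )
                )
    tab = pd.DataFrame(rows)
    return (
        tab.groupby(["strategy", "level"])
        .agg(score_mean=("mean_score", "mean"), score_se=("mean_score", _se))
        .reset_index()
    )


def ideal_observer_benchmark(
    sigma_rhos,
    n_sim: int = 20000,
    rng: np.random.Generator | int = 0,
    n_boot: int = 1000,
) -> dict:
    """Score ceiling of ideal observers sharing the subjects' sensory noise.

    For each subject's ``sigma_rho``, simulates an observer with the
    veridical mapping (D = 2), no adjustment cost (alpha = 0) and no motor
    noise, and averages its score per uncertainty class.  The group spread
    is a bootstrap SD over subjects.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sigma_rhos = np.atleast_1d(np.asarray(sigma_rhos, float))
    per_subject = {"low": [], "high": []}
    for sr in sigma_rhos:
        params = ObserverParams(sigma_rho=float(sr), dim_d=2.0, alpha=0.0, sigma_motor=0.0)
        for klass in ("low", "high"):
            mean, _ = expected_score(params, klass, n_sim, rng)
            per_subject[klass].append(mean)
    out = {}
    for klass in ("low", "high"):
        vals = np.asarray(per_subject[klass])
        boot = np.empty(n_boot)
        for i in range(n_boot):
            boot[i] = vals[rng.integers(0, len(vals), len(vals))].mean()
        out[klass] = dict(
            mean=float(vals.mean()),
            boot_sd=float(boot.std(ddof=1)) if len(vals) > 1 else 0.0,
            per_subject=vals,
        )
    return out


def bias_curve(records: pd.DataFrame, n_bins: int = 9) -> pd.DataFrame:
    """Binned mean residual error versus target location per perturbation level.

    Bins are equal-width over the occupied range of true center-of-mass
    locations (presentation only -- they never feed any fit).  Empty bins are
    absent from the output, not reported as zero.
    """
    df = records.copy()
    s = df["s_true_cm"].to_numpy(float)
    edges = np.linspace(s.min(), s.max() + 1e-9, n_bins + 1)
    df["bin"] = np.digitize(s, edges) - 1
    rows = []
    for (level, bi), grp in df.groupby(["perturbation_level", "bin"], sort=True):
        if grp.empty:
            continue
        per_subj = grp.groupby("subject_id")["delta_s_cm"].mean()
        rows.append(
            dict(
                perturbation_level=float(level),
                bin_center=float(0.5 * (edges[bi] + edges[bi + 1])),
                bias_mean=float(per_subj.mean()),
                bias_se=_se(per_subj.to_numpy()),
                n_trials=len(grp),
            )
        )
    return pd.DataFrame(rows)


def slope_agreement(data_slopes, model_slopes) -> dict:
    """Agreement between measured and model-predicted slopes.

    The coefficient of determination is computed against the identity line
    (residuals are data minus model), so a constant model prediction scores
    at or below zero and perfect prediction scores 1.
    """
    y = np.asarray(data_slopes, float)
    x = np.asarray(model_slopes, float)
    if len(x) != len(y) or len(y) < 3:
        raise ValueError("need >= 3 paired slopes")
    ss_res = float(((y - x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return dict(pairs=pd.DataFrame(dict(model=x, data=y)), r_squared=float(r2))
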