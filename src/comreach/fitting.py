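"""Maximum-likelihood estimation of observer parameters.

Protocol: the sensory noise ``sigma_rho`` is estimated once per subject from
the training session (feedback trials, no perturbations, full correction
assumed, with ``D`` and ``sigma_motor`` as nuisance parameters), then held
fixed while the test session is fit over ``(D, alpha, 1/sigma_adj,
sigma_motor)``.  The per-trial likelihood marginalizes the unobserved
internal measurement by Gauss-Hermite quadrature; the two-stage decision
path is tabulated on a ``(rho_m, b)`` grid per parameter vector and
interpolated inside the quadrature to keep the fit tractable.

Optimization is derivative-free (Nelder-Mead) from Latin-hypercube starts;
the flat-adjustment-loss boundary ``sigma_adj -> inf`` is represented by the
inverse scale ``1/sigma_adj in [0, 2]`` so it is an interior-representable
fit, and a dedicated ``alpha = 0`` (no effort cost) submodel competes on
log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from ._engine import SQRT2, SQRTPI, DecisionCache, hermgauss
from .observer_core import (
    DEFAULT_GEOMETRY,
    GaussianMixture1D,
    ObserverParams,
    ResponseDistribution,
    TaskGeometry,
)
from .task_synthetic import SessionConfig, generate_session, simulate_responses

__all__ = [
    "FitResult",
    "TrainingFit",
    "trial_loglik",
    "session_loglik",
    "fit_training",
    "fit_test",
    "fit_cohort",
    "predict_slopes",
    "recover_parameters",
]

# Multi-start search boxes.  The test-session fit is parameterized as
# (D, log alpha, kappa, sigma_motor) with kappa = alpha / sigma_adj^2: the
# small-displacement curvature of the weighted adjustment loss.  kappa is the
# combination the data identify sharply, while the likelihood is nearly flat
# along (alpha, sigma_adj) at fixed kappa, so using kappa as an axis aligns
# that ridge with a coordinate and lets the simplex search traverse it.
# kappa = 0 encodes a flat adjustment loss (sigma_adj -> inf), making that
# boundary interior-representable.
TEST_BOUNDS = [(0.5, 4.0), (-3.0, 3.0), (0.0, 2.5), (0.1, 3.0)]
TRAIN_BOUNDS = [(0.01, 0.4), (0.5, 4.0), (0.05, 3.0)]  # sigma_rho, D, sigma_motor

#: 1/sigma_adj is capped here (sigma_adj >= 0.5 cm) inside the fit.
MAX_INV_SIGMA_ADJ = 2.0


@dataclass
class TrainingFit:
    sigma_rho: float
    dim_d: float
    sigma_motor: float
    loglik: float
    n_trials: int
    converged: bool
    boundary: list[str] = field(default_factory=list)
    n_restarts_used: int = 0


@dataclass
class FitResult:
    params: ObserverParams
    loglik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    fixed_fields: list[str] = field(default_factory=list)
    predicted_slopes: tuple[float, float] | None = None
    #: loss parameters pinned at a search bound (or the alpha=0 submodel won):
    #: alpha/sigma_adj are then reported but individually uninformative.
    loss_boundary: list[str] = field(default_factory=list)


def trial_loglik(
    r: float,
    rho: float,
    b: float,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    n_quad: int = 101,
) -> float:
    """Log marginal response likelihood of a single trial.

    The marginal over the internal measurement is evaluated by quadrature;
    requires ``sigma_motor > 0``.
    """
    if params.sigma_motor <= 0:
        raise ValueError("trial_loglik requires sigma_motor > 0")
    dist = ResponseDistribution(rho, b, params, geometry, prior=prior, n_quad=n_quad)
    out = float(dist.logpdf(r))
    if not np.isfinite(out):
        raise FloatingPointError(
            f"likelihood quadrature failed at r={r}, rho={rho}, b={b}, params={params}"
        )
    return out


def _build_cache(params, prior, geometry, rho, b, n_quad, step=0.1, n_rho=181, n_b=17):
    t, _ = hermgauss(n_quad)
    pad = SQRT2 * t[-1] * params.sigma_rho * 1.05
    rho_range = (float(rho.min()) - pad, float(rho.max()) + pad)
    b_values = None
    if np.any(b != 0.0):
        lo, hi = float(b.min()), float(b.max())
        b_values = np.linspace(lo - 0.05, hi + 0.05, n_b)
    return DecisionCache(
        params, prior, geometry.half_length, rho_range,
        n_rho=n_rho, b_values=b_values, step=step,
    )


def session_loglik(
    r: np.ndarray,
    rho: np.ndarray,
    b: np.ndarray,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    n_quad: int = 61,
    cache: DecisionCache | None = None,
) -> float:
    """Summed log-likelihood of a vector of trials under one parameter set."""
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    r = np.asarray(r, float)
    rho = np.asarray(rho, float)
    b = np.asarray(b, float)
    if cache is None:
        cache = _build_cache(params, prior, geometry, rho, b, n_quad)
    t, w = hermgauss(n_quad)
    nodes = rho[:, None] + SQRT2 * params.sigma_rho * t[None, :]
    s_star = cache.s_star(
        nodes.ravel(), np.repeat(b, n_quad)
    ).reshape(nodes.shape)
    var = params.sigma_motor**2
    d = r[:, None] - s_star
    dens = (
        (w / SQRTPI) * np.exp(-0.5 * d * d / var) / math.sqrt(2 * math.pi * var)
    ).sum(axis=1)
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def _lhs(bounds, n, seed):
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    u = sampler.random(n)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + u * (hi - lo)


def _initial_simplex(x0, bounds, frac=0.15):
    """Simplex with bound-scaled steps, reflected inward at the box edges.

    Nelder-Mead's default simplex scales steps with the coordinate value, so
    a start at 0 (e.g. log alpha = 0, or 1/sigma_adj = 0) gets an essentially
    degenerate simplex along that axis and never moves; absolute steps sized
    to the search box avoid that.
    """
    x0 = np.asarray(x0, float)
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i, (lo, hi) in enumerate(bounds):
        step = frac * (hi - lo)
        xi = x0[i] + step
        if xi > hi:
            xi = x0[i] - step
        simplex[i + 1, i] = xi
    return simplex


def _nm(neg_ll, x0, bounds, maxfev, xatol=1e-3, fatol=0.01):
    return optimize.minimize(
        neg_ll, x0, method="Nelder-Mead", bounds=bounds,
        options=dict(
            maxfev=maxfev, xatol=xatol, fatol=fatol,
            initial_simplex=_initial_simplex(x0, bounds),
        ),
    )


def _multistart(neg_ll, bounds, starts, n_polish, maxfev, extra_starts=()):
    """Probe LHS starts, polish the best few with Nelder-Mead.

    The best polished point is re-polished from a fresh (smaller) simplex,
    which lets Nelder-Mead escape the collapsed simplices it tends to end in
    on ridged likelihood surfaces.
    """
    probes = [(neg_ll(x), x) for x in starts]
    probes.sort(key=lambda t: t[0])
    best = None
    n_used = 0
    seeds = [x for _, x in probes[:n_polish]] + [np.asarray(x) for x in extra_starts]
    for x0 in seeds:
        res = _nm(neg_ll, x0, bounds, maxfev)
        n_used += 1
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        neg_ll, best.x, method="Nelder-Mead", bounds=bounds,
        options=dict(
            maxfev=maxfev, xatol=5e-4, fatol=0.005,
            initial_simplex=_initial_simplex(best.x, bounds, frac=0.04),
        ),
    )
    n_used += 1
    if res.fun < best.fun:
        best = res
    return best, n_used


def fit_training(
    records: pd.DataFrame,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    seed: int = 0,
    n_probe: int = 8,
    n_polish: int = 2,
    maxfev: int = 200,
    n_quad: int = 61,
) -> TrainingFit:
    """Estimate ``sigma_rho`` from a training session.

    Feedback trials carry no perturbation, so the adjustment cost is
    irrelevant (the adjusted optimum equals the preliminary one) and the
    model reduces to ``alpha = 0`` with ``(sigma_rho, D, sigma_motor)`` free.
    Estimates pinned at the search bounds are flagged, not silently returned.
    """
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    df = records[records["phase"] == "training"] if "phase" in records else records
    if len(df) < 50:
        raise ValueError(f"need >= 50 training trials, got {len(df)}")
    r = df["r_cm"].to_numpy(float)
    rho = df["rho"].to_numpy(float)
    b = np.zeros(len(df))

    def neg_ll(x):
        p = ObserverParams(
            sigma_rho=x[0], dim_d=x[1], alpha=0.0, sigma_motor=x[2]
        )
        return -session_loglik(r, rho, b, p, geometry, prior, n_quad=n_quad)

    starts = _lhs(TRAIN_BOUNDS, n_probe, seed)
    best, n_used = _multistart(
        neg_ll, TRAIN_BOUNDS, starts, n_polish, maxfev,
        extra_starts=[np.array([0.06, 2.0, 1.0])],
    )
    x = best.x
    boundary = [
        name
        for name, (lo, hi), v in zip(
            ["sigma_rho", "dim_d", "sigma_motor"], TRAIN_BOUNDS, x
        )
        if v - lo < 1e-3 * (hi - lo) or hi - v < 1e-3 * (hi - lo)
    ]
    return TrainingFit(
        sigma_rho=float(x[0]),
        dim_d=float(x[1]),
        sigma_motor=float(x[2]),
        loglik=-float(best.fun),
        n_trials=len(df),
        converged=bool(np.isfinite(best.fun)),
        boundary=boundary,
        n_restarts_used=n_used,
    )


def _params_from_x(x, sigma_rho):
    d, log_alpha, kappa, sig_m = x
    alpha = float(np.exp(log_alpha))
    inv = min(MAX_INV_SIGMA_ADJ, math.sqrt(kappa / alpha)) if kappa > 0 else 0.0
    return ObserverParams(
        sigma_rho=sigma_rho,
        dim_d=float(d),
        alpha=alpha,
        sigma_adj=math.inf if inv == 0.0 else 1.0 / inv,
        sigma_motor=float(sig_m),
    )


def fit_test(
    records: pd.DataFrame,
    sigma_rho: float,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    seed: int = 0,
    n_probe: int = 10,
    n_polish: int = 2,
    maxfev: int = 300,
    n_quad: int = 61,
    compute_slopes: bool = False,
    slope_rng: np.random.Generator | None = None,
) -> FitResult:
    """ML fit of the test session with ``sigma_rho`` fixed from training.

    Free parameters: ``(D, alpha, sigma_adj, sigma_motor)``, searched in the
    ridge-aligned ``(D, log alpha, kappa, sigma_motor)`` space (see
    :data:`TEST_BOUNDS`); an ``alpha = 0`` (full-correction) submodel is fit
    alongside and wins if its likelihood is higher.  ``sigma_motor`` is the
    residual response scale.  Because the likelihood is nearly flat along
    the ``(alpha, sigma_adj)`` ridge at fixed curvature, the individual loss
    parameters are weakly identified at session size; fits pinned at the
    ``alpha`` or ``kappa`` search bounds are flagged via
    ``FitResult.loss_boundary``.
    """
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    df = records[records["phase"] == "test"] if "phase" in records else records
    if len(df) < 100:
        raise ValueError(f"need >= 100 test trials, got {len(df)}")
    r = df["r_cm"].to_numpy(float)
    rho = df["rho"].to_numpy(float)
    b = df["b_cm"].to_numpy(float)

    def neg_ll(x):
        p = _params_from_x(x, sigma_rho)
        return -session_loglik(r, rho, b, p, geometry, prior, n_quad=n_quad)

    starts = _lhs(TEST_BOUNDS, n_probe, seed)
    best, n_used = _multistart(
        neg_ll, TEST_BOUNDS, starts, n_polish, maxfev,
        extra_starts=[np.array([2.0, 0.0, 0.5, 1.0])],
    )

    # alpha = 0 submodel: no adjustment cost at all.
    def neg_ll0(x2):
        p = ObserverParams(
            sigma_rho=sigma_rho, dim_d=x2[0], alpha=0.0, sigma_motor=x2[1]
        )
        return -session_loglik(r, rho, b, p, geometry, prior, n_quad=n_quad)

    res0 = _nm(
        neg_ll0, np.array([2.0, 1.0]), [TEST_BOUNDS[0], TEST_BOUNDS[3]], maxfev=150
    )
    n_used += 1
    loss_boundary = []
    if res0.fun < best.fun:
        params = ObserverParams(
            sigma_rho=sigma_rho, dim_d=float(res0.x[0]), alpha=0.0,
            sigma_motor=float(res0.x[1]),
        )
        loglik = -float(res0.fun)
        loss_boundary = ["alpha"]
    else:
        params = _params_from_x(best.x, sigma_rho)
        loglik = -float(best.fun)
        for name, i in (("alpha", 1), ("kappa", 2)):
            lo, hi = TEST_BOUNDS[i]
            v = best.x[i]
            if v - lo < 1e-3 * (hi - lo) or hi - v < 1e-3 * (hi - lo):
                loss_boundary.append(name)
    slopes = None
    if compute_slopes:
        rng = slope_rng if slope_rng is not None else np.random.default_rng(seed + 1)
        slopes = predict_slopes(params, geometry, rng=rng)
    return FitResult(
        params=params,
        loglik=loglik,
        n_trials=len(df),
        converged=bool(np.isfinite(loglik)),
        n_restarts_used=n_used,
        fixed_fields=["sigma_rho"],
        predicted_slopes=slopes,
        loss_boundary=loss_boundary,
    )


def predict_slopes(
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    n_sessions: int = 4,
    rng: np.random.Generator | int = 0,
    cfg: SessionConfig | None = None,
) -> tuple[float, float]:
    """Uncorrected-fraction pair (low, high) predicted by a parameter set.

    Simulates test sessions from the observer and applies the same
    baseline-subtracted residual-error regression as the data analysis.
    """
    from .analysis_pipeline import subject_slopes

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cfg = cfg if cfg is not None else SessionConfig(geometry=geometry)
    frames = []
    for _ in range(n_sessions):
        session = generate_session(rng, cfg, subject_id="model")
        frames.append(simulate_responses(session, params, rng, geometry=geometry))
    df = pd.concat(frames, ignore_index=True)
    df = df[df["phase"] == "test"]
    slopes = subject_slopes(df)
    lo = float(slopes.loc[slopes["uncertainty"] == "low", "slope"].iloc[0])
    hi = float(slopes.loc[slopes["uncertainty"] == "high", "slope"].iloc[0])
    return lo, hi


def fit_cohort(
    cohort: pd.DataFrame,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    seed: int = 0,
    compute_slopes: bool = False,
    **fit_kw,
) -> pd.DataFrame:
    """Training + test fits for every subject in a trial table.

    Returns one row per subject with the training ``sigma_rho`` estimate and
    the test-session parameter estimates.
    """
    rows = []
    for i, (sid, df) in enumerate(cohort.groupby("subject_id", sort=True)):
        tr = fit_training(df, geometry, prior, seed=seed + 1000 * i)
        te = fit_test(
            df, tr.sigma_rho, geometry, prior, seed=seed + 1000 * i + 7,
            compute_slopes=compute_slopes, **fit_kw,
        )
        p = te.params
        rows.append(
            dict(
                subject_id=sid,
                sigma_rho=tr.sigma_rho,
                sigma_rho_boundary=("sigma_rho" in tr.boundary),
                dim_d=p.dim_d,
                alpha=p.alpha,
                sigma_adj=p.sigma_adj,
                inv_sigma_adj=p.inv_sigma_adj,
                kappa=p.alpha * p.inv_sigma_adj**2,
                sigma_motor=p.sigma_motor,
                loss_boundary=bool(te.loss_boundary),
                loglik_train=tr.loglik,
                loglik_test=te.loglik,
                slope_low=te.predicted_slopes[0] if te.predicted_slopes else np.nan,
                slope_high=te.predicted_slopes[1] if te.predicted_slopes else np.nan,
            )
        )
    return pd.DataFrame(rows)


def recover_parameters(
    true_params: ObserverParams,
    n_subjects: int = 16,
    seed: int = 1,
    cfg: SessionConfig | None = None,
    compute_slopes: bool = False,
) -> dict:
    """Parameter-recovery harness: simulate a cohort at known parameters,
    refit it, and compare group-level estimates with the truth.

    Returns the per-subject estimate table plus, for each parameter, the
    group mean, its standard error, and whether the truth lies within two
    group-level SEs of the mean.
    """
    from .task_synthetic import simulate_cohort

    cfg = cfg if cfg is not None else SessionConfig()
    cohort = simulate_cohort(n_subjects, true_params, seed, cfg)
    est = fit_cohort(cohort, cfg.geometry, seed=seed + 99, compute_slopes=compute_slopes)
    truth = dict(
        sigma_rho=true_params.sigma_rho,
        dim_d=true_params.dim_d,
        alpha=true_params.alpha,
        sigma_adj=true_params.sigma_adj,
        kappa=true_params.alpha * true_params.inv_sigma_adj**2,
        sigma_motor=true_params.sigma_motor,
    )
    # Loss parameters (alpha, sigma_adj) are summarized over subjects whose
    # loss fit is interior -- the same convention as reporting them only for
    # subjects without a flat adjustment loss.  All other parameters are
    # summarized over the whole cohort.
    interior = ~est["loss_boundary"].to_numpy(bool)
    summary = {}
    for name, tv in truth.items():
        sel = interior if name in ("alpha", "sigma_adj") else np.ones(len(est), bool)
        vals = est.loc[sel, name].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            summary[name] = dict(truth=tv, mean=float("nan"), se=float("nan"),
                                 n=len(vals), within_2se=False)
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(len(vals)))
        summary[name] = dict(
            truth=tv, mean=mean, se=se, n=int(len(vals)),
            within_2se=bool(abs(mean - tv) <= 2 * se),
        )
    return dict(estimates=est, summary=summary, cohort=cohort)
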