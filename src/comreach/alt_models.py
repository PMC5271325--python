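"""Alternative observers used as controls for the effort-cost model.

Three variants probe which ingredients of the primary model are necessary
for uncertainty-dependent partial correction:

* ``quadratic_error`` -- quadratic error loss in place of the inverted
  Gaussian.  The expected quadratic loss is ``(s_hat - posterior mean)^2``
  plus a constant, so the optimum depends on the posterior only through its
  mean: correction cannot depend on posterior width and the predicted
  uncorrected fraction is identical in both uncertainty classes.
* ``power_adjustment`` -- adjustment cost ``alpha * |s_hat - r0|**gamma``
  instead of the inverted Gaussian.  Preserves uncertainty modulation and is
  empirically indistinguishable from the primary model on matched cohorts.
* ``miscalibrated`` -- no effort cost; the observer corrects fully toward
  its target but perceives the reappeared cursor's correction distance with
  a gain (and offset), leaving a residual proportional to the perturbation
  with the same proportion in both classes.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .observer_core import (
    DEFAULT_GEOMETRY,
    GaussianMixture1D,
    ObserverParams,
    TaskGeometry,
)
from .task_synthetic import ScoreConfig, score as score_fn

__all__ = [
    "AltModelSpec",
    "quadratic_adjusted_endpoint",
    "power_adjusted_endpoint",
    "miscalibrated_response",
    "simulate_variant_responses",
]

_VARIANTS = ("quadratic_error", "power_adjustment", "miscalibrated")


@dataclass(frozen=True)
class AltModelSpec:
    """Configuration of one alternative observer."""

    variant: str
    gamma: float = 2.0  # power_adjustment exponent
    gain: float = 1.0  # miscalibrated perceived-correction gain
    offset: float = 0.0  # miscalibrated perceived-position offset (cm)

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.variant == "power_adjustment" and not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not np.isfinite(self.gain) or not np.isfinite(self.offset):
            raise ValueError("calibration gain/offset must be finite")


def _rows(mix):
    return mix.weights[None, :], mix.means[None, :], mix.sds[None, :]


def quadratic_adjusted_endpoint(
    post_com: GaussianMixture1D,
    r0: float,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    step: float = 0.01,
) -> float:
    """Adjusted endpoint under a quadratic error loss.

    Minimizes ``E[(s_hat - s)^2] + alpha * L_adj(s_hat - r0)`` with the
    inverted-Gaussian adjustment loss; the posterior variance enters only as
    an additive constant, so the result is a function of the posterior mean
    and ``r0`` alone.
    """
    if not np.isfinite(r0):
        raise ValueError("r0 must be finite")
    Z, m, sd = _rows(post_com)
    if params.alpha == 0.0 or params.inv_sigma_adj == 0.0:
        return float((Z * m).sum())
    s, _ = _engine.optimize_endpoint(
        Z, m, sd, params.sigma_err, geometry.half_length,
        r0=np.array([r0]), alpha=params.alpha,
        inv_sigma_adj=params.inv_sigma_adj, kind="quad_err", step=step,
    )
    return float(s[0])


def power_adjusted_endpoint(
    post_com: GaussianMixture1D,
    r0: float,
    params: ObserverParams,
    gamma: float,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    step: float = 0.01,
) -> float:
    """Adjusted endpoint with adjustment cost ``alpha * |d|**gamma``.

    Same dense-grid optimizer contract as the primary adjusted endpoint.
    """
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    if not np.isfinite(r0):
        raise ValueError("r0 must be finite")
    Z, m, sd = _rows(post_com)
    if params.alpha == 0.0:
        from .observer_core import preliminary_endpoint

        return preliminary_endpoint(post_com, params.sigma_err, geometry, step=step)
    s, _ = _engine.optimize_endpoint(
        Z, m, sd, params.sigma_err, geometry.half_length,
        r0=np.array([r0]), alpha=params.alpha, kind="power", gamma=gamma, step=step,
    )
    return float(s[0])


def miscalibrated_response(
    s_pre: float, b: float, spec: AltModelSpec
) -> float:
    """Deterministic endpoint of the miscalibrated-cursor observer.

    The observer plans ``s_pre``, lands (visually) at ``r0 = s_pre + b``,
    and corrects fully toward its target -- but perceives the correction
    distance with the calibration ``gain`` and ``offset``, so the executed
    endpoint is ``s_pre + (1 - gain) * b - offset``.  The residual error is
    proportional to the perturbation with the same proportion in both
    uncertainty classes.
    """
    return s_pre + (1.0 - spec.gain) * b - spec.offset


def simulate_variant_responses(
    session: pd.DataFrame,
    params: ObserverParams,
    spec: AltModelSpec,
    rng: np.random.Generator,
    prior: GaussianMixture1D | None = None,
    geometry: TaskGeometry | None = None,
    score_cfg: ScoreConfig = ScoreConfig(),
    step: float = 0.01,
) -> pd.DataFrame:
    """Simulate a session under one of the alternative observers.

    Mirrors the primary simulator: draw the internal measurement, compute
    the preliminary endpoint, apply the perturbation, then the variant's
    adjustment rule, and add motor noise.
    """
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    geometry = geometry if geometry is not None else DEFAULT_GEOMETRY
    out = session.copy()
    rho = out["rho"].to_numpy(float)
    b = out["b_cm"].to_numpy(float)
    rho_m = rho + params.sigma_rho * rng.standard_normal(len(out))
    Z, mu, sdr = _engine.posterior_components(
        rho_m, prior.weights, prior.means, prior.sds, params.sigma_rho
    )
    m, sdc = _engine.moment_map(mu, sdr, params.dim_d, geometry.half_length)
    if spec.variant == "miscalibrated":
        s_pre, _ = _engine.optimize_endpoint(
            Z, m, sdc, params.sigma_err, geometry.half_length, kind="pre", step=step
        )
        r0 = s_pre + b
        s_star = s_pre + (1.0 - spec.gain) * b - spec.offset
    else:
        kind = "quad_err" if spec.variant == "quadratic_error" else "power"
        s_pre, r0, s_star = _engine.decision_path(
            rho_m, b, Z, m, sdc, params.sigma_err,
            params.alpha, params.inv_sigma_adj, geometry.half_length,
            kind=kind, gamma=spec.gamma, step=step,
        )
    r = s_star + params.sigma_motor * rng.standard_normal(len(out))
    out["r_cm"] = r
    out["delta_s_cm"] = r - out["s_true_cm"].to_numpy(float)
    sc = score_fn(out["delta_s_cm"].to_numpy(float), score_cfg)
    fb = out["feedback"].to_numpy(bool)
    out["score"] = pd.array(
        [int(s) if f else pd.NA for s, f in zip(sc, fb)], dtype="Int64"
    )
    out["rho_m"] = rho_m
    out["s_pre_cm"] = s_pre
    out["r0_cm"] = r0
    out["s_star_cm"] = s_star
    return out
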