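"""Bayesian observer for the center-of-mass reaching task.

The observer watches a two-disk dumbbell whose disks sit ``bar_length`` cm
apart, receives a noisy internal measurement of the log radius ratio
``rho = log(r2 / r1)``, combines it with the (trimodal) experimental prior,
maps the inferred ratio onto a center-of-mass position via a power-law
mass model (masses ~ radius**D), and then picks a reach endpoint in two
stages:

1. a *preliminary* endpoint that minimizes the expected inverted-Gaussian
   error loss under the posterior;
2. after the cursor reappears displaced by a covert perturbation ``b``, an
   *adjusted* endpoint that trades the same error loss against an effort
   (adjustment) cost ``alpha * L_adj(r - r0)``, an inverted Gaussian of
   length scale ``sigma_adj`` centered on the pre-adjustment position
   ``r0 = s*_pre + b``.

Gaussian motor noise of SD ``sigma_motor`` is added to the final choice.
All positions are in cm relative to the bar midpoint (positive toward the
right disk); log-ratios are in natural-log units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _engine
from ._engine import SQRTPI, SQRT2, hermgauss

__all__ = [
    "SCORE_SIGMA",
    "TaskGeometry",
    "ObserverParams",
    "GaussianMixture1D",
    "DecisionOutcome",
    "ResponseDistribution",
    "com_map",
    "posterior_rho",
    "posterior_com",
    "preliminary_endpoint",
    "adjusted_endpoint",
    "decide_trial",
    "response_distribution",
    "expected_score",
    "gaussian_score_mean",
]

#: Length scale of the scoring function, in cm.  Fixed by requiring the
#: rounded score 10*exp(-ds^2 / (2 sigma^2)) to be 10 at ds = 0 and to stay
#: nonzero exactly up to |ds| = 1 cm: 10*exp(-1/(2 sigma^2)) = 1/2.
SCORE_SIGMA = 1.0 / math.sqrt(2.0 * math.log(20.0))


@dataclass(frozen=True)
class TaskGeometry:
    """Geometry of the dumbbell: disks at +-bar_length/2 on the x axis."""

    bar_length: float = 24.0

    def __post_init__(self):
        if self.bar_length <= 0:
            raise ValueError("bar_length must be positive")

    @property
    def half_length(self) -> float:
        return self.bar_length / 2.0


DEFAULT_GEOMETRY = TaskGeometry()


@dataclass(frozen=True)
class ObserverParams:
    """Observer parameter vector theta = (sigma_rho, D, alpha, sigma_adj, sigma_motor).

    ``sigma_err`` is the error-loss length scale, tied to the score length
    scale of the task.  ``sigma_adj = inf`` encodes a flat adjustment loss
    (equivalent to no adjustment cost).
    """

    sigma_rho: float
    dim_d: float = 2.0
    alpha: float = 0.0
    sigma_adj: float = math.inf
    sigma_motor: float = 0.0
    sigma_err: float = SCORE_SIGMA

    def __post_init__(self):
        if not self.sigma_rho > 0:
            raise ValueError("sigma_rho must be > 0")
        if not self.dim_d > 0:
            raise ValueError("dim_d must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.sigma_adj > 0:
            raise ValueError("sigma_adj must be > 0 (inf allowed)")
        if self.sigma_motor < 0:
            raise ValueError("sigma_motor must be >= 0")
        if not self.sigma_err > 0:
            raise ValueError("sigma_err must be > 0")

    @property
    def inv_sigma_adj(self) -> float:
        """Inverse adjustment length scale; 0 encodes sigma_adj = inf."""
        return 0.0 if math.isinf(self.sigma_adj) else 1.0 / self.sigma_adj

    def replace(self, **kw) -> "ObserverParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class GaussianMixture1D:
    """1-D Gaussian mixture; components with sd 0 are delta functions.

    ``space`` tags whether means/sds live in log-ratio units ('rho') or in
    cm along the bar ('com').
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    space: str = "rho"

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        m = np.atleast_1d(np.asarray(self.means, dtype=float))
        s = np.atleast_1d(np.asarray(self.sds, dtype=float))
        if not (len(w) == len(m) == len(s)):
            raise ValueError("weights, means, sds must have equal length")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        if (s < 0).any():
            raise ValueError("sds must be nonnegative")
        if self.space not in ("rho", "com"):
            raise ValueError("space must be 'rho' or 'com'")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @classmethod
    def ratio_prior(cls) -> "GaussianMixture1D":
        """The experimental prior over log radius ratios.

        Equal-weight mixture of Gaussians at -log 1.5, 0, +log 1.5 with SDs
        0.1, 0, 0.1 (the central component is the equal-disk delta).
        """
        L = math.log(1.5)
        return cls(
            weights=np.array([1 / 3, 1 / 3, 1 / 3]),
            means=np.array([-L, 0.0, L]),
            sds=np.array([0.1, 0.0, 0.1]),
            space="rho",
        )

    def pdf(self, x):
        """Mixture density; delta components contribute nothing off-atom."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(np.shape(x))
        for w, m, s in zip(self.weights, self.means, self.sds):
            if s > 0:
                out = out + w * np.exp(_engine.norm_logpdf(x, m, s**2))
        return out

    @property
    def mean(self) -> float:
        return float((self.weights * self.means).sum())


@dataclass(frozen=True)
class DecisionOutcome:
    """Intermediate quantities of one simulated decision."""

    rho_m: float
    s_pre: float
    r0: float
    s_star: float
    r: float
    b: float = 0.0


def com_map(rho, dim_d: float, geometry: TaskGeometry = DEFAULT_GEOMETRY):
    """Map a log radius ratio to the center-of-mass position (cm).

    With masses proportional to radius**D at +-l/2, the balance point is
    ``(l/2) * tanh(D * rho / 2)``: odd and strictly increasing in rho, and
    bounded by the disk positions.
    """
    if not dim_d > 0:
        raise ValueError("dim_d must be > 0")
    out = _engine.com_map(rho, dim_d, geometry.half_length)
    return float(out) if np.isscalar(rho) else out


def posterior_rho(
    rho_m: float, prior: GaussianMixture1D, sigma_rho: float
) -> GaussianMixture1D:
    """Posterior over the log ratio after measuring ``rho_m``.

    Per-component conjugate Gaussian update of the mixture prior; component
    weights are proportional to ``prior weight x N(rho_m | prior mean,
    sigma_rho^2 + prior sd^2)``, renormalized.
    """
    if not sigma_rho > 0:
        raise ValueError("sigma_rho must be > 0")
    Z, mu, sd = _engine.posterior_components(
        rho_m, prior.weights, prior.means, prior.sds, sigma_rho
    )
    return GaussianMixture1D(Z[0], mu[0], sd[0], space="rho")


def posterior_com(
    post_rho: GaussianMixture1D,
    dim_d: float,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    n_quad: int = 31,
) -> GaussianMixture1D:
    """Moment-matched Gaussian-mixture posterior in center-of-mass space.

    Each log-ratio component maps to one com-space component with the exact
    first two moments of the com map under that component (Gauss-Hermite
    quadrature, not a linearization).  Delta components map exactly.
    """
    if not dim_d > 0:
        raise ValueError("dim_d must be > 0")
    m, s = _engine.moment_map(
        post_rho.means, post_rho.sds, dim_d, geometry.half_length, n_quad
    )
    # Exact zero sd for delta inputs (quadrature returns ~1e-17 round-off).
    s = np.where(post_rho.sds == 0.0, 0.0, s)
    return GaussianMixture1D(post_rho.weights, m, s, space="com")


def _as_rows(mix: GaussianMixture1D):
    return mix.weights[None, :], mix.means[None, :], mix.sds[None, :]


def preliminary_endpoint(
    post_com: GaussianMixture1D,
    sigma_err: float = SCORE_SIGMA,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    step: float = 0.01,
    full_output: bool = False,
):
    """Endpoint minimizing the expected inverted-Gaussian error loss.

    Global optimum over the bar, found by dense grid search at resolution
    ``step`` plus parabolic refinement.  With ``full_output=True`` also
    returns a flag marking a degenerate (flat) objective, in which case the
    midpoint of the maximizing set is returned.
    """
    if not sigma_err > 0:
        raise ValueError("sigma_err must be > 0")
    Z, m, s = _as_rows(post_com)
    s_opt, flat = _engine.optimize_endpoint(
        Z, m, s, sigma_err, geometry.half_length, kind="pre", step=step
    )
    return (float(s_opt[0]), bool(flat[0])) if full_output else float(s_opt[0])


def adjusted_endpoint(
    post_com: GaussianMixture1D,
    r0: float,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    step: float = 0.01,
    full_output: bool = False,
):
    """Final endpoint trading error loss against the adjustment cost.

    Minimizes ``alpha * L_adj(s - r0) + E[L_err(s - target)]`` over the bar,
    both losses inverted Gaussians.  With ``alpha = 0`` (or a flat
    adjustment loss) this reduces exactly to :func:`preliminary_endpoint`.
    """
    if not np.isfinite(r0):
        raise ValueError("r0 must be finite")
    Z, m, s = _as_rows(post_com)
    if params.alpha == 0.0 or params.inv_sigma_adj == 0.0:
        return preliminary_endpoint(
            post_com, params.sigma_err, geometry, step=step, full_output=full_output
        )
    s_opt, flat = _engine.optimize_endpoint(
        Z, m, s, params.sigma_err, geometry.half_length,
        r0=np.array([r0]), alpha=params.alpha,
        inv_sigma_adj=params.inv_sigma_adj, kind="invgauss", step=step,
    )
    return (float(s_opt[0]), bool(flat[0])) if full_output else float(s_opt[0])


def decide_trial(
    rho_m: float,
    b: float,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
    rng: np.random.Generator | None = None,
    step: float = 0.01,
) -> DecisionOutcome:
    """Run the full two-stage decision for one internal measurement.

    Returns every intermediate quantity: the preliminary endpoint, the
    perturbed pre-adjustment position, the adjusted optimum, and the final
    response (with motor noise if an ``rng`` is given).
    """
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    post = posterior_com(posterior_rho(rho_m, prior, params.sigma_rho),
                         params.dim_d, geometry)
    s_pre = preliminary_endpoint(post, params.sigma_err, geometry, step=step)
    r0 = s_pre + b
    s_star = adjusted_endpoint(post, r0, params, geometry, step=step)
    noise = (
        params.sigma_motor * rng.standard_normal()
        if rng is not None and params.sigma_motor > 0
        else 0.0
    )
    return DecisionOutcome(
        rho_m=float(rho_m), s_pre=s_pre, r0=r0, s_star=s_star,
        r=s_star + noise, b=float(b),
    )


class ResponseDistribution:
    """Marginal distribution of the final response r for one trial.

    ``Pr(r | rho, b; theta) = int N(rho_m | rho, sigma_rho^2)
    N(r | s*(rho_m, s*_pre(rho_m) + b), sigma_motor^2) drho_m``, the internal
    measurement marginalized by Gauss-Hermite quadrature.  The density is a
    Gaussian mixture over quadrature nodes and therefore integrates to 1 by
    construction; the sampler draws the same two-stage decision path.
    """

    def __init__(
        self,
        rho: float,
        b: float,
        params: ObserverParams,
        geometry: TaskGeometry = DEFAULT_GEOMETRY,
        prior: GaussianMixture1D | None = None,
        n_quad: int = 101,
        n_table: int = 801,
        step: float = 0.01,
    ):
        self.rho = float(rho)
        self.b = float(b)
        self.params = params
        self.geometry = geometry
        prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
        t, w = hermgauss(n_quad)
        half_range = SQRT2 * t[-1] * params.sigma_rho * 1.05
        cache = _engine.DecisionCache(
            params,
            prior,
            geometry.half_length,
            rho_range=(rho - half_range, rho + half_range),
            n_rho=n_table,
            b_values=np.array([b]),
            step=step,
        )
        self._cache = cache
        self._nodes = rho + SQRT2 * params.sigma_rho * t
        self._weights = w / SQRTPI
        self._s_star_nodes = cache.s_star(self._nodes, b)

    def pdf(self, r):
        """Evaluate the marginal response density at r (requires motor noise)."""
        if self.params.sigma_motor <= 0:
            raise ValueError(
                "density undefined for sigma_motor = 0 (point-mass decision); "
                "use sample() or the decision path directly"
            )
        r = np.asarray(r, dtype=float)
        var = self.params.sigma_motor**2
        d = r[..., None] - self._s_star_nodes
        out = (
            self._weights * np.exp(-0.5 * d * d / var) / np.sqrt(2 * np.pi * var)
        ).sum(axis=-1)
        return float(out) if np.isscalar(r) or r.ndim == 0 else out

    def logpdf(self, r):
        return np.log(np.maximum(self.pdf(r), 1e-300))

    def mean(self) -> float:
        """Mean response (motor noise is zero-mean)."""
        return float((self._weights * self._s_star_nodes).sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rho_m = self.rho + self.params.sigma_rho * rng.standard_normal(n)
        s_star = self._cache.s_star(rho_m, self.b)
        return s_star + self.params.sigma_motor * rng.standard_normal(n)


def response_distribution(
    rho: float,
    b: float,
    params: ObserverParams,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    **kw,
) -> ResponseDistribution:
    """Marginal response distribution for a trial (evaluable and samplable)."""
    return ResponseDistribution(rho, b, params, geometry, **kw)


def gaussian_score_mean(
    sigma: float, sigma_score: float = SCORE_SIGMA, max_score: float = 10.0
) -> float:
    """Closed-form mean of the continuous score under Gaussian error.

    If ``ds ~ N(0, sigma^2)``, then ``E[max * exp(-ds^2/(2 s0^2))] =
    max * s0 / sqrt(s0^2 + sigma^2)`` (rounding ignored).
    """
    return max_score * sigma_score / math.sqrt(sigma_score**2 + sigma**2)


def expected_score(
    params: ObserverParams,
    trial_class: str,
    n_sim: int,
    rng: np.random.Generator | int,
    geometry: TaskGeometry = DEFAULT_GEOMETRY,
    prior: GaussianMixture1D | None = None,
):
    """Monte-Carlo mean score (+/- SE) of an observer on one stimulus class.

    Simulates unperturbed trials of the given class ('low' = equal disks,
    'high' = unequal disks with the experimental ratio distribution, sides
    balanced), runs the observer's decision path, scores the responses, and
    returns (mean, se).  With ``b = 0`` the two decision stages coincide, so
    only the preliminary endpoint is needed.
    """
    from .task_synthetic import ScoreConfig, score as score_fn

    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    if trial_class == "low":
        rho = np.zeros(n_sim)
    elif trial_class == "high":
        mag = rng.lognormal(math.log(1.5), 0.1, size=n_sim)
        sign = rng.permuted(np.where(np.arange(n_sim) % 2 == 0, 1.0, -1.0))
        rho = sign * np.log(mag)
    else:
        raise ValueError("trial_class must be 'low' or 'high'")
    s_true = com_map(rho, 2.0, geometry)
    rho_m = rho + params.sigma_rho * rng.standard_normal(n_sim)
    lo = rho_m.min() - 1e-6
    hi = rho_m.max() + 1e-6
    n_tab = max(401, int((hi - lo) / 0.002) + 1)
    cache = _engine.DecisionCache(
        params, prior, geometry.half_length,
        rho_range=(lo, hi), n_rho=n_tab, b_values=None, step=0.01,
    )
    r = cache.s_star(rho_m, 0.0)
    if params.sigma_motor > 0:
        r = r + params.sigma_motor * rng.standard_normal(n_sim)
    scores = score_fn(r - s_true, ScoreConfig())
    return float(scores.mean()), float(scores.std(ddof=1) / math.sqrt(n_sim))
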