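"""Vectorized numerical kernels for the observer model.

Everything in here operates on arrays of trials (or of internal-measurement
grid nodes) at once; the public single-trial API in :mod:`comreach.observer_core`
wraps these kernels with ``n = 1``.

Conventions
-----------
* Positions are in cm, measured from the bar midpoint; log radius ratios are
  in natural-log units.
* A mixture component with ``sd == 0`` is a delta function; all formulas below
  handle that case without special branches (a zero-variance Gaussian update
  keeps its mean, and zero-variance quadrature nodes collapse onto the mean).
* 1-D endpoint optimizations use a deterministic dense grid over the bar
  followed by a local parabolic refinement; ties are broken toward the
  smaller ``|s|``.
"""

from __future__ import annotations

import functools

import numpy as np

SQRT2 = np.sqrt(2.0)
SQRTPI = np.sqrt(np.pi)
_LOG2PI = np.log(2.0 * np.pi)


@functools.lru_cache(maxsize=16)
def hermgauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached Gauss-Hermite nodes/weights (physicists' convention)."""
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, w


def com_map(rho, dim_d: float, half_length: float):
    """Center of mass of two D-spheres with radius log-ratio ``rho``.

    Masses scale as radius**D at positions +-half_length, which gives
    ``s = half_length * tanh(D * rho / 2)``.
    """
    return half_length * np.tanh(0.5 * dim_d * np.asarray(rho, dtype=float))


def norm_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def posterior_components(
    rho_m: np.ndarray,
    prior_w: np.ndarray,
    prior_mu: np.ndarray,
    prior_sd: np.ndarray,
    sigma_rho: float,
):
    """Conjugate per-component update of a Gaussian-mixture prior.

    Parameters
    ----------
    rho_m : (n,) measurements in log-ratio space.

    Returns
    -------
    Z, mu, sd : (n, k) posterior weights (rows sum to 1), means and SDs.
    Delta components (prior sd 0) keep their mean with sd 0; their weight is
    updated through the measurement likelihood like any other component.
    """
    rho_m = np.atleast_1d(np.asarray(rho_m, dtype=float))
    var_tot = sigma_rho**2 + prior_sd**2  # (k,)
    logw = np.log(prior_w)[None, :] + norm_logpdf(
        rho_m[:, None], prior_mu[None, :], var_tot[None, :]
    )
    logw -= logw.max(axis=1, keepdims=True)
    Z = np.exp(logw)
    Z /= Z.sum(axis=1, keepdims=True)
    mu = (sigma_rho**2 * prior_mu[None, :] + prior_sd[None, :] ** 2 * rho_m[:, None]) / var_tot
    sd = np.broadcast_to(
        np.sqrt(prior_sd**2 * sigma_rho**2 / var_tot), mu.shape
    ).copy()
    return Z, mu, sd


def moment_map(
    mu: np.ndarray,
    sd: np.ndarray,
    dim_d: float,
    half_length: float,
    n_quad: int = 31,
):
    """Exact first two moments of the com map under N(mu, sd^2) per component.

    Gauss-Hermite quadrature; for sd == 0 the nodes all collapse onto ``mu``
    so the delta case needs no special handling.
    """
    t, w = hermgauss(n_quad)
    x = mu[..., None] + SQRT2 * sd[..., None] * t  # (..., q)
    s = com_map(x, dim_d, half_length)
    wn = w / SQRTPI
    m = (wn * s).sum(axis=-1)
    var = (wn * (s - m[..., None]) ** 2).sum(axis=-1)
    return m, np.sqrt(np.maximum(var, 0.0))


def expected_error_gain(
    shat: np.ndarray,
    Z: np.ndarray,
    m: np.ndarray,
    sd: np.ndarray,
    sigma_err: float,
):
    """Negative expected inverted-Gaussian error loss, -E[L_err](shat).

    ``E[L_err](shat) = -sum_i Z_i * sigma_err/sqrt(v_i) * exp(-(shat-m_i)^2/(2 v_i))``
    with ``v_i = sd_i^2 + sigma_err^2`` -- the closed form of the expected loss
    of an inverted Gaussian of length scale ``sigma_err`` under the mixture
    posterior.  Maximizing this gain is the same as the mixture-density argmax
    of the preliminary-endpoint rule (the component amplitudes carry the
    ``1/sqrt(v_i)`` factors).

    Shapes: shat (G,) or (n, G); Z, m, sd (n, k).  Returns (n, G).
    """
    v = sd**2 + sigma_err**2  # (n, k)
    amp = Z * sigma_err / np.sqrt(v)
    if shat.ndim == 1:
        d = shat[None, None, :] - m[:, :, None]  # (n, k, G)
    else:
        d = shat[:, None, :] - m[:, :, None]
    return (amp[:, :, None] * np.exp(-0.5 * d * d / v[:, :, None])).sum(axis=1)


def _objective(
    shat,
    Z,
    m,
    sd,
    sigma_err,
    r0=None,
    alpha=0.0,
    inv_sigma_adj=0.0,
    kind="invgauss",
    gamma=None,
):
    """Decision objective to *maximize* over shat.

    kind:
      'pre'       gain only (preliminary endpoint)
      'invgauss'  gain + alpha * exp(-(d*inv)^2/2)      (primary model)
      'power'     gain - alpha * |d|^gamma              (power adjustment loss)
      'quad_err'  -(shat - post_mean)^2 + alpha * exp(-(d*inv)^2/2)
                  (quadratic error loss variant; depends on the posterior
                  only through its mean)
    """
    if kind == "quad_err":
        mean = (Z * m).sum(axis=1)  # (n,)
        if shat.ndim == 1:
            g = -((shat[None, :] - mean[:, None]) ** 2)
        else:
            g = -((shat - mean[:, None]) ** 2)
    else:
        g = expected_error_gain(shat, Z, m, sd, sigma_err)
    if kind == "pre" or r0 is None:
        return g
    if shat.ndim == 1:
        d = shat[None, :] - np.atleast_1d(r0)[:, None]
    else:
        d = shat - np.atleast_1d(r0)[:, None]
    if kind in ("invgauss", "quad_err"):
        g = g + alpha * np.exp(-0.5 * (d * inv_sigma_adj) ** 2)
    elif kind == "power":
        g = g - alpha * np.abs(d) ** gamma
    else:  # pragma: no cover
        raise ValueError(f"unknown objective kind {kind!r}")
    return g


def make_grid(half_length: float, step: float) -> np.ndarray:
    n = int(round(2 * half_length / step)) + 1
    return np.linspace(-half_length, half_length, n)


def grid_argmax(grid: np.ndarray, vals: np.ndarray, flat_frac: float = 0.5):
    """Row-wise argmax with small-|s| tie-breaking and flat detection.

    Returns (idx, s, flat) where flat rows get the midpoint of the maximizing
    set instead of a tie-broken grid point.
    """
    vmax = vals.max(axis=1, keepdims=True)
    span = vals.max(axis=1, keepdims=True) - vals.min(axis=1, keepdims=True)
    tol = 1e-12 * np.maximum(np.abs(vmax), 1.0)
    is_max = vals >= vmax - tol
    masked = np.where(is_max, np.abs(grid)[None, :], np.inf)
    idx = masked.argmin(axis=1)
    s = grid[idx]
    n_max = is_max.sum(axis=1)
    flat = (n_max > flat_frac * len(grid)) | (span[:, 0] <= tol[:, 0])
    if flat.any():
        first = is_max.argmax(axis=1)
        last = len(grid) - 1 - is_max[:, ::-1].argmax(axis=1)
        mid = 0.5 * (grid[first] + grid[last])
        s = np.where(flat, mid, s)
    return idx, s, flat


def optimize_endpoint(
    Z,
    m,
    sd,
    sigma_err,
    half_length,
    r0=None,
    alpha=0.0,
    inv_sigma_adj=0.0,
    kind="pre",
    gamma=None,
    step=0.01,
    refine=True,
):
    """Batch 1-D endpoint optimization over [-half_length, half_length].

    Dense-grid argmax at resolution ``step`` followed by one parabolic
    refinement (kept only when it improves the objective).  Returns
    (s, flat_flags), each of shape (n,).
    """
    grid = make_grid(half_length, step)
    kw = dict(
        Z=Z, m=m, sd=sd, sigma_err=sigma_err, r0=r0, alpha=alpha,
        inv_sigma_adj=inv_sigma_adj, kind=kind, gamma=gamma,
    )
    vals = _objective(grid, **kw)
    idx, s, flat = grid_argmax(grid, vals)
    if refine:
        n = vals.shape[0]
        rows = np.arange(n)
        i = np.clip(idx, 1, len(grid) - 2)
        y1, y2, y3 = vals[rows, i - 1], vals[rows, i], vals[rows, i + 1]
        denom = y1 - 2 * y2 + y3
        ok = (i == idx) & (denom < 0) & ~flat
        delta = np.zeros(n)
        delta[ok] = 0.5 * (y1[ok] - y3[ok]) / denom[ok]
        delta = np.clip(delta, -1.0, 1.0)
        cand = np.clip(grid[i] + delta * step, -half_length, half_length)
        cand_vals = _objective(cand[:, None], **kw)[:, 0]
        better = ok & (cand_vals >= y2)
        s = np.where(better, cand, s)
    return s, flat


def decision_path(
    rho_m,
    b,
    Z,
    m,
    sd,
    sigma_err,
    alpha,
    inv_sigma_adj,
    half_length,
    kind="invgauss",
    gamma=None,
    step=0.01,
):
    """Two-stage decision for a batch of internal measurements.

    Returns (s_pre, r0, s_star).  ``b`` may be scalar or (n,).
    """
    s_pre, _ = optimize_endpoint(Z, m, sd, sigma_err, half_length, kind="pre", step=step)
    r0 = s_pre + np.asarray(b, dtype=float)
    if alpha == 0.0 or (kind == "invgauss" and inv_sigma_adj == 0.0):
        # No (or flat) adjustment cost: the final optimum is the error-loss
        # optimum itself, except under the quadratic error variant whose
        # optimum is the posterior mean.
        if kind == "quad_err":
            s_star = (Z * m).sum(axis=1)
        else:
            s_star = s_pre.copy()
    else:
        s_star, _ = optimize_endpoint(
            Z, m, sd, sigma_err, half_length,
            r0=r0, alpha=alpha, inv_sigma_adj=inv_sigma_adj,
            kind=kind, gamma=gamma, step=step,
        )
    return s_pre, r0, s_star


class DecisionCache:
    """Tabulated decision path for one observer parameter vector.

    Used by the likelihood (which needs ``s*(rho_m, b)`` at many quadrature
    nodes) and by fast samplers.  ``s*_pre`` is tabulated on a ``rho_m`` grid;
    ``s*`` on a ``(rho_m, b)`` grid, interpolated bilinearly.
    """

    def __init__(
        self,
        params,
        prior,
        half_length,
        rho_range,
        n_rho=181,
        b_values=None,
        step=0.1,
        n_moment_quad=31,
        kind="invgauss",
        gamma=None,
    ):
        self.half_length = half_length
        self.rho_grid = np.linspace(rho_range[0], rho_range[1], n_rho)
        Z, mu, sdr = posterior_components(
            self.rho_grid, prior.weights, prior.means, prior.sds, params.sigma_rho
        )
        m, sdc = moment_map(mu, sdr, params.dim_d, half_length, n_moment_quad)
        self._Z, self._m, self._sd = Z, m, sdc
        self.s_pre_tab, _ = optimize_endpoint(
            Z, m, sdc, params.sigma_err, half_length, kind="pre", step=step
        )
        self.b_grid = None
        self.s_star_tab = None
        effort_free = params.alpha == 0.0 or (
            kind == "invgauss" and params.inv_sigma_adj == 0.0
        )
        if b_values is not None and not effort_free:
            self.b_grid = np.asarray(b_values, dtype=float)
            nb = len(self.b_grid)
            Zr = np.repeat(Z, nb, axis=0)
            mr = np.repeat(m, nb, axis=0)
            sr = np.repeat(sdc, nb, axis=0)
            r0 = (self.s_pre_tab[:, None] + self.b_grid[None, :]).ravel()
            s_star, _ = optimize_endpoint(
                Zr, mr, sr, params.sigma_err, half_length,
                r0=r0, alpha=params.alpha, inv_sigma_adj=params.inv_sigma_adj,
                kind=kind, gamma=gamma, step=step,
            )
            self.s_star_tab = s_star.reshape(n_rho, nb)
        self._quad_mean = (Z * m).sum(axis=1) if kind == "quad_err" else None

    def s_pre(self, rho_m):
        return np.interp(rho_m, self.rho_grid, self.s_pre_tab)

    def s_star(self, rho_m, b):
        """Final endpoint for measurements ``rho_m`` and perturbations ``b``."""
        rho_m = np.asarray(rho_m, dtype=float)
        if self.s_star_tab is None:
            if self._quad_mean is not None:
                return np.interp(rho_m, self.rho_grid, self._quad_mean)
            return self.s_pre(rho_m)
        if len(self.b_grid) == 1:
            return np.interp(rho_m, self.rho_grid, self.s_star_tab[:, 0])
        b = np.broadcast_to(np.asarray(b, dtype=float), rho_m.shape)
        bg = self.b_grid
        ib = np.clip(np.searchsorted(bg, b) - 1, 0, len(bg) - 2)
        fb = np.clip((b - bg[ib]) / (bg[ib + 1] - bg[ib]), 0.0, 1.0)
        rg = self.rho_grid
        ir = np.clip(np.searchsorted(rg, rho_m) - 1, 0, len(rg) - 2)
        fr = np.clip((rho_m - rg[ir]) / (rg[ir + 1] - rg[ir]), 0.0, 1.0)
        t = self.s_star_tab
        v00 = t[ir, ib]
        v01 = t[ir, ib + 1]
        v10 = t[ir + 1, ib]
        v11 = t[ir + 1, ib + 1]
        return (1 - fr) * ((1 - fb) * v00 + fb * v01) + fr * ((1 - fb) * v10 + fb * v11)
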