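"""Generative model of the center-of-mass reaching experiment.

Stimuli, covert cursor perturbations, the integer scoring rule, session
assembly with counterbalancing, and simulated observer responses.  The
generator's defaults reproduce the study conditions: a 120-trial training
session with performance feedback, and a 576-trial test session made of 192
unperturbed, 192 small-perturbation (+-0.5 cm) and 192 large-perturbation
(+-1.5 cm) trials.  Disk radii are log-normal (mean log 1 cm, SD 0.1 in log
space); on one third of trials the disks are equal (a line bisection), on the
rest the radius ratio is log-normal (mean log 1.5, SD 0.1) with the larger
disk's side counterbalanced.  Perturbations are Gaussian around the signed
level with SD 0.2 cm, truncated at 2.5 SD so the small and large supports
never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .observer_core import (
    SCORE_SIGMA,
    DEFAULT_GEOMETRY,
    GaussianMixture1D,
    ObserverParams,
    TaskGeometry,
    com_map,
)

__all__ = [
    "ScoreConfig",
    "SessionConfig",
    "TrialSpec",
    "score",
    "sample_stimulus",
    "sample_perturbation",
    "generate_session",
    "simulate_responses",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Integer score: Round(max * exp(-ds^2 / (2 sigma_score^2)))."""

    max_score: int = 10
    sigma_score: float = SCORE_SIGMA


@dataclass(frozen=True)
class SessionConfig:
    """Trial counts, stimulus statistics and perturbation model."""

    n_training: int = 120
    n_test_standard: int = 192
    n_test_small: int = 192
    n_test_large: int = 192
    level_small: float = 0.5
    level_large: float = 1.5
    perturb_sd: float = 0.2
    perturb_trunc_sds: float = 2.5
    radius_log_mean: float = 0.0  # log 1 cm
    radius_log_sd: float = 0.1
    ratio_log_mean: float = math.log(1.5)
    ratio_log_sd: float = 0.1
    p_equal: float = 1.0 / 3.0
    jitter_half_range: float = 3.0
    block_size: int = 36
    geometry: TaskGeometry = field(default_factory=TaskGeometry)


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus/perturbation configuration."""

    r1: float
    r2: float
    rho: float
    s_true: float
    jitter: float
    b: float
    perturbation_level: float
    uncertainty_class: str  # 'low' | 'high-left' | 'high-right'
    feedback: bool
    phase: str  # 'training' | 'test'
    block: int = 0


def score(delta_s, cfg: ScoreConfig = ScoreConfig()):
    """Integer score 0..max for a signed endpoint error (cm).

    Rounding is half-away-from-zero, so the score at exactly 1 cm (where the
    continuous score is 0.5 with the default length scale) is still 1.
    """
    ds = np.asarray(delta_s, dtype=float)
    raw = cfg.max_score * np.exp(-0.5 * ds * ds / cfg.sigma_score**2)
    # raw >= 0 always; the 1e-9 guard keeps the half-way case (raw exactly
    # 0.5 at |ds| = 1 cm with the default length scale) rounding up despite
    # floating-point round-off.
    out = np.floor(raw + 0.5 + 1e-9).astype(int)
    return int(out) if np.isscalar(delta_s) else out


def sample_stimulus(rng: np.random.Generator, cfg: SessionConfig = SessionConfig()) -> TrialSpec:
    """Draw a single unperturbed stimulus from the experimental statistics."""
    base = rng.lognormal(cfg.radius_log_mean, cfg.radius_log_sd)
    if rng.random() < cfg.p_equal:
        r1 = r2 = base
        klass = "low"
    else:
        ratio = rng.lognormal(cfg.ratio_log_mean, cfg.ratio_log_sd)
        if rng.random() < 0.5:
            r1, r2, klass = base, base * ratio, "high-right"
        else:
            r1, r2, klass = base * ratio, base, "high-left"
    rho = math.log(r2 / r1)
    return TrialSpec(
        r1=r1,
        r2=r2,
        rho=rho,
        s_true=com_map(rho, 2.0, cfg.geometry),
        jitter=rng.uniform(-cfg.jitter_half_range, cfg.jitter_half_range),
        b=0.0,
        perturbation_level=0.0,
        uncertainty_class=klass,
        feedback=True,
        phase="training",
    )


def sample_perturbation(
    level: float, rng: np.random.Generator, cfg: SessionConfig = SessionConfig()
) -> float:
    """Signed perturbation: truncated Gaussian around the signed level."""
    if level == 0.0:
        return 0.0
    lim = cfg.perturb_trunc_sds * cfg.perturb_sd
    while True:
        b = rng.normal(level, cfg.perturb_sd)
        if abs(b - level) <= lim:
            return b


def _block_layout(counts_per_class: dict[str, list[float]], rng: np.random.Generator):
    """Expand {class: [signed levels]} into a shuffled within-block list."""
    trials = [(k, lv) for k, levels in counts_per_class.items() for lv in levels]
    rng.shuffle(trials)
    return trials


_CLASSES = ("low", "high-left", "high-right")


def _session_blocks(phase: str, cfg: SessionConfig, rng: np.random.Generator):
    """Yield per-block lists of (class, signed level, feedback).

    Composition is exact: one third of trials per uncertainty class, and for
    perturbed test trials the signed levels are counterbalanced within each
    block of ``block_size`` trials.
    """
    if phase == "training":
        n = cfg.n_training
        per_block = []
        left = n
        while left > 0:
            size = min(cfg.block_size, left)
            if size % 3:
                raise ValueError("training block sizes must be divisible by 3")
            k = size // 3
            block = {c: [0.0] * k for c in _CLASSES}
            per_block.append(block)
            left -= size
    else:
        n = cfg.n_test_standard + cfg.n_test_small + cfg.n_test_large
        if n % cfg.block_size:
            raise ValueError("test trial count must divide into blocks")
        n_blocks = n // cfg.block_size
        if cfg.block_size % 12:
            raise ValueError("block size must allow 3 classes x 3 levels x 2 signs")
        per_level = cfg.block_size // 3  # trials per perturbation group per block
        k = per_level // 3  # per class within group
        per_block = []
        for _ in range(n_blocks):
            block = {c: [] for c in _CLASSES}
            for c in _CLASSES:
                block[c] += [0.0] * k
                for level in (cfg.level_small, cfg.level_large):
                    half = k // 2
                    block[c] += [level] * half + [-level] * (k - half)
            per_block.append(block)
    out = []
    for i, block in enumerate(per_block):
        trials = _block_layout(block, rng)
        out.append(trials)
    return out


def generate_session(
    rng: np.random.Generator,
    cfg: SessionConfig = SessionConfig(),
    subject_id: str = "S01",
) -> pd.DataFrame:
    """Assemble a full session (training + test) as a trial table.

    Columns follow the canonical trial-table schema; response columns
    (``r_cm``, ``delta_s_cm``, ``score``) are left empty until responses are
    simulated or imported.  Deterministic given the generator state.
    """
    rows = []
    trial_index = 0
    for phase in ("training", "test"):
        blocks = _session_blocks(phase, cfg, rng)
        for bi, block in enumerate(blocks):
            for klass, level in block:
                base = rng.lognormal(cfg.radius_log_mean, cfg.radius_log_sd)
                if klass == "low":
                    r1 = r2 = base
                else:
                    ratio = rng.lognormal(cfg.ratio_log_mean, cfg.ratio_log_sd)
                    if klass == "high-right":
                        r1, r2 = base, base * ratio
                    else:
                        r1, r2 = base * ratio, base
                rho = math.log(r2 / r1)
                b = sample_perturbation(level, rng, cfg)
                feedback = (phase == "training") or (level == 0.0)
                rows.append(
                    dict(
                        subject_id=subject_id,
                        phase=phase,
                        block=bi,
                        trial_index=trial_index,
                        r1_cm=r1,
                        r2_cm=r2,
                        rho=rho,
                        s_true_cm=com_map(rho, 2.0, cfg.geometry),
                        jitter_cm=rng.uniform(
                            -cfg.jitter_half_range, cfg.jitter_half_range
                        ),
                        perturbation_level=level,
                        b_cm=b,
                        uncertainty_class=klass,
                        feedback=feedback,
                    )
                )
                trial_index += 1
    df = pd.DataFrame(rows)
    df["r_cm"] = np.nan
    df["delta_s_cm"] = np.nan
    df["score"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def simulate_responses(
    session: pd.DataFrame,
    params: ObserverParams,
    rng: np.random.Generator,
    prior: GaussianMixture1D | None = None,
    geometry: TaskGeometry | None = None,
    score_cfg: ScoreConfig = ScoreConfig(),
    step: float = 0.01,
    keep_internals: bool = True,
) -> pd.DataFrame:
    """Simulate the observer's responses for every trial of a session.

    Per trial: draw the internal measurement ``rho_m``, compute the
    preliminary endpoint, shift it by the perturbation, solve the adjusted
    endpoint, and add motor noise.  The decision path is solved exactly
    (batched dense-grid optimization), not interpolated.  Scores are filled
    in on feedback trials only.
    """
    prior = prior if prior is not None else GaussianMixture1D.ratio_prior()
    geometry = geometry if geometry is not None else DEFAULT_GEOMETRY
    out = session.copy()
    rho = out["rho"].to_numpy(dtype=float)
    b = out["b_cm"].to_numpy(dtype=float)
    rho_m = rho + params.sigma_rho * rng.standard_normal(len(out))
    Z, mu, sdr = _engine.posterior_components(
        rho_m, prior.weights, prior.means, prior.sds, params.sigma_rho
    )
    m, sdc = _engine.moment_map(mu, sdr, params.dim_d, geometry.half_length)
    s_pre, r0, s_star = _engine.decision_path(
        rho_m, b, Z, m, sdc, params.sigma_err,
        params.alpha, params.inv_sigma_adj, geometry.half_length, step=step,
    )
    r = s_star + params.sigma_motor * rng.standard_normal(len(out))
    out["r_cm"] = r
    out["delta_s_cm"] = r - out["s_true_cm"].to_numpy(dtype=float)
    sc = score(out["delta_s_cm"].to_numpy(dtype=float), score_cfg)
    fb = out["feedback"].to_numpy(dtype=bool)
    out["score"] = pd.array(
        [int(s) if f else pd.NA for s, f in zip(sc, fb)], dtype="Int64"
    )
    if keep_internals:
        out["rho_m"] = rho_m
        out["s_pre_cm"] = s_pre
        out["r0_cm"] = r0
        out["s_star_cm"] = s_star
    return out


def simulate_cohort(
    n_subjects: int,
    params: ObserverParams,
    seed: int | np.random.SeedSequence,
    cfg: SessionConfig = SessionConfig(),
    prior: GaussianMixture1D | None = None,
    subject_prefix: str = "S",
) -> pd.DataFrame:
    """Simulate a cohort of identical-parameter synthetic subjects.

    Each subject gets an independent child RNG stream derived from the single
    top-level seed, so cohorts are reproducible and subjects independent.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_subjects)
    frames = []
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        sid = f"{subject_prefix}{i + 1:02d}"
        session = generate_session(rng, cfg, subject_id=sid)
        frames.append(
            simulate_responses(session, params, rng, prior, cfg.geometry)
        )
    return pd.concat(frames, ignore_index=True)
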