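# Methods

## Model

The observer infers the log radius ratio ρ = log(r₂/r₁) of a two-disk
dumbbell from a noisy internal measurement ρₘ ~ 𝒩(ρ, σ_ρ²) and combines it
with the experimental prior — an equal-weight mixture of 𝒩(−log 1.5, 0.1²),
a delta at 0 (the equal-disk trials), and 𝒩(+log 1.5, 0.1²) — under the
convention 𝒩(x|μ, 0) ≡ δ(x−μ). Conjugacy gives a mixture posterior with
closed-form component weights Zⁱ ∝ wⁱ·𝒩(ρₘ | μⁱ, σ_ρ² + σⁱ²), means
(σ_ρ²μⁱ + σⁱ²ρₘ)/(σ_ρ² + σⁱ²) and variances σⁱ²σ_ρ²/(σ_ρ² + σⁱ²); delta
components stay deltas.

Positions follow through the mass mapping: with masses ∝ radiusᴰ at ±ℓ/2,
the balance point is s = (ℓ/2)·tanh(Dρ/2) — odd, strictly increasing,
bounded by the disks. Each posterior component is pushed through this map
by moment matching: the component's exact first two moments under the map
are computed by Gauss–Hermite quadrature (31 nodes), *not* by
linearization, which matters where the map curves (large |ρ| or D ≠ 2).
The com-space posterior is again a Gaussian mixture.

Decisions minimize expected loss. The error loss is an inverted Gaussian
L_err(d) = −exp(−d²/2σ_err²) whose expectation under the mixture has the
closed form −Σᵢ Zⁱ·(σ_err/√vᵢ)·exp(−(ŝ−mᵢ)²/2vᵢ), vᵢ = sᵢ² + σ_err². The
preliminary endpoint maximizes this gain; after the cursor reappears
displaced to r₀ = s*_pre + b, the final endpoint maximizes
gain(ŝ) + α·exp(−(ŝ−r₀)²/2σ_adj²), the second term being the (negated)
effort cost of moving away from the pre-adjustment position. Both losses
peak at magnitude 1, so α is the relative weight of effort against error.
Gaussian motor noise σ_motor is added to the final choice. The response
marginal Pr(r|ρ, b; θ) integrates the decision path over ρₘ by
Gauss–Hermite quadrature (61 nodes for fitting, 101 for single-trial
density evaluation); since it is a Gaussian mixture over nodes it
normalizes by construction, and the companion sampler draws the identical
decision path.

## Parameters

| parameter | units | default / truth used in recovery | meaning |
|---|---|---|---|
| σ_ρ | log-units | 0.063 | sensory noise on the log radius ratio |
| D | — | 1.94 (2 = veridical disks) | exponent of the radius→mass mapping |
| α | — | 3.1 | weight of the adjustment (effort) loss |
| σ_adj | cm | 2.8 (∞ = flat loss) | length scale of the effort loss |
| σ_motor | cm | 0.76 | residual response noise |
| σ_err | cm | 1/√(2 ln 20) ≈ 0.4086 | error-loss scale, tied to the score rule |

σ_err is fixed, not fitted: the scoring rule Round(10·exp(−Δs²/2σ_score²))
with maximum 10 and support exactly |Δs| ≤ 1 cm pins
σ_score = 1/√(2 ln 20), and the observer is assumed to adopt the task's own
error scale. Rounding is half-away-from-zero with a 1e-9 guard so the
knife-edge value 0.5 at exactly 1 cm rounds up despite float round-off.

## Synthetic sessions

The generator reproduces the study design: 120 feedback training trials,
then 576 test trials — 192 unperturbed, 192 small (±0.5 cm) and 192 large
(±1.5 cm) perturbations, Gaussian with SD 0.2 cm truncated at 2.5 SD so the
levels' supports never overlap. Disk radii are log-normal (mean log 1 cm,
SD 0.1 in log space); one third of trials are equal-disk, the rest draw a
log-normal ratio (mean log 1.5, SD 0.1) multiplying the base radius on the
larger side. Composition is exact (thirds per class) and counterbalanced —
sides and perturbation signs balance within every 36-trial block, the block
size the task used for score reports. Display jitter is generated and
stored for fidelity but all analysis coordinates are midpoint-relative, so
it is a no-op downstream. Feedback (and hence a stored score) is present on
all training trials and only unperturbed test trials.

What the generator does *not* emulate: reach kinematics (trajectories,
exit positions, adjustment times), missed-trial re-presentation, learning
or drift across the session, and any between-subject heterogeneity beyond
independent noise streams — synthetic cohorts share one parameter vector.
Passing tests therefore validate the inference machinery and the analysis
pipeline, not claims about real subjects' data; in particular the model
shares one σ_motor across uncertainty classes, so a simulated cohort's
low-uncertainty response SD (≈ σ_motor) is larger than the 0.40 cm real
subjects show, and simulated mean scores differ accordingly.

## Fitting

Per the study's protocol, σ_ρ is estimated per subject from the training
session alone (feedback, no perturbations — the adjustment cost is then
irrelevant, because with b = 0 both decision stages coincide), with D and
σ_motor as nuisance parameters; it is then frozen for the test-session fit
of (D, α, σ_adj, σ_motor), where σ_motor is the residual response scale.

The per-trial likelihood tabulates the two-stage decision on a (ρₘ, b)
grid per parameter vector (181 ρₘ nodes spanning the data ± the quadrature
range, 17 b nodes, bilinear interpolation) and evaluates the 61-node
quadrature against it; endpoint optimizations inside the tables run on a
0.1 cm grid with parabolic refinement, the public single-trial functions on
0.01 cm. Optimization is Nelder–Mead from Latin-hypercube starts (10
probes, best 2 polished, plus a fixed heuristic start and a final
re-polish), with explicit bound-scaled initial simplices — scipy's default
relative simplex collapses on coordinates that start at 0.

**Parameterization.** The search runs in (D, log α, κ, σ_motor) with
κ = α/σ_adj², the small-displacement curvature of the weighted effort
loss. Profiling the likelihood shows why: at 576 trials the data pin κ
sharply but are nearly flat (≲ 0.5 log-likelihood units) along the
(α, σ_adj) ridge at fixed κ, because the perturbations (≤ 2 cm) probe the
effort loss mostly in its quadratic regime. Searching in the raw
coordinates stalls on this diagonal ridge; the κ axis aligns it with a
coordinate. κ = 0 encodes the flat-adjustment-loss boundary σ_adj → ∞ as
an interior point, and an explicit α = 0 submodel competes on likelihood.
Consequently the *individual* loss parameters are weakly identified at
session size: fits pinned at the α or κ search bounds are flagged
(`loss_boundary`), and group summaries of α and σ_adj follow the
convention of averaging over subjects with interior loss fits only —
the same aggregation the original group values use (three of sixteen
subjects had flat adjustment losses and were excluded from those means).
The recovery harness reports κ alongside; it tends to come back slightly
high (the tabulated decision path inside the likelihood is a hair smoother
than the exact simulation path), a known approximation documented here
rather than hidden.

## Analysis conventions

* Group summaries are always subject-level first, reported mean ± SE
  between subjects; trials are never pooled across subjects.
* High-uncertainty trials are pooled across sides by mirroring left-target
  trials (sign flip of target position, perturbation, response, residual).
* Baseline subtraction removes each subject's unperturbed-trial mean
  residual per raw stimulus class *before* mirroring, so a constant
  response bias is removed exactly; the pooled slope regression carries a
  side-specific intercept, which makes the slope exactly invariant to that
  subtraction. The slope of residual error on the continuous perturbation
  is the uncorrected fraction (0 = full correction, 1 = none).
* The ideal-observer benchmark simulates D = 2, α = 0, σ_motor = 0
  observers sharing each subject's σ_ρ; group spread is a bootstrap SD over
  subjects. Reading the benchmark as noiseless-execution ("fully
  compensated for any movement error") is a modeling choice.
* Counterfactual rescoring shifts each subject's unperturbed low-uncertainty
  responses by a tabulated per-level bias (e.g. slope × level) and rescores
  them with the task rule.
* Bias curves bin residual error by target location (9 equal-width bins
  over the occupied range); bins are presentation-only and never feed fits.
  Score summaries are reported both over unperturbed-only and all trials,
  since the two aggregations differ slightly under partial correction.

## Numerical choices

* Endpoint optimizers: deterministic dense grid over the bar plus one
  parabolic refinement step, ties broken toward smaller |ŝ|; a flat
  objective returns the midpoint of the maximizing set with a diagnostic
  flag. Equivalence with 0.001 cm brute-force grids is tested on 200
  random instances.
* Delta mixture components are exact (sd = 0), handled by the same
  formulas without jitter.
* Mixture weights are computed in log space and renormalized; response
  densities are floored at 1e-300 before logs.
* Truncated perturbations use rejection sampling.
* Randomness: a single top-level seed; per-subject and per-stage child
  streams via `numpy.random.SeedSequence.spawn`, so cohorts are
  reproducible and subjects independent.
* Problem sizes: the recovery harness uses 16 subjects × (120 + 576)
  trials — the study's own scale; the ideal-observer benchmark uses 1–2 ×
  10⁵ trials per class, which puts its Monte-Carlo SE an order of magnitude
  below the benchmark's bootstrap spread.

## Known limitations

* α and σ_adj are individually near-unidentifiable at single-session size
  (by design of the task: perturbations only probe the effort loss's
  quadratic regime); only κ = α/σ_adj² is sharply constrained. Group-level
  conclusions should rest on κ or on interior-fit summaries.
* Simulations at group-mean parameters overshoot the printed group slopes
  (≈ 0.07/0.23 vs 0.03/0.16): the printed values average per-subject fits
  including full-correctors and a right-skewed α distribution, so the mean
  parameter vector is not the mean predictor (Jensen effect).
* The MAT import adapter discovers per-subject struct layouts; it is
  exercised against the package's own synthetic stand-in container, since
  the deposited subject file's internal layout is not documented.
* Endpoints only: no trajectories, no within-movement feedback gains, no
  belief updating triggered by cursor reappearance.
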