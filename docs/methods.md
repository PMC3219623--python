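# Methods

## The design-selection problem

Given a comparison set of M generative models with prior probabilities
p(m), and a candidate experimental design u, we score u by (a bound on) the
probability that Bayesian model selection — choose the model with the
highest posterior p(m | y, u) — picks the wrong model once data arrive.
The error rate marginalized over datasets has no closed form; the package
minimizes an information-theoretic surrogate instead.

## Bounds and the Laplace-Chernoff risk

All entropies and divergences are in base 2, so that the surrogate is
bounded by 1 for two equiprobable models; natural-log values are available
via the `units` flag of the divergence functions.

With D_JS the Jensen-Shannon divergence of the prior predictive densities
{p(y | m, u)} under weights p(m), and H the prior entropy, define
b(u) = H − D_JS(u).  The selection error rate satisfies the Lin-type
sandwich

    b² / (4 (M − 1))  ≤  p(e | u)  ≤  b / 2 .

For nonlinear Gaussian models, y = g_m(θ) + ε, θ ~ N(η_m, Σ_θm),
ε ~ N(0, Σ_ε), the predictive moments are obtained by first-order expansion
at the prior mean:

    μ_m = g_m(η_m),   Q_m = J_m Σ_θm J_mᵀ + Σ_ε ,

exact for affine mappings.  The mixture entropy inside D_JS is approximated
by collapsing the mixture to a Gaussian that matches its first two moments
(Q̄ = Σ p(m) (Q_m + δ_m δ_mᵀ), δ_m = μ_m − μ̄), giving the closed form

    D_JS ≈ ½ log₂|Q̄| − Σ_m p(m) ½ log₂|Q_m| ,

and the **Laplace-Chernoff risk** b_LC = H − D_JS.  The moment-matched
entropy overestimates the true mixture entropy, so at high discriminability
D_JS can exceed H and b_LC goes negative; the `RiskReport.valid` flag
records this (the error-rate bounds are then vacuous), and values are never
clipped — empirically the mapping between b_LC and the exact error rate
stays monotone, which is what design ranking needs.  Exact 1-D oracles
(`exact_error_rate_1d`, quadrature JSD) and a stratified Monte-Carlo JSD
(default 1e5 samples, seed mandatory) are provided as cross-checks, never
as the scoring path.

The residual covariance entering Q_m is, by default, I/E[λ] with
E[λ] = shape·scale of the model's Gamma precision hyperprior
("expected-precision" mode) — the bounds are conditional on the expected
noise precision; a fixed Σ_ε is available as "fixed" mode.

**Families.**  To compare families of models irrespective of member-level
structure, each family's predictive is the prior-weighted mixture of member
predictives, collapsed by moment matching, with family priors the summed
member priors.  The report's `method`/`notes` fields keep this provenance.
With singleton families this reduces exactly to the model-level risk.

**GLM special case.**  For the nested linear comparison (full design X
versus X without column i, i.i.d. N(0, v) priors, flat model priors) the
risk has the determinant-lemma form

    b_LC = 1 − ½ log₂(1 + v s/2) + ¼ log₂(1 + v s),
    s    = x_iᵀ (v X₋ᵢX₋ᵢᵀ + σ² I)⁻¹ x_i ,

monotone decreasing in s.  As v → ∞, ranking by b_LC coincides with
ranking by the classical C-optimality efficiency
e = x_iᵀ(I − P₋ᵢ)x_i / σ²; the "non-informative" limit is realized
numerically at v = 10⁶ σ² (rankings already agree from v ≈ 10² σ² in the
test problems; at small v they may not, which the ranking report flags
without error).  General contrasts are handled by rotating the design
matrix so the contrast becomes a column.

## DCM forward model

Neural states z (one per region) follow the bilinear evolution

    dz/dt = (A + Σ_j u_j B_j + Σ_r z_r D_r) z + C u ,

with between-region coupling A (Hz; diagonal fixed at −1 Hz unless freed,
guaranteeing prior-mean stability), input modulations B_j, driving gains C,
and optional nonlinear gating D (off by default).  Each region's activity
drives a balloon model — vasodilatory signal s, inflow f, volume v,
deoxyhemoglobin q:

    ds/dt = z − κ s − γ (f − 1)
    df/dt = s
    dv/dt = (f − v^{1/α}) / τ
    dq/dt = (f E(f)/E₀ − v^{1/α} q / v) / τ,   E(f) = 1 − (1 − E₀)^{1/f}

and BOLD percent signal change is read out statically:

    y = 100 V₀ [k₁(1 − q) + k₂(1 − q/v) + k₃(1 − v)],
    k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2 .

Constants are the standard published conventions (κ = 0.64 s⁻¹,
γ = 0.32 s⁻¹, τ = 2 s, α = 0.32, E₀ = 0.32, V₀ = 0.04), overridable per
region; they are a convention of the DCM literature, not values we derived.
Five states per region is asserted structurally.

**Integration.**  Fixed-step RK4 on the microtime grid (dt = 0.1 s default;
up to 0.2 s is accepted with < 0.1% RMS self-convergence error on halving),
zero-order-hold inputs, observations sampled at the end of each TR.  The
integrator is batched over columns of parameter vectors so a central
finite-difference Jacobian of the full mapping (step
max(1e-4, 1e-4|η_i|)) costs one pass; complex parameter vectors propagate
analytically, so a complex-step Jacobian is available as an independent
derivative route (the two agree to relative 1e-4 on the DCM mapping, and
the complex-step route is the second method behind
`jacobian_method="complex-step"`).  Trajectories exceeding |z| = 1e6 raise
an instability error naming the free parameters.

**Priors.**  Free parameters (masked entries of A, B, C, D) carry i.i.d.
Gaussian shrinkage priors centered on the spec values with variance 1 by
default (a common DCM convention; the generating literature does not print
its value).  The residual precision carries a Gamma hyperprior — unit shape
with scale 0.1 for the scenario library (weakly informative), and unit
shape with scale equal to the simulated precision in the Monte-Carlo
validation loops, so the bounds condition on the true expected precision.

## Variational-Laplace inversion

Fixed-form Gaussian posterior on θ, Gamma posterior on the residual
precision.  Per iteration: closed-form Gamma update given the current θ
moments, then a Gauss-Newton step on the posterior mean with step-halving
(up to 8 halvings) until the free energy does not decrease — so the
accepted-iteration free-energy trace is non-decreasing by construction.
Initialization at the prior mean; convergence at |ΔF| < 0.01 nats or 64
iterations (both configurable); non-convergence flags the result instead of
raising.  F is reported in nats.  For linear mappings with fixed precision
the scheme reproduces the conjugate posterior and the exact log marginal
likelihood to numerical precision (the suite checks 1e-3 nats).  Model
posteriors are softmax(F + log prior) with max-subtraction; ties select the
lowest index for determinism.

At very high SNR the posterior becomes tight enough that the local
linearization biases the mean by a non-negligible fraction of a posterior
SD; recovery is therefore assessed per parameter (fraction of coupling
parameters within 2 posterior SD across repetitions) rather than as a joint
event, whose coverage compounds multiplicatively.

## Design generators and scenarios

Blocked designs tile the session with inter-block slots (default 32 s,
5-minute sessions, TR 1.3 s), center each epoch in its slot and jitter
onsets with a truncated Gaussian (default sd 2 s, truncated so epochs never
overlap).  Multi-input designs cycle through balanced factorial conditions
(u₁, u₂, u₁&u₂) — co-activation blocks are what make modulatory effects
visible at all.  Event-related designs randomize a trial sequence with the
requested per-type counts; inter-trial intervals are jittered uniformly
(±50%) around the requested mean; a blocked variant groups identical
consecutive trials.  Correlated input pairs place one block per slot for
the second channel — coincident, anti-phase, or partially overlapping —
with the counts solved from the binary-correlation identity
corr = (p₁₁ − p²)/(p(1−p)), hitting each requested level up to microtime
rounding.  On-line TMS is an extra binary channel of 5 Hz pulse trains
grouped in 8 s epochs, interleaved with the stimulus blocks so it stays
near-orthogonal to them.

The scenario library (two-region networks throughout): `driving-input`,
`modulatory-input`, `feedback` (two models each), `input-entry-pair` (which
input drives which region; the Monte-Carlo validation scenario),
`ppi-3x2` — the factorial set of six models compatible with a
psycho-physiological interaction, three PPI classes × presence of feedback,
partition 1 grouping by interpretation and partition 2 by feedback —,
`tms-site` (the PPI set with a TMS channel entering region 1, region 2, or
absent), and `finger-tapping` (models F, IF, NF, NF2; family 1 = {F, NF}).
The three PPI classes are a reconstruction: class B (the psychological
factor modulates the 1→2 connection), class Bd (additionally drives region
2), class D (region 1 gates region 2's response to the factor, a D-matrix
gain term whose baseline self-inhibition is deepened to −(1+η) to keep the
operating point stable under feedback).  The η grids (0.2–0.8 for the
canonical questions, 0.1–0.4 for the PPI set) and the 32 s inter-block
interval are likewise reconstructed working values, not verbatim protocol
constants.

## What the synthetic data do and do not emulate

Simulated sessions are two-region BOLD time series: deterministic bilinear
dynamics plus i.i.d. Gaussian observation noise at a stated precision,
seeded and reproducible.  They emulate hemodynamic delay and saturation
(refractoriness), coupling-dependent lags, and realistic SNR.  They do not
contain physiological noise spectra (cardiac/respiratory), scanner drift,
motion, slice-timing effects, inter-regional hemodynamic variability beyond
the parameter priors, or neural (state) noise — so passing tests show the
machinery is correct under its own model class, not that the model class
captures real fMRI.  In the splitting analysis each segment is re-inverted
from resting initial conditions, ignoring hemodynamic history across the
cut; segments shorter than 8 scans are rejected.

## Problem sizes used by the test suite

Simulation-heavy checks run at a reduced scale chosen to keep the whole
suite desk-sized: 2-minute sessions on a 0.2 s microtime grid sampled every
2 s (risk-curve comparisons use 5-minute sessions at the same grid).  The
Monte-Carlo validation of the bounds uses 3 correlation levels × 2
generating models × 2 noise precisions (0.005 and 0.02, i.e. noise sd 14%
and 7% signal change — low-SNR conditions under which selection errors
actually occur) × 8 noise realizations, with the inverter at |ΔF| < 0.05
nats and at most 32 iterations.  The parameter-recovery check uses 20
repetitions at precision 100.

## Known limitations and observed behaviors

- The b_LC ordering of designs tracks the exact error rate in every 1-D
  sweep we test (Spearman ρ = 1), but the *upper bound* becomes vacuous
  once the exact error drops below roughly 0.2 — consistent with its
  moment-matched derivation — and reports flag this.
- For the `modulatory-input` set under the default variance-1 shrinkage
  priors, discriminability is dominated by second-moment differences
  between the models, which shrink as the prior coupling mean η grows; the
  mean contrast grows with η but does not dominate at these settings, so
  the risk does not decrease monotonically with η for this set (it does for
  `feedback`, and increases for `driving-input`, where feedback
  synchronizes the regions and blurs the question).
- Hyperparameter (precision) uncertainty is not propagated into the
  predictive covariance, and no unscented or sampling-based predictive is
  offered as a scoring path.
- The inverter is a generic variational-Laplace scheme: no slice-timing,
  confound regressors, or MCMC gold standard.
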