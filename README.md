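# designrisk

Bayesian optimal experimental design for **model comparison**: rank candidate
experimental designs by how well they let Bayesian model selection
discriminate among competing generative models, before any data are
collected.  The package was built for network-identification questions in
neuroimaging — which of several dynamic causal models (DCMs) of a small
brain network generated the BOLD time series? — but the core machinery
applies to any set of nonlinear Gaussian generative models.

## Who it is for

Experimenters who will analyze their data by Bayesian model selection (e.g.
DCM studies of effective connectivity) and want to choose stimulation
parameters — epoch duration, input correlation, TMS intervention site,
blocked versus event-related presentation — so as to minimize the
probability of selecting the wrong model.

## The statistic at its core

Each candidate model m predicts the data y through its **prior predictive
density** p(y | m, u), which depends on the design u.  The probability that
Bayesian selection picks the wrong model, marginalized over datasets, is
bounded both ways by the Jensen-Shannon divergence D_JS of the predictive
densities (Lin-type inequalities).  Writing, in bits,

    b(u) = H(p(m)) − D_JS(u),

with H the Shannon entropy of the model priors and M models,

    b(u)² / (4 (M−1))  ≤  p(error | u)  ≤  b(u) / 2 .

For nonlinear Gaussian models y = g_m(θ) + ε with θ ~ N(η_m, Σ_θ) the
predictive moments follow from a first-order expansion around the prior
mean, μ_m = g_m(η_m) and Q_m = J_m Σ_θ J_mᵀ + Σ_ε, and the mixture entropy
in D_JS is collapsed by moment matching.  The resulting closed form is the
**Laplace-Chernoff risk** b_LC(u).  For two equiprobable models with equal
predictive covariance Q it reduces to a contrast-resolution measure

    b_LC = 1 − ½ log₂(1 + Δμᵀ Q⁻¹ Δμ / 4),

which tends to 1 (upper error bound → 0.5) as the predictions coincide.  At
high discriminability the Laplace estimate of D_JS can exceed H, making
b_LC negative; reports then carry `valid=False` rather than clipping —
ranking designs by b_LC remains monotone in the true error rate there.

Around this sit: a bilinear DCM forward model (neural dynamics → balloon
hemodynamics → BOLD, five states per region), a variational-Laplace
inverter whose free energy approximates the log evidence, the classical
C-optimality efficiency for the GLM special case (with the proof-of-concept
equivalence at the non-informative limit), family-level comparisons that
marginalize over model subsets, a scenario library of canonical two-region
questions, and Monte-Carlo loops that validate the bounds by simulating,
inverting and counting selection errors.

## Worked example

Score blocked designs of different epoch durations for the question "is
there a feedback connection from region 2 to region 1?":

```python
from designrisk import scenario_library, laplace_chernoff_risk

scen = scenario_library("feedback", session_length=300.0, dt=0.2, tr=2.0)
model_set = scen.build_model_set(0.5)   # prior mean of the coupling (Hz)
for epoch in (4.0, 16.0, 32.0):
    design = scen.make_design(epoch, jitter_sd=2.0, seed=0)
    report = laplace_chernoff_risk(model_set, design)
    print(f"epoch {epoch:5.1f} s  b_LC = {report.laplace_chernoff_risk:+.3f} bits  "
          f"JSD = {report.jsd:.3f} bits  valid bound regime: {report.valid}")
```

prints

```
epoch   4.0 s  b_LC = -0.838 bits  JSD = 1.838 bits  valid bound regime: False
epoch  16.0 s  b_LC = -1.354 bits  JSD = 2.354 bits  valid bound regime: False
epoch  32.0 s  b_LC = -0.031 bits  JSD = 1.031 bits  valid bound regime: False
```

Lower risk is better: for this comparison and session, 16 s epochs beat
both shorter and longer blocks.  All three values are negative — the
comparison is highly discriminable, so the absolute error-rate bounds have
broken down (flagged by `valid`), but the *ranking* of designs is what
design optimization uses.  `designrisk risk|curve|simulate|invert|mc-validate|split`
expose the same workflow on the command line.

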