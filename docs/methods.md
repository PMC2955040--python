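# Methods

## Models and anchoring

Five sigmoidal growth laws are implemented for tumor weight P(t) (grams)
against time (days): the hyperbolastic types I–III and the Gompertz and
Weibull curves (closed forms and rate equations in the README table). All
are self-limiting: the growth rate rises, peaks at the curve's inflection,
and decays as P approaches the asymptote (carrying capacity M for
H1/H2/H3/Weibull; the Gompertz asymptote is its own scale constant α).
The hyperbolastic family's extra hyperbolic terms (θ·arcsinh t in H1,
arcsinh(θt) in H3, the tanh/arcsinh kernel of H2) buy flexibility in *when*
growth becomes self-limiting and *how* the rate decays — θ measures
distance from a symmetric sigmoid, γ accelerates the time scale. Setting
θ=0 in H3 recovers the Weibull law exactly, a degeneration the tests
exercise.

The integration constant α is always derived from the initial condition
P(t₀)=P₀ — by default the series' first observation — and re-derived at
every objective evaluation during fitting. This removes α from the
parameter count (k = 3, 3, 4, 2, 3 for H1, H2, H3, Gompertz, Weibull) and
makes every candidate curve pass exactly through the anchor; the identity
P(t₀)=P₀ is asserted to 1e-12 relative across random parameters.

Conventions fixed by checking them against the published combined-treatment
tables (see the test suite):

* **Weibull scale sign.** The scale is stored positive (β > 0) inside
  exp(−βt^γ); published tables that print a negative β fold the sign into a
  different internal parameterization of the same curve.
* **Typeset rate equations.** The H1 kernel is δ + θ/√(1+t²) and the H3
  kernel δγt^(γ−1) + θ/√(1+θ²t²) (the derivative of arcsinh(θt)); both were
  fixed by requiring algebraic identity with the closed forms' derivatives,
  which the dual-evaluation self-check (closed-form derivative vs ODE
  right-hand side at P = P(t), ≤1e-9 relative) enforces at run time in the
  tests.

## Numerical choices

* **H2 stability.** α·arcsinh(exp(−δt^γ)) is evaluated through
  log(asinh(exp(−u))) with the asymptote −u for u > 30; the literal α
  overflows once δt₀^γ ≳ 700, which multistart starting points can reach.
  The literal printed form is kept as the independent evaluation path for
  the self-check, exercised where it is finite.
* **Derivatives.** dP/dt is the analytic derivative of the closed form;
  d²P/dt² is computed as f_t + f_P·f from the rate equation f(t,P), which
  equals the closed form's second derivative. Finite-difference
  cross-checks hold to 1e-6 (first) and 1e-4 (second) relative. For γ < 1
  the t^(γ−1) factor is singular at t=0: evaluation there raises a domain
  error rather than returning infinity (the curve itself is defined at 0).
* **ODE consistency.** Each family's rate equation is integrated with an
  8th-order Runge–Kutta scheme (rtol 1e-10/atol 1e-12) and must agree with
  the closed form to 1e-6 relative — a transcription check on both forms.
* **Optimizer.** scipy's bounded trust-region least squares (xtol = ftol =
  gtol = 1e-14). Bounds: M ∈ (max w, 10·max w], δ ≥ 0 (β ≥ 0), γ ∈ (0, 10],
  θ free for H1 (the combined-treatment fit needs θ < 0) but θ ≥ 0 for H3;
  Gompertz b, c < 0. The H3/Weibull scale is optimized as log₁₀(scale)
  because its natural scale spans 1e-9..1e-6; estimates and uncertainty are
  reported on the natural scale.
* **Multistart.** Heuristic start (M₀ = 1.05·max w; γ₀ and the scale from a
  Weibull-type linearization log(−log((M₀−w)/M₀)) vs log t; Gompertz b₀, c₀
  from a log-log linearization; small positive δ₀, θ₀ for H1) plus restarts
  at γ ∈ {1, 2, 3, 5, 7} with the scale re-linearized per γ, plus two
  seed-controlled jittered starts. Lowest SSE wins; SSE ties within 1e-12
  break toward smaller γ. A constant-weight series raises an initialization
  error.
* **Uncertainty.** SEs from s²(JᵀJ)⁻¹ with J a central finite-difference
  Jacobian w.r.t. the natural-scale parameters (relative step 1e-6) and
  s² = SSE/(n−k); 95% CIs are estimate ± t(0.975, n−k)·SE. Wald intervals
  are reported unclipped even when they cross a bound (e.g. the H3 δ
  interval includes negative values), for comparability with standard
  software. A Jacobian condition number above 1e8 — which the H3 δ–γ ridge
  triggers — sets a rank-deficiency flag rather than suppressing output.
* **Rate maximum.** Grid scan at 0.1 d then bounded scalar refinement
  (xatol 1e-8); plateaus report the earliest time; a peak on the window
  edge sets a boundary flag instead of raising. The default window
  [t₀, 1.5·max t] deliberately extends past the data because the Gompertz
  peak for this series falls near day 68, close to the last observation.
  For Gompertz the closed-form peak time ln(−1/b)/c is used as a test
  oracle.

## Model comparison

AIC = n·ln(2π·SSE/n) + n + 2k (Gaussian likelihood, k = mean-function
parameters, error variance profiled out), RMS = SSE/(n−k), R² = 1−SSE/SST,
MARE = mean(|obs−pred|/obs). These specific conventions — among the several
AIC/RMS variants in circulation — are the ones that reproduce the published
accuracy table for this data set, and the reconstruction is pinned by
tests (AIC within 1.0 absolute: the published values inherit the rounding
of 2-dp fitted values; the other statistics to ~1 unit in the last printed
digit). Ranking is ascending AIC with exact ties broken toward fewer
parameters.

## Synthetic data

The generator emulates the combined-treatment design: n = 18 observation
days over 9–82 d, a sigmoidal mean with carrying capacity ~7.5–8.3 g, and
additive homoscedastic Gaussian noise — consistent with unweighted least
squares — at σ defaulting to 0.08 g, the lower end of the residual scale
of the real fits (√RMS ≈ 0.08–0.28 g across families). A proportional
(CV-based) noise option exists for robustness studies. Weights truncate at
0.01 g to stay positive; at large σ this truncation biases early, near-zero
points upward (documented, not corrected). One root seed drives
deterministically spawned per-replicate streams, so replicate r is
reproducible independently of the replicate count.

What the generator does *not* emulate: per-animal heterogeneity and
within-arm averaging, serial correlation of measurement errors, and
treatment-arm dropout (animal death) — so passing recovery tests show the
estimator works under the model's own assumptions, not that real tumor
series satisfy them.

For the four-arm treatment comparison only the combined arm's raw series is
public. The untreated, IAA-only and DMSO-only arms are therefore synthetic
stand-ins: type-III curves whose (δ, γ) are found by numerically inverting
the peak map so each arm's true rate maximum matches the published per-arm
kinetics to well under 1%, at fixed asymmetry θ = 0.004 (the combined arm's
value) and carrying capacities chosen once as 8.0 g (untreated) and 7.6 g
(single treatments) — treated arms plateau near the combined arm's 7.5 g,
untreated higher. The combined arm uses the published fit directly. Those
published per-arm maxima are calibration targets for the generator, not
reproduction claims about the unpublished raw data.

## Problem sizes

The recovery studies use the study's own design (n = 18 per series):
200 replicates at σ = 0.08 for capacity recovery and interval coverage
(median relative error ≤ 2%, coverage ≥ 90%), 40 replicates for the
end-to-end generate→fit→peak pipeline, and 4000 replicates for the
Monte-Carlo check of the noise scale. These sizes give comfortably stable
medians and proportions for the asserted tolerances.

## Known limitations

* No weighted/robust regression, bootstrap or Bayesian uncertainty.
* No shift/delay time parameters and no multivariable (covariate) variant
  of the type-III model.
* Between-arm differences are summarized descriptively (rate ratios, peak
  delays); no formal tests are attached to them.
* The Wald/linearization uncertainty is first-order; on the H3 ridge the
  individual δ and γ intervals should be read jointly, not marginally.
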