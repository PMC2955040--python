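# hyperbolastic

Growth-curve analysis for solid tumor time series: the hyperbolastic
sigmoidal growth laws of types I–III (H1, H2, H3) fitted alongside the
Gompertz and Weibull models, with linearized uncertainty, information-
criterion model comparison, and growth-kinetics analysis (when is the tumor
growing fastest, and how fast). It is aimed at biostatisticians and
modellers who work with mean tumor-weight trajectories — here, solid
Ehrlich carcinoma in mice under a combined iodoacetate (IAA) +
dimethylsulfoxide (DMSO) treatment — and want a more flexible alternative
to the Gompertz curve that still yields closed-form velocity and
acceleration.

## The models

Each law is an ODE for the weight P(t) (grams, t in days) with a closed
form. With carrying capacity M and arcsinh the inverse hyperbolic sine:

| family | dP/dt | P(t) |
|---|---|---|
| H1 | (P/M)(M−P)(δ + θ/√(1+t²)) | M / (1 + α·exp(−δt − θ·arcsinh t)) |
| H2 | αδγP²t^(γ−1) tanh((M−P)/(αP)) / M | M / (1 + α·arcsinh(exp(−δt^γ))) |
| H3 | (M−P)(δγt^(γ−1) + θ/√(1+θ²t²)) | M − α·exp(−δt^γ − arcsinh(θt)) |
| Gompertz | P·bc·e^{ct} | α·exp(b·e^{ct}) |
| Weibull | (M−P)βγt^(γ−1) | M − α·exp(−βt^γ) |

α is never free: it is re-derived from the initial condition P(t₀)=P₀ at
every objective evaluation ("anchoring", t₀/P₀ = the first observation), so
fitted curves pass exactly through it. Estimation is bounded trust-region
nonlinear least squares with a gamma multistart; standard errors are the
usual s²(JᵀJ)⁻¹ linearization and 95% CIs use Student-t critical values at
n−k degrees of freedom. Models are compared by AIC
(n·ln(2π·SSE/n)+n+2k), residual mean square SSE/(n−k), R², and mean
absolute relative error. The growth-rate maximum (the curve's inflection)
is located by a grid scan plus bounded refinement of the analytic dP/dt.

## Worked example

The 18-point combined-treatment arm ships with the package. The analysis
scripts under `analysis/` run the full study; for a quick look:

```
$ hyperbolastic fit --families h3
Model     Parameter      Estimate     Std.Err   95% lower   95% upper
H3        M                 7.533     0.09832       7.322       7.744
          delta         3.594e-09   3.925e-09  -4.823e-09   1.201e-08
          gamma             4.712      0.2654       4.143       5.281
          theta          0.004033   0.0005666    0.002818    0.005248
          [rank-deficient Jacobian (correlated ridge)]
```

The tumor's asymptotic weight under the combined treatment is estimated at
7.53 g (95% CI 7.32–7.74). The tiny δ with γ≈4.7 is a strongly correlated
ridge — hence the rank-deficiency note — but the curve itself is pinned
down tightly. The δ interval crossing zero is the unbounded Wald interval,
reported for comparability with standard nonlinear-regression software.

```
$ python analysis/02_model_comparison.py
  family  k    sse      aic    rms     r2   mare
      H3  4 0.0810 -38.1854 0.0058 0.9993 0.0366
      H2  3 0.1740 -26.4266 0.0116 0.9986 0.0597
      H1  3 0.1792 -25.8884 0.0119 0.9985 0.0597
 WEIBULL  3 0.2583 -19.3137 0.0172 0.9978 0.0818
GOMPERTZ  2 1.2165   6.5827 0.0760 0.9899 0.0959

best model by AIC: H3
```

H3 wins on every measure; Gompertz — the field's default — is the clear
loser on this series. Kinetics (`analysis/03_growth_dynamics.py`): the H3
growth rate peaks at 0.184 g/day on day 57.2, whereas Gompertz misplaces
the peak at 0.146 g/day on day 67.6. The four-arm comparison
(`analysis/04_treatment_arms.py`, synthetic stand-ins calibrated to the
published per-arm kinetics) shows every treated arm peaking at less than
half the untreated rate (ratios ≈ 0.45–0.47), with peak delays ordered
IAA (+17.7 d) < DMSO (+27.3 d) < combined (+37.6 d): the two drugs delay
the fast-growth phase additively rather than lowering its height.

A one-shot bundle (tables, kinetics JSON, figures) is available via
`hyperbolastic reproduce --out <dir>`.

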