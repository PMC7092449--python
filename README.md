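# rctadjust

Baseline covariate adjustment in **small two-arm randomized trials** with a
continuous outcome: how does inverse probability of treatment weighting
(IPTW) with an *estimated* propensity score compare with conventional
regression adjustment (ANCOVA) when n is 40–200?

In a 1:1 randomized trial the propensity score e(X) = P(Z = 1 | X) is known
to be 0.5, yet deliberately re-estimating it from the data and weighting each
participant by the reciprocal of the probability of the arm they actually
received (w = 1/ê for treated, 1/(1 − ê) for controls) yields a
covariate-adjusted estimate of the marginal treatment effect θ without
putting covariates in the outcome model. Its variance must account for the
estimation of the score: this package implements the full M-estimation
sandwich that stacks the weighted moment conditions with the logistic score
equations,

    ψ₁ᵢ = Zᵢ(Yᵢ − μ₁)/êᵢ,   ψ₀ᵢ = (1 − Zᵢ)(Yᵢ − μ₀)/(1 − êᵢ),   ψ_αᵢ = xᵢ(Zᵢ − êᵢ),

    Var(θ̂) = cᵀA⁻¹BA⁻ᵀc / n,   θ̂ = μ̂₁ − μ̂₀ (Hájek),   c = (1, −1, 0, …, 0),

with A the empirical mean of −∂ψ/∂(μ₁, μ₀, α)ᵀ and B the empirical mean of
ψψᵀ. Alongside it: ANCOVA (`Y = α + θZ + βX + e`, model-based SE, t
intervals), the unadjusted difference in means, a nonparametric bootstrap
that refits the propensity model in every resample, balance/overlap
diagnostics, synthetic-trial generators, and a Monte-Carlo engine that
measures bias, SE calibration, and 95% CI coverage across a 52-scenario
grid. The headline finding the package reproduces: the large-sample
equivalence of the IPTW sandwich SE with the ANCOVA SE breaks down in small
samples — coverage falls to roughly 89–92% at n = 40 while regression
adjustment holds the nominal 95% throughout.

Intended users: trial statisticians and methods researchers evaluating
adjustment strategies for small-population trials.

## Worked example

```python
from rctadjust import (ScenarioConfig, generate_continuous_trial,
                       ancova_estimate, estimate_iptw, unadjusted_estimate)

cfg = ScenarioConfig(n=40, seed=0)   # θ_true = 5, adjust for all six covariates
trial = generate_continuous_trial(cfg)
for est in (unadjusted_estimate(trial),
            ancova_estimate(trial, cfg.adjust_set),
            estimate_iptw(trial, cfg.adjust_set)):
    print(f"{est.method:>10}: theta = {est.theta_hat:5.2f}  SE = {est.se_hat:4.2f}"
          f"  95% CI ({est.ci_low:5.2f}, {est.ci_high:5.2f})")
```

prints

```
unadjusted: theta =  4.63  SE = 2.41  95% CI (-0.24,  9.50)
regression: theta =  4.76  SE = 1.82  95% CI ( 1.04,  8.47)
      iptw: theta =  4.93  SE = 1.77  95% CI ( 1.47,  8.39)
```

All three point estimates sit near the true effect of 5, but only the
adjusted analyses exclude zero: adjustment removes the covariates'
contribution to the residual and shrinks the SE from 2.41 to ~1.8. The
IPTW sandwich SE is the smallest of the three — in one dataset that is a
feature or a symptom, and the simulation grid shows which: at this sample
size the sandwich systematically understates the sampling variability.

The same analyses run from the shell:

```bash
rctadjust simulate --n 40 --reps 200 --adjust C1,C2 --seed 7 --out-dir results/demo
rctadjust emulate-adapt --outcome total_scorad --boot 10000 --seed 7 --out-dir results/demo
rctadjust analyze results/demo/adapt_like_total_scorad.csv \
    --covariates baseline,ige1500,age10 --out-dir results/demo
```

## Analysis pipeline

Numbered drivers under `analysis/` rebuild every table in `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_grid.py` | 52-scenario continuous-covariate benchmark, 2000 reps |
| `02_simulate_mixed.py` | the same grid with 3 binary + 3 continuous covariates |
| `03_diagnostics_summary.py` | standardized differences and propensity-score overlap |
| `04_bootstrap_evaluation.py` | bootstrap vs sandwich vs empirical SE (scaled run) |
| `05_adapt_case_study.py` | emulated 60-child eczema trial, three outcomes, 10 000 bootstrap draws |
| `06_figures.py` | estimate / SE-calibration / coverage figures |

The case-study emulator targets the published baseline table of a 60-child
anti-IgE eczema trial (severity scores SCORAD, EASI, (C)DLQI; baseline–
follow-up correlations 0.25/0.25/0.20); the raw trial data are not public,
so those numbers characterise the emulation, not the trial.

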