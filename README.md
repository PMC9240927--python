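# graftsurv

Discrete-time recurrent survival modelling, risk-bin hazard calibration
and evaluation metrics for kidney-graft survival prediction.

## The problem

When a deceased-donor kidney is offered to a transplant candidate, the
clinical question is how long the graft can be expected to function for
this particular donor-recipient pair.  `graftsurv` models
**death-censored graft survival** — the time from transplantation to
diagnosed graft failure, censoring death and loss to follow-up — on a
quarterly grid spanning 15 years, and is aimed at biostatisticians and
ML engineers building decision-support tools on registry-style cohorts
(one row per transplant, mixed continuous/categorical covariates,
right-censored outcomes).

## The model

For each of the `N = 60` quarterly intervals, the covariate vector `x`
is passed together with the normalised interval value `t/N` through a
stack of LSTM layers; a shared dense sigmoid head emits the conditional
hazard `h[i,t]` — the probability of failure in interval `t` given
survival to its start.  Survival follows the discrete-time identity

    S_i(t) = prod_{s<=t} (1 - h[i,s]).

Training minimises either a DeepHit-style pairwise **ranking loss**
`exp(-(F_i(t_i) - F_j(t_i))/sigma)` over acceptable pairs (good
discrimination, uncalibrated outputs) or the discrete-time survival
**likelihood**.  Because the ranking objective only rewards ordering,
the raw hazards are then recalibrated: at every time step the scores
`R[i,t]` are cut into `n` quantile bins, each bin receives a
Breslow-style baseline hazard

    BH[k,t] = d_k(t) / sum_{i in R_k(t)} R[i,t],

and the calibrated hazard is `R[i,t] * BH[k(i,t),t]`.  On training data
the calibrated hazards of each bin's risk set sum exactly to the bin's
event count.  The evaluation suite provides the Harrell and Antolini
(time-dependent) concordance indexes, the IPCW Brier score and its grid
average (IBS), decile and restricted-cubic-spline calibration curves,
and the integrated calibration index (ICI).

Real transplant registries are access-restricted, so the package ships
a synthetic cohort generator with known discrete-time logistic hazards
(`h = expit(logit(bh_t) + x·beta_t)`), right censoring and an NDD/DCD
donor-type split; every pipeline stage is tested against this known
truth.

## Worked example

```python
import numpy as np
from graftsurv import (
    TimeGrid, RecurrentHazard, ModelConfig, LossConfig, RiskBinModel,
    SimulationConfig, generate_cohort, true_survival, antolini_cindex,
    hazards_to_survival, evaluate_model,
)

grid = TimeGrid()                       # 60 quarterly intervals, 15 years
sim = SimulationConfig(                 # cohort with known true hazards
    n_individuals=5000, n_continuous=5, baseline_hazard=0.03,
    coefficient_schedule=np.array([0.8, -0.8, 0.6, -0.6, 0.5]),
    censoring_rate=0.005, seed=7,
)
cohort, _ = generate_cohort(sim, grid)
train, test = cohort.subset(np.arange(4000)), cohort.subset(np.arange(4000, 5000))

config = ModelConfig(layer_widths=[16, 8], learning_rate=0.003,
                     batch_size=256, max_epochs=15, seed=0)
result = RecurrentHazard(train, grid, config, LossConfig(kind="ranking")).fit()
print(result.summary())

bins = RiskBinModel.fit(train, result.predict_risk_scores(train), grid, n_bins=10)
S = hazards_to_survival(bins.calibrate(result.predict_risk_scores(test)))
report = evaluate_model(S, test, grid, horizons=(1.0, 5.0, 15.0))

intervals, events = test.discretize(grid)
c_oracle = antolini_cindex(true_survival(sim, test.covariates, grid), intervals, events)
print(f"Antolini C: {report.antolini_c:.3f}  (data-generating oracle: {c_oracle:.3f})")
print(f"IBS: {report.ibs:.4f}")
print("ICI:", {k: round(v, 4) for k, v in report.ici.items()})
```

Output (about half a minute on one core):

```
Recurrent discrete-time hazard model
============================================
grid:            60 x 0.25 y (horizon 15.0 y)
covariates:      5
layers (LSTM):   [16, 8]
batch norm:      True   dropout: 0.1   L2: 0.001
loss:            ranking (alpha=0.1, sigma=0.1)
parameters:      2329
epochs trained:  15
final loss:      train 0.08645, monitor 0.07499
Antolini C: 0.772  (data-generating oracle: 0.788)
IBS: 0.1485
ICI: {'1y': 0.0037, '5y': 0.0349, '15y': 0.0566}
```

The held-out time-dependent C-index of 0.772 sits within 0.016 of the
best achievable on this cohort (the data-generating model's own 0.788),
and the 1-year ICI of 0.004 shows the risk-bin calibration mapping the
ranking model's arbitrary score scale back onto observed failure rates.

A command-line workflow wrapping the same pipeline is available as
`graftsurv simulate | train | evaluate | predict`; every run writes a
`manifest.json` (seed, config digest, package version) so it can be
reproduced exactly.

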