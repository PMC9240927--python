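# Methods

## Outcome and time grid

The quantity modelled is death-censored kidney-graft survival: the time
from transplantation to diagnosed graft failure, with death before
failure and loss to follow-up treated as right censoring.  Predictions
live on a uniform discrete grid of `N = 60` quarterly intervals covering
15 years.  Interval `t` (1-based) is the half-open span
`((t-1)·0.25, t·0.25]` years; an observation on an interval boundary
belongs to the earlier interval, and observations beyond the horizon are
administratively censored at interval `N`.  The grid is interpreted as
60 intervals with survival defined at interval ends (rather than 61 grid
points including `t = 0`, where survival is trivially 1).

The discrete conditional hazard `h[i,t]` is the probability that
individual `i` fails in interval `t` given survival to its start, and

    S[i,t] = prod_{s<=t} (1 - h[i,s]),      F[i,t] = 1 - S[i,t].

This standard discrete-time identity is used everywhere hazards are
turned into survival curves.  Event indicators are stored with positive
polarity (`event_observed = True` means failure was seen); the loss
functions convert internally to the censoring convention `c_i = 0` for
an observed event, so the sign flip lives in exactly one place.

## The recurrent hazard model

For each of the `N` intervals, the covariate vector `x_i` is
concatenated with the normalised interval value `t/N` and passed through
a stack of `m` LSTM layers; a dense layer with sigmoid activation shared
across steps maps the final hidden state to one hazard per interval.
Feeding `t/N` rather than the raw index keeps the time input on the
same scale as the standardised covariates.  Covariates are standardised
column-wise with training-set statistics stored in the fitted results.

The default configuration uses LSTM widths 64/32/16, batch
normalisation after each recurrent layer, dropout (rate 0.10) after the
normalisation, L2 weight penalty 0.001, and Adam with learning rate
0.001 and batch size 128.  The network is implemented directly in numpy
(forward pass and backpropagation through time written out by hand,
float64 throughout); the analytic gradients are verified against central
finite differences in the test suite.  Batch-norm statistics are pooled
over batch and time; inference uses running averages (momentum 0.9).
The head bias is initialised at −3 so that training starts from a small,
plausible hazard level instead of 0.5.

Two objectives are available:

* **Ranking loss** (default): for every acceptable ordered pair — `i`
  uncensored with observed interval `t_i` strictly earlier than `j`'s —
  the penalty is `exp(-(F_i(t_i) - F_j(t_i))/sigma)`.  The loss is the
  `alpha`-weighted **mean** over acceptable pairs (`alpha = 0.1`,
  `sigma = 0.1` by default; `sigma` is not prescribed by the reference
  configuration and is exposed in `LossConfig`).  The objective is
  implemented as this single weighted ranking term rather than as a
  likelihood-plus-ranking composite; it therefore rewards ordering only
  and exerts no pressure towards absolute calibration, which is exactly
  the behaviour the risk-bin post-processing is designed to repair.
* **Likelihood loss**: the discrete-time survival likelihood — for an
  uncensored individual the negative log of
  `p_i(t_i) = h[i,t_i]·prod_{s<t_i}(1-h[i,s])`, for a censored one the
  negative log of `S_i(t_i)` — with probabilities clipped at `1e-7`
  before taking logs.

Training uses mini-batch Adam with shuffling, an internal hold-out slice
of the training data (10% by default) for early stopping (patience 5 by
default; the epoch budget is configuration since no stopping rule is
prescribed), and keeps the best-scoring parameter state.  A `min_epochs`
warmup delays the stopping rule: the pairwise ranking loss evaluated on
a few hundred held-out rows is noisy in the first epochs, and without
the warmup a fluke-low early reading can freeze training prematurely.  When the
internal validation slice would be smaller than 20 rows the training
loss is monitored instead.  A non-finite loss aborts with a diagnostic.
Transfer learning is plain warm-starting: fit on the large (majority,
NDD-like) cohort, then continue training on the small (DCD-like) cohort
from the stage-one parameters and input scaler.

## Risk-bin baseline-hazard calibration

The raw per-interval hazards are reinterpreted as time-varying relative
risk scores `R[i,t]`.  At each time step the training scores are cut at
their `n`-quantiles (linear interpolation between order statistics,
`n = 10` by default, matching the decile convention used for
calibration assessment; ties go to the upper bin, and evaluation-time
scores outside the training range use the outer bins).  Each bin `k`
gets a Breslow-style baseline hazard

    BH[k,t] = d_k(t) / sum_{i in R_k(t)} R[i,t],

where `d_k(t)` counts observed events in interval `t` among bin-`k`
members and `R_k(t)` is the bin's risk set (observed interval `>= t`);
`BH = 0` when the denominator vanishes.  Calibrated hazards are
`R[i,t]·BH[k(i,t),t]`, clipped to [0,1] with a logged count of clips.
On the training data the calibrated hazards of each bin's risk set sum
*exactly* to that bin's event count — the estimator's keystone identity,
tested to 1e-9.  Evaluation-time individuals are re-binned with the
*training* cutoffs; refitting cutoffs on evaluation data would leak
information into the calibration.  Within a bin the mapping is a
positive rescaling, so ranking within a time step is preserved.

## Evaluation metrics

* **Harrell C-index**: pair `(i,j)` comparable iff `t_i < t_j` and `i`
  had the event; concordant iff `score_i > score_j`; score ties count
  0.5 and tied event times are not comparable.  Zero comparable pairs
  raises rather than returning a silent 0.5.
* **Antolini time-dependent C-index**: same comparability on the
  discretised grid; concordance compares `S_i(t_i) < S_j(t_i)`.  When
  predicted curves never cross this equals the Harrell index of any
  order-consistent scalar score (property-tested).
* **IPCW Brier score** at `t*`: events by `t*` contribute
  `S_i(t*)² / G(t_i⁻)`, individuals at risk past `t*` contribute
  `(1-S_i(t*))² / G(t*)`, censored-before contribute 0.  `G`, the
  censoring survival `P[C > t]`, is a Kaplan-Meier fit with flipped
  indicators, evaluated left-continuously at event times.  Individuals
  whose weight would be `1/0` are dropped from that horizon's average
  with a warning.  The integrated Brier score is the plain mean over the
  60 grid horizons (the grid is uniform, so interval-width weighting
  would only rescale).
* **Calibration**: at a horizon `t*`, either decile grouping (group
  means of predicted failure paired with `1 - KM_group(t*)`; duplicate
  quantile cutoffs merge adjacent groups) or a smooth curve obtained by
  regressing observed failure on `cloglog(F_pred) = log(-log(1-F_pred))`
  through a restricted cubic spline basis (4 knots at the 5th/35th/65th/
  95th percentiles of the transformed predictions) inside a
  proportional-hazards fit (lifelines `CoxPHFitter`, penalizer 1e-4 for
  numerical stability); the estimated observed probability at `t*` is
  read off for every individual.  Degenerate predictions (zero variance
  or a singular fit) fall back to the decile method with a warning.  The
  integrated calibration index (ICI) is the mean absolute difference
  between predicted and estimated observed probabilities.
* The Kaplan-Meier product-limit estimator is implemented in-package
  (the IPCW machinery needs left limits); it is cross-checked against
  lifelines in the tests, and the Harrell index against scikit-survival.
* `evaluate_model` uses cumulative failure at the final horizon as the
  scalar risk score for the Harrell index.

## Cross-validation and strategy experiments

`cross_validate` uses simple random k-fold partitions (sizes differing
by at most one, k = 5 by default, unstratified).  Per fold the model is
trained and the risk-bin model fitted on the training folds only; raw
and calibrated predictions are scored on the held-out fold, and the
summary reports unweighted fold means ± sd.  Cross-validated metrics are
reported as fold mean ± sd rather than pooled.

`strategy_experiment` holds out one random `1/k` share of the minority
subgroup and compares three trainings evaluated on it: minority-only,
combined, and transfer (majority pretraining, minority fine-tuning).
One held-out split is used per call; averaging over seeds is left to the
caller, which keeps single calls cheap.

`scenario_predict` builds three covariate rows for a fixed recipient —
offered donor, average DCD donor, average NDD donor — where "average"
means training-subgroup means for continuous donor covariates and modal
levels for one-hot blocks, then predicts and calibrates each row.

## Synthetic cohort generator

True hazards follow a logistic model on the grid:
`h[i,t] = expit(logit(bh_t) + x_i·beta[:,t])`, with standard-normal
continuous covariates, one-hot categoricals, per-interval
log-hazard-ratio columns (constant columns give proportional hazards)
and the logistic link chosen to match the model family of the sigmoid
network head.  Events are drawn by sequential per-interval Bernoulli;
independent per-interval Bernoulli censoring (a geometric censoring
time) satisfies the random-censoring assumption behind IPCW, and
survivors of the last interval are censored at exactly 15 years.
Observed times are drawn uniformly inside the interval where the
event/censoring occurred, so discretisation recovers the interval
exactly.

The named `transplant_fixture` mimics a deceased-donor registry slice:
standardised donor age / recipient age / donor creatinine, recipient
diabetes, donation type at an 86:14 NDD:DCD mix, blood type, baseline
hazard 0.012 per quarter and a modest DCD excess hazard.  What the
generator deliberately does **not** emulate: the ~170 one-hot covariates
of real registry data, HLA mismatch structure, demographic imbalance
beyond the NDD/DCD split, informative censoring, or era effects.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative assumptions, not clinical
performance on registry data.

## Experiment problem sizes

The benchmark drivers in `graftsurv.experiments` run the full pipeline
at desk scale: cohorts of 4,000-10,000 individuals (50,000 where only
closed-form curves are scored), LSTM widths [16, 8], learning rate
0.003, batch 128, and 10-20 epochs (warmup 10, patience 5).  These
sizes were chosen once so that a complete run finishes in minutes on a
single CPU core while preserving the qualitative behaviour of the
registry-scale defaults.  The strong-signal cohort uses five covariates
with constant log-hazard ratios (±0.8, ±0.6, 0.5), baseline hazard 0.03
per quarter and per-interval censoring 0.005, which yields roughly 30%
censoring overall (random plus administrative).

## Numerical choices and edge cases

- Probability clipping at 1e-7 in the losses; calibrated hazards clipped
  to [0,1]; hazards validated to lie in [0,1] at container boundaries.
- Quantile cutoffs use linear interpolation; all-tied scores put every
  individual in the top bin with all cutoffs equal to the tied value.
- Boundary times (exact multiples of the step) map to the earlier
  interval; discretisation guards float noise with a 1e-9 rounding.
- Seeded `numpy` generators drive initialisation, shuffling, dropout and
  simulation; two fits with identical data, configuration and seed are
  bit-identical (single-threaded).

## Known limitations

- The ranking objective alone can drift towards extreme raw hazards on
  long training runs; the calibration stage corrects the survival scale
  but raw curves should not be read as probabilities.
- The spline calibration inherits the proportional-hazards assumption of
  its smoother; grossly non-proportional miscalibration patterns may be
  smoothed imperfectly.
- The numpy LSTM is CPU-bound and intended for cohorts up to the tens of
  thousands, not registry scale.
- Competing risks are out of scope: death before graft failure is
  treated as censoring, as in the outcome definition.
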