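# Methods

This note documents the data-generating process, the modelling and
evaluation choices, the defaults and their rationale, and the limits of what
the synthetic experiments establish.

## The synthetic cohort generator

The generator emulates the *structure* of a linked cancer-registry /
Medicare-claims cohort of elderly women with stage IV breast cancer: one
row of time-fixed covariates per patient, a monthly stream of visit entries
carrying treatment-class flags, 18 adverse-event category flags and a
comorbidity index, and a possibly right-censored death time. It makes no
claim of clinical realism in treatment sequencing; its purpose is to provide
a cohort whose true hazard is known, so that parameter recovery and
discrimination experiments are well-posed.

### Data-generating process

Each patient is diagnosed at a study month drawn uniformly on the horizon
(300 months by default, a ~25-year window), and followed until death or
administrative censoring when the horizon ends. Death in month
$s \ge 1$ after diagnosis follows the logistic discrete hazard

$$h(s) = \operatorname{sigmoid}\bigl(\operatorname{logit}(h_0) +
\beta_{\text{fixed}}^\top x + \beta_{\text{tv}}^\top z(H_s)\bigr),$$

the discrete-time analogue of proportional hazards, with history summaries
$z(H_s)$ computed from the visits up to and including month $s$ (so a visit
and a death may share a month, and the visit counts). A death falling
exactly on the administrative boundary is recorded as censored; events are
therefore observable only strictly inside the follow-up window.

### Default parameters and calibration

| Parameter | Default | Why |
|---|---|---|
| age at diagnosis | truncated normal, mean 76.0 y, SD 7.5 y, floor 65 y | the published population moments of the emulated cohort; the floor is the insurance-eligibility age. The pre-truncation location is solved numerically so the *post*-truncation mean hits 76.0. Truncation necessarily shrinks the SD (≈ 6.3 observed); only the mean is a calibration target. |
| baseline comorbidity | negative binomial, mean 1.6, SD 2.6 | published moments; SD > mean forces an overdispersed law, and the negative binomial is the standard choice. |
| baseline hazard $h_0$ | 0.015 / month | implies a median survival of roughly 3–4 years before covariate effects, plausible for this population, and yields ~90 % observed deaths over the horizon. |
| $\beta_{\text{fixed}}$ | age +0.02/y, grade +0.30, ER+ −0.30, HER2+ +0.15 | modest prognostic effects of the diagnosis-time variables, giving a time-fixed concordance in the low 0.6s for a linear model — comparable to published time-fixed baselines. |
| $\beta_{\text{tv}}$ | comorbidity +0.35/point, cumulative chemo months +0.10, recent adverse event +0.60 | the emulated study's central finding is that history sharply improves individual prediction, so the default hazard is strongly history-driven; the comorbidity coefficient dominates because the comorbidity index is the most persistent (hence most learnable-at-landmark) history feature. These were fixed from a preliminary linear-model check that landmark features carry signal, before the neural experiments were run. |
| visit process | Bernoulli(0.5)/month, always a visit at diagnosis | a claims-like entry density (~12–15 entries per patient-year). |
| treatment policy | chemo probability decays with a 18-month half-life from 0.55; hormone maintenance grows toward 0.45; biotherapy flat 0.12 | creates informative temporal structure (early chemo phase, later maintenance) without modelling real regimens. |
| adverse events | per-category probabilities 0.01–0.10 given any same-month treatment, 0.01 background | a few common toxicity categories and a long tail. |
| comorbidity drift | +1 with probability 0.08 at each visit | monotone chronic accumulation, keeping current comorbidity correlated with — but not equal to — its baseline. |

The event/censoring fraction is an emergent property of these choices
(~90 % events by default), not a calibration target; it is configurable
through the hazard and horizon.

## Timeline preparation

* **Cleaning** collapses duplicate (patient, month) visit rows (union of
  binary flags, last comorbidity value), drops visits outside the
  observation window and drops patients with invalid durations. It is
  idempotent and always returns a removal report.
* **Bucketing** is half-open, $[b_i, b_{i+1})$: values below the first
  boundary map to bucket 0, values at or above the last boundary to the last
  bucket. Default age boundaries (65, 70, 75, 80, 85); comorbidity
  boundaries (0, 1, 2, 3, 5, 8). Exact boundaries are configurable — no
  published set exists.
* **Covariate extension** at month $m$ concatenates the fixed block with
  history summaries over visits dated $\le m$. The summary set (cumulative
  treatment counts, cumulative adverse-event counts per category, most
  recent bucketed comorbidity, months since diagnosis, months since last
  treatment with sentinel −1) is the simplest set that makes the
  extended-vs-fixed contrast testable; it is deliberately pluggable, since
  published descriptions of such representations leave the exact summaries
  open.
* **Encoding.** `fixed_only` yields one row per patient. `extended` yields
  one landmark row per patient-visit-month with the *residual* duration as
  outcome (an optional `last` policy keeps only the final visit). Per-visit
  landmark rows are the standard discrete-time treatment of time-varying
  covariates and preserve the no-lookahead contract; a single
  covariates-summarise-everything row would leak follow-up length into the
  features. Standardization (zero mean, unit variance) is always fitted on
  training rows only and stored with the dataset.

## Models

All four estimators share a fully connected ReLU network with inverted
dropout, He initialisation and Adam, implemented in numpy with analytic
loss gradients (the DeepHit gradient is verified against finite differences
in the test suite). Training is deterministic given the estimator seed.
Ties in partial likelihoods are handled by Breslow's convention throughout.
Probabilities inside logarithms are clamped at $10^{-7}$. A non-finite
training loss aborts the fit with a diagnostic rather than continuing.

Discrete-output families coarsen durations onto a grid of interval endpoints
placed at quantiles of the training durations (default 50 intervals); the
monthly grid remains the data-level truth and the coarse grid is purely a
model-size device. DeepSurv estimates a Breslow baseline cumulative hazard
on the training set after fitting; Cox-Time draws its control samples
without replacement from the risk set (falling back to the full risk set
when it is small, which makes the sampled loss coincide exactly with the
Breslow partial likelihood in that limit — a tested equivalence) and
rebuilds Breslow-type baseline increments by rescoring the training risk
set at every grid time. Optional early stopping on a validation split is
available but off by default so that a fit is a pure function of
(data, hyperparameters, seed).

The hyperparameter configuration object validates against the tuning
search space (layers 2–5; nodes, dropout, batch size, epochs, DeepHit's
α and σ from fixed categorical sets; learning rate continuous on
[0.0001, 0.1], sampled log-uniformly). Experiments in the test suite use
smaller epoch counts than the search space's smallest value; the estimators
accept any positive value, and the configuration object is only binding for
tuning.

## Evaluation

* **Time-dependent concordance (Antolini).** Comparable pairs are (i, j)
  with i an observed event and $T_i < T_j$, or $T_i = T_j$ with j censored;
  the pair is concordant when $S_i(T_i) < S_j(T_i)$, and prediction ties
  score ½. The implementation is a transparent $O(n^2)$ scan, tested to
  $10^{-10}$ against an independent brute-force oracle and shown to equal
  Harrell's C (via lifelines) on crossing-free curves.
* **Brier score / IBS (Graf).** IPCW weights use the Kaplan-Meier estimate
  of the censoring distribution with left limits at event times,
  $1/G(T_i^-)$ for failures and $1/G(t)$ for survivors; rows censored
  before $t$ get weight 0, and rows whose weight would divide by $G = 0$
  are excluded with a warning. The integral is trapezoidal over a uniform
  grid on $[0,$ 90th percentile of observed durations$]$ by default — the
  quantile cap keeps the unstable tail of $G$ out of the integral — and is
  divided by the grid span.

## Experiments

Cross-validation partitions patients, never landmark rows; standardization
is refitted inside each training fold. For extended encodings, held-out
metrics are computed on one landmark per test patient — the earliest — so
each patient is represented once and the fixed/extended comparison is on
the same prediction task (full residual survival from around diagnosis);
all-landmark evaluation is available as an option. A master seed fans out
through `SeedSequence` into independent per-fold and per-configuration
seeds.

Hyperparameter search is in-repo: pure random search, plus an optional
simple sequential scheme that proposes candidates near the top quantile of
the trace in normalised hyperparameter space. It is deliberately not a full
Bayesian optimiser; at the cohort sizes used here random search is an
adequate and fully reproducible baseline. Tied scores break toward the
earliest evaluated configuration.

Problem sizes in the shipped experiments (1,500-patient cohorts, 5 folds,
60 epochs, 32-node 2-layer networks, 50 intervals) were chosen so the full
contrast experiment completes in minutes on one CPU while leaving the
extended-vs-fixed gap several fold-SDs wide.

## What the synthetic experiments do and do not show

Passing tests establish that the pipeline is internally correct: the
metrics match their definitions, the losses match their closed forms, the
estimators recover known hazards and coefficients, and the extended
representation captures genuine history signal when the generator contains
one (and no spurious signal when it does not). They do **not** establish
clinical performance: the generator's hazard is exactly of the logistic
discrete-time form the models assume, its history dependence is low-order
and Markov-ish, visit timing is uninformative (missingness carries no
signal), and measurement error, coding drift and informative censoring are
all absent. Concordance values obtained here therefore transfer to real
claims data only as a qualitative direction, not as magnitudes.

## Known limitations

* Single-event setting only; no competing risks.
* The comorbidity index only changes at visits, and the generator's
  "recent adverse event" window (3 months) is not itself an encoded
  feature — models see it only through cumulative counts.
* Cox-Time predictions rescore the stored training set at every grid time,
  which is memory-proportional to the training data.
* The model-based tuning scheme is a heuristic; no convergence claim.
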