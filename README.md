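# survtv

Discrete-time deep survival analysis with time-varying covariates, built as a
fully testable pipeline around a synthetic claims-style oncology cohort.

## The problem

Predicting an individual patient's survival in metastatic (stage IV) breast
cancer depends not only on what is known at diagnosis — age, hormone-receptor
status, grade — but on everything that happens afterwards: which treatment
classes were given, which adverse events occurred, how the comorbidity burden
evolved. Linked registry/claims cohorts carry exactly this longitudinal
record, but they are access-restricted, which makes methods built on them
hard to validate. `survtv` addresses that by pairing the modelling stack with
a generator that produces structurally similar cohorts from a *known*
discrete-time hazard, so every model can be checked against ground truth.

The package is aimed at biostatisticians and methods researchers who want a
self-contained, oracle-backed environment for landmark-style survival
prediction with neural estimators.

## The model

Follow-up is divided into months. For patient $i$ with covariate vector $x$
the discrete hazard is the conditional event probability per month,
$h(t \mid x) = P(T = t \mid T \ge t, x)$, and the survival curve is the
product-limit $S(t \mid x) = \prod_{s \le t} (1 - h(s \mid x))$. Observation
is right-censored administratively: we see $T = \min(T^*, C^*)$ and the
indicator $D = \mathbf{1}\{T = T^*\}$.

The *covariate extension* step replaces the time-fixed vector with
$x(t) = (x_{\text{fixed}},\, z(H_t))$ where $z(H_t)$ summarises the visit
history up to the landmark month $t$: cumulative counts per treatment class
(chemotherapy / biotherapy / hormone therapy), cumulative counts per
adverse-event category (18 categories), the most recent bucketed comorbidity
index, months since diagnosis and months since last treatment. No visit after
$t$ can influence $x(t)$.

Four objectives are implemented as scikit-learn-style estimators over a
shared feed-forward network:

| Estimator | Objective |
|---|---|
| `DeepSurv` | Cox partial likelihood (Breslow ties), $h(t\mid x) = h_0(t)\,e^{g(x)}$ |
| `LogisticHazardNet` | per-interval Bernoulli (logistic) hazard |
| `DeepHitSingle` | PMF over intervals, $\alpha\,L_{\text{lik}} + (1{-}\alpha)\,L_{\text{rank}}$ |
| `CoxTime` | case-control sampled partial likelihood with time-dependent score $g(t, x)$ |

Evaluation uses Antolini's time-dependent concordance index $C^{td}$ (1 =
perfect, 0.5 = chance) and the Graf integrated Brier score with
inverse-probability-of-censoring weights; both are implemented directly and
are tested against exhaustive pairwise oracles.

## Worked example

```python
import survtv

cohort = survtv.generate_cohort(survtv.GeneratorConfig(n_patients=800, seed=7))
print(survtv.cohort_summary(cohort))

table = survtv.compare_covariate_sets(
    cohort, ["logistic_hazard", "deepsurv", "deephit", "cox_time"],
    k=5, seed=11, estimator_overrides={"epochs": 40},
)
print(table[["ctd_fixed", "ctd_extended"]].round(3))
```

Output from this exact script:

```
{'n_patients': 800, 'n_entries': 12061, 'age_mean': 75.883, 'age_sd': 6.078,
 'comorbidity_mean': 1.621, 'comorbidity_sd': 2.616, 'event_fraction': 0.915,
 'means_defined': True}
                 ctd_fixed  ctd_extended
family
logistic_hazard      0.535         0.632
deepsurv             0.525         0.628
deephit              0.514         0.616
cox_time             0.537         0.612
```

The cohort reproduces the calibrated population moments (age ≈ 76,
comorbidity index ≈ 1.6, ~90 % observed deaths under the default hazard).
The comparison table shows the central finding the pipeline is built to
demonstrate: for every model family, extending the covariates with history
summaries raises the time-dependent concordance well beyond the time-fixed
baseline (here by ~0.08–0.10, several fold-SDs), because the generator's
hazard genuinely depends on the evolving history. Setting
`coef_timevarying={}` in the generator removes the effect, and the gap
vanishes — the improvement is signal, not artefact.

A command-line interface mirrors the library:

```bash
survtv simulate --out cohort/ --seed 1
survtv prepare --in cohort/ --mode extended --out data/
survtv fit --data data/ --family logistic_hazard --seed 1 --out model/
survtv evaluate --model model/ --data data/ --out report.json
survtv compare --out comparison/ --epochs 40 --seed 1
```

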