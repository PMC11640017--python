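"""Synthetic longitudinal claims-style cohort generator.

Emulates the structure of a linked cancer-registry / Medicare-claims cohort of
elderly women with metastatic (stage IV) breast cancer: time-fixed tumour and
demographic covariates at diagnosis, a monthly visit process carrying
treatment-class flags (chemotherapy / biotherapy / hormone therapy), 18
adverse-event category flags and an evolving comorbidity index, and a death
time driven by a *known* discrete-time logistic hazard.  Because the hazard
that generated each patient is recorded in the configuration, every downstream
model can be validated against ground truth — something the restricted real
data does not permit.

The data-generating process is the discrete-time analogue of a proportional
hazards model:

    h(t | x, H_t) = sigmoid( logit(h0) + beta_fixed' x + beta_tv' z(H_t) )

where ``h0`` is the baseline monthly event probability, ``x`` the time-fixed
covariates and ``z(H_t)`` history summaries (current comorbidity, cumulative
chemotherapy exposure, recent adverse events) computed from visits up to and
including month ``t``.  Survival is the product-limit of the monthly hazards,
``S(t) = prod_{s<=t} (1 - h(s))``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "TimeGrid",
    "generate_cohort",
    "true_survival_curve",
    "cohort_summary",
    "write_cohort",
    "read_cohort",
]

N_AE_CATEGORIES = 18

#: history-summary features the generator's hazard may depend on
TIMEVARYING_FEATURES = ("comorbidity", "cum_chemo", "recent_ae")

# default adverse-event probabilities per category, conditional on receiving
# any treatment that month (a few common toxicities, a long tail of rare ones)
_DEFAULT_AE_PROBS = (
    0.10, 0.08, 0.06, 0.05, 0.04, 0.04, 0.03, 0.03, 0.03,
    0.02, 0.02, 0.02, 0.02, 0.02, 0.01, 0.01, 0.01, 0.01,
)


@dataclass(frozen=True)
class TimeGrid:
    """Consecutive, left-closed monthly intervals indexed 0..n_intervals-1."""

    origin_label: str = "study start"
    n_intervals: int = 300
    interval_unit: str = "month"

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated to the published population moments of the cohort
    being emulated: age at diagnosis 76.0 +/- 7.5 years (left-truncated at the
    Medicare eligibility age of 65) and baseline comorbidity index 1.6 +/- 2.6
    (overdispersed, hence negative-binomial), on a 300-month study horizon.
    """

    n_patients: int = 2000
    age_mean: float = 76.0
    age_sd: float = 7.5
    age_floor: float = 65.0
    comorbidity_mean: float = 1.6
    comorbidity_sd: float = 2.6
    horizon_months: int = 300
    baseline_hazard_per_month: float = 0.015
    coef_fixed: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.02,          # per year above the configured mean
            "grade": 0.30,        # per grade above 2
            "er_positive": -0.30,
            "her2_positive": 0.15,
        }
    )
    coef_timevarying: Mapping[str, float] = field(
        default_factory=lambda: {
            "comorbidity": 0.35,  # per index point above the configured mean
            "cum_chemo": 0.10,    # per chemotherapy month received so far
            "recent_ae": 0.60,    # any adverse event in the last 3 months
        }
    )
    visit_rate_per_month: float = 0.5
    chemo_start_prob: float = 0.55
    chemo_halflife_months: float = 18.0
    bio_prob: float = 0.12
    hormone_base_prob: float = 0.25
    hormone_gain: float = 0.20
    ae_prob_given_treatment: Sequence[float] = _DEFAULT_AE_PROBS
    ae_background_prob: float = 0.01
    comorbidity_drift_prob: float = 0.08
    recent_ae_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")
        probs = [
            self.baseline_hazard_per_month,
            self.visit_rate_per_month,
            self.chemo_start_prob,
            self.bio_prob,
            self.hormone_base_prob,
            self.ae_background_prob,
            self.comorbidity_drift_prob,
            *self.ae_prob_given_treatment,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.ae_prob_given_treatment) != N_AE_CATEGORIES:
            raise ValueError(
                f"ae_prob_given_treatment must have {N_AE_CATEGORIES} entries"
            )
        unknown = set(self.coef_timevarying) - set(TIMEVARYING_FEATURES)
        if unknown:
            raise ValueError(f"unknown time-varying features: {sorted(unknown)}")

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(n_intervals=self.horizon_months)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["coef_fixed"] = dict(d["coef_fixed"])
        d["coef_timevarying"] = dict(d["coef_timevarying"])
        d["ae_prob_given_treatment"] = list(d["ae_prob_given_treatment"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "ae_prob_given_treatment" in d:
            d["ae_prob_given_treatment"] = tuple(d["ae_prob_given_treatment"])
        return cls(**d)


@dataclass
class Cohort:
    """A generated or loaded cohort.

    ``patients`` has one row per patient (patient_id, diagnosis_month,
    duration_months, event, fixed covariates, baseline comorbidity);
    ``visits`` one row per patient-month visit (treatment flags, 18
    adverse-event flags, comorbidity index).  ``config`` is retained when the
    cohort is synthetic so that the true hazard is available as an oracle.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    grid: TimeGrid
    config: GeneratorConfig | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_entries(self) -> int:
        return len(self.visits)


PATIENT_COLUMNS = [
    "patient_id", "diagnosis_month", "duration_months", "event",
    "age", "race", "er_positive", "pr_positive", "her2_positive",
    "grade", "histology", "comorbidity_baseline",
]
VISIT_COLUMNS = (
    ["patient_id", "month", "treat_chemo", "treat_bio", "treat_hormone"]
    + [f"ae_{k:02d}" for k in range(1, N_AE_CATEGORIES + 1)]
    + ["comorbidity_index"]
)


def _truncnorm_location(target_mean: float, sd: float, floor: float) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``floor``
    has mean ``target_mean``."""
    def gap(mu: float) -> float:
        a = (floor - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    return optimize.brentq(gap, target_mean - 10 * sd, target_mean + sd)


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    """(n, p) of a negative binomial with the given mean and SD (requires
    variance > mean, i.e. overdispersion)."""
    var = sd**2
    if var <= mean:
        raise ValueError("comorbidity SD must exceed the mean (overdispersion)")
    n = mean**2 / (var - mean)
    return n, n / (n + mean)


def fixed_linear_predictor(config: GeneratorConfig, fixed: Mapping[str, float]) -> float:
    """beta_fixed' x for one patient's time-fixed covariates."""
    feats = {
        "age": lambda: fixed["age"] - config.age_mean,
        "grade": lambda: fixed["grade"] - 2.0,
        "er_positive": lambda: float(fixed["er_positive"]),
        "pr_positive": lambda: float(fixed["pr_positive"]),
        "her2_positive": lambda: float(fixed["her2_positive"]),
        "race_black": lambda: float(fixed["race"] == 1),
    }
    return sum(b * feats[k]() for k, b in config.coef_fixed.items())


def history_linear_predictor(config: GeneratorConfig, summaries: Mapping[str, float]) -> float:
    """beta_tv' z for one month's history summaries.

    Recognised summaries: ``comorbidity`` (current index; centred at the
    configured mean internally), ``cum_chemo`` (months of chemotherapy so
    far), ``recent_ae`` (0/1: any adverse event within the recency window).
    """
    lp = 0.0
    for k, b in config.coef_timevarying.items():
        z = summaries.get(k, 0.0)
        if k == "comorbidity":
            z = z - config.comorbidity_mean
        lp += b * z
    return lp


def discrete_hazard(config: GeneratorConfig, lp_fixed: float, summaries: Mapping[str, float]) -> float:
    """Monthly event probability h(t) = sigmoid(logit(h0) + lp_fixed + lp_tv)."""
    h0 = config.baseline_hazard_per_month
    if h0 <= 0.0:
        return 0.0
    if h0 >= 1.0:
        return 1.0
    eta = math.log(h0 / (1.0 - h0)) + lp_fixed + history_linear_predictor(config, summaries)
    return 1.0 / (1.0 + math.exp(-eta))


def _sample_fixed_covariates(config: GeneratorConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    mu = _truncnorm_location(config.age_mean, config.age_sd, config.age_floor)
    a = (config.age_floor - mu) / config.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=config.age_sd, size=n, random_state=rng)
    nb_n, nb_p = _negbin_params(config.comorbidity_mean, config.comorbidity_sd)
    return pd.DataFrame(
        {
            "age": np.round(age, 1),
            "race": rng.choice(4, size=n, p=[0.82, 0.10, 0.04, 0.04]),
            "er_positive": rng.binomial(1, 0.70, size=n),
            "pr_positive": rng.binomial(1, 0.60, size=n),
            "her2_positive": rng.binomial(1, 0.15, size=n),
            "grade": rng.choice([1, 2, 3], size=n, p=[0.15, 0.45, 0.40]),
            "histology": rng.choice(3, size=n, p=[0.75, 0.12, 0.13]),
            "comorbidity_baseline": rng.negative_binomial(nb_n, nb_p, size=n).astype(float),
        }
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate a full cohort under the configured discrete hazard.

    Deterministic given ``config.seed``.  Each patient is diagnosed at a
    uniformly drawn study month and followed until death or administrative
    censoring at the study horizon.  Month 0 after diagnosis always carries a
    (baseline) visit; later months carry a visit with probability
    ``visit_rate_per_month``.  Treatments follow a simple phase policy
    (chemotherapy decays over time, hormone maintenance grows), adverse events
    occur conditional on same-month treatment, and the comorbidity index
    accumulates by a monotone random drift.  Death in month ``s >= 1`` is drawn
    from the logistic discrete hazard evaluated on the history *including*
    month ``s``'s visit, so a death and a visit may share a month.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return Cohort(
            patients=pd.DataFrame(columns=PATIENT_COLUMNS),
            visits=pd.DataFrame(columns=VISIT_COLUMNS),
            grid=config.grid,
            config=config,
        )

    fixed = _sample_fixed_covariates(config, rng, n)
    diagnosis = rng.integers(0, config.horizon_months, size=n)

    patients = []
    visit_rows: list[list] = []
    for i in range(n):
        row = fixed.iloc[i]
        lp_fixed = fixed_linear_predictor(config, row)
        censor_at = config.horizon_months - int(diagnosis[i])  # administrative

        comorbidity = float(row["comorbidity_baseline"])
        cum_chemo = 0
        ae_month_log: list[int] = []  # months (since diagnosis) with any AE

        def visit(s: int) -> None:
            nonlocal comorbidity, cum_chemo
            p_chemo = config.chemo_start_prob * 2.0 ** (-s / config.chemo_halflife_months)
            p_horm = config.hormone_base_prob + config.hormone_gain * (s / (s + 12.0))
            chemo = rng.random() < p_chemo
            bio = rng.random() < config.bio_prob
            horm = rng.random() < p_horm
            treated = chemo or bio or horm
            ae_p = np.asarray(config.ae_prob_given_treatment) if treated else config.ae_background_prob
            aes = (rng.random(N_AE_CATEGORIES) < ae_p).astype(int)
            if aes.any():
                ae_month_log.append(s)
            if rng.random() < config.comorbidity_drift_prob:
                comorbidity += 1.0
            cum_chemo += int(chemo)
            visit_rows.append(
                [i, int(diagnosis[i]) + s, int(chemo), int(bio), int(horm), *aes, comorbidity]
            )

        visit(0)
        duration, event = censor_at, 0
        # death is observable only strictly before the administrative
        # boundary; a tie at the boundary is recorded as censored
        for s in range(1, censor_at):
            if rng.random() < config.visit_rate_per_month:
                visit(s)
            recent = any(s - m < config.recent_ae_window for m in ae_month_log)
            h = discrete_hazard(
                config, lp_fixed,
                {"comorbidity": comorbidity, "cum_chemo": cum_chemo, "recent_ae": float(recent)},
            )
            if rng.random() < h:
                duration, event = s, 1
                break

        patients.append(
            [f"P{i:06d}", int(diagnosis[i]), duration, event, *row.tolist()]
        )

    patients_df = pd.DataFrame(patients, columns=PATIENT_COLUMNS)
    visits_df = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS)
    visits_df["patient_id"] = patients_df["patient_id"].to_numpy()[visits_df["patient_id"].to_numpy()]
    # drop visits simulated after an (unknown-at-the-time) death month
    keep = visits_df["month"].to_numpy() <= (
        patients_df.set_index("patient_id")
        .loc[visits_df["patient_id"], ["diagnosis_month", "duration_months"]]
        .sum(axis=1)
        .to_numpy()
    )
    visits_df = visits_df.loc[keep].reset_index(drop=True)
    return Cohort(patients=patients_df, visits=visits_df, grid=config.grid, config=config)


def true_survival_curve(
    config: GeneratorConfig,
    fixed_covariates: Mapping[str, float],
    treatment_history: Mapping[int, Mapping[str, float]] | None = None,
    n_months: int | None = None,
):
    """Ground-truth survival curve S(t) for a fully specified covariate path.

    ``treatment_history`` maps month-since-diagnosis -> history summaries
    (keys among ``comorbidity``, ``cum_chemo``, ``recent_ae``); months absent
    from the mapping reuse the most recent earlier entry (empty history means
    baseline throughout).  Returns a ``SurvivalCurve`` over months
    ``1..n_months`` with ``S(t) = prod_{s<=t} (1 - h(s))``.
    """
    from .metrics import SurvivalCurve  # local import to avoid a cycle

    history = dict(treatment_history or {})
    if n_months is None:
        n_months = config.horizon_months
    if history and max(history) > config.horizon_months:
        raise ValueError("history extends beyond the study horizon")
    lp_fixed = fixed_linear_predictor(config, fixed_covariates)
    current: Mapping[str, float] = {}
    surv, s_t = [], 1.0
    for s in range(1, n_months + 1):
        if s in history:
            current = history[s]
        s_t *= 1.0 - discrete_hazard(config, lp_fixed, current)
        surv.append(s_t)
    return SurvivalCurve(times=np.arange(1, n_months + 1, dtype=float), survival=np.asarray(surv))


def cohort_summary(cohort: Cohort) -> dict:
    """Population-characteristics summary: counts, age and baseline
    comorbidity moments, and the observed event fraction."""
    if cohort.n_patients == 0:
        return {
            "n_patients": 0, "n_entries": 0, "age_mean": float("nan"),
            "age_sd": float("nan"), "comorbidity_mean": float("nan"),
            "comorbidity_sd": float("nan"), "event_fraction": float("nan"),
            "means_defined": False,
        }
    p = cohort.patients
    return {
        "n_patients": int(cohort.n_patients),
        "n_entries": int(cohort.n_entries),
        "age_mean": float(p["age"].mean()),
        "age_sd": float(p["age"].std(ddof=1)) if len(p) > 1 else 0.0,
        "comorbidity_mean": float(p["comorbidity_baseline"].mean()),
        "comorbidity_sd": float(p["comorbidity_baseline"].std(ddof=1)) if len(p) > 1 else 0.0,
        "event_fraction": float(p["event"].mean()),
        "means_defined": True,
    }


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(out / "patients.csv", index=False)
    cohort.visits.to_csv(out / "visits.csv", index=False)


def read_cohort(in_dir: str | Path, grid: TimeGrid | None = None) -> Cohort:
    p = Path(in_dir)
    patients = pd.read_csv(p / "patients.csv")
    visits = pd.read_csv(p / "visits.csv")
    if grid is None:
        last = int((patients["diagnosis_month"] + patients["duration_months"]).max()) if len(patients) else 1
        grid = TimeGrid(n_intervals=max(last, 1))
    return Cohort(patients=patients, visits=visits, grid=grid)
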