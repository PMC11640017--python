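"""Timeline cleaning, bucketing, covariate extension and dataset encoding.

The central operation is the *extension* of a patient's covariate vector: at
any month m of follow-up, the time-fixed block (demographics and tumour
characteristics at diagnosis) is concatenated with history summaries computed
strictly from visits dated at or before m — cumulative treatment-class
counts, cumulative counts of each of the 18 adverse-event categories, the
most recent (bucketed) comorbidity index, months since diagnosis and months
since the last treatment.  The no-lookahead contract (visits after m can
never influence the vector at m) is what makes landmark-style prediction
honest.

Encoding turns a cohort into a model-ready matrix.  ``fixed_only`` emits one
row per patient carrying only the fixed block; ``extended`` emits one landmark
row per patient-visit-month (or, optionally, a single row at the last visit)
whose outcome is the *residual* time from the landmark to death/censoring.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .simulate import Cohort, N_AE_CATEGORIES, TimeGrid

__all__ = [
    "CodeMaps",
    "ExtendedCovariateVector",
    "EncodedDataset",
    "load_code_maps",
    "clean_records",
    "bucket_continuous",
    "extend_covariates",
    "encode_dataset",
    "write_dataset",
    "read_dataset",
]

DEFAULT_AGE_BOUNDARIES = (65.0, 70.0, 75.0, 80.0, 85.0)
DEFAULT_COMORBIDITY_BOUNDARIES = (0.0, 1.0, 2.0, 3.0, 5.0, 8.0)
NO_TREATMENT_SENTINEL = -1.0

FIXED_FEATURES = [
    "age_bucket", "race", "er_positive", "pr_positive",
    "her2_positive", "grade", "histology",
]
_TREATMENTS = ["chemo", "bio", "hormone"]


@dataclass(frozen=True)
class CodeMaps:
    """Claims-code lookup tables: ICD-9 adverse-event codes -> 18 categories,
    HCPCS J codes -> treatment class (82 chemotherapy / 49 biotherapy / 10
    hormone therapy).  Shipped as editable fixture tables; the cardinalities
    are enforced, the membership is illustrative."""

    ae_map: pd.DataFrame
    drug_map: pd.DataFrame

    def __post_init__(self):
        cats = set(self.ae_map["category_index"])
        if cats != set(range(1, N_AE_CATEGORIES + 1)):
            raise ValueError(f"ae_map must cover exactly categories 1..{N_AE_CATEGORIES}")
        counts = self.drug_map["drug_class"].value_counts()
        expected = {"chemotherapy": 82, "biotherapy": 49, "hormone": 10}
        if counts.to_dict() != expected:
            raise ValueError(f"drug_map class counts must be {expected}, got {counts.to_dict()}")

    def ae_category(self, icd9_code: str) -> int:
        hit = self.ae_map.loc[self.ae_map["icd9_code"] == icd9_code, "category_index"]
        if hit.empty:
            raise KeyError(icd9_code)
        return int(hit.iloc[0])

    def drug_class(self, hcpcs_code: str) -> str:
        hit = self.drug_map.loc[self.drug_map["hcpcs_code"] == hcpcs_code, "drug_class"]
        if hit.empty:
            raise KeyError(hcpcs_code)
        return str(hit.iloc[0])


def load_code_maps(ae_path: str | Path | None = None, drug_path: str | Path | None = None) -> CodeMaps:
    data = importlib.resources.files("survtv") / "data"
    ae = pd.read_csv(ae_path if ae_path else str(data / "ae_map.csv"), dtype={"icd9_code": str})
    drug = pd.read_csv(drug_path if drug_path else str(data / "drug_map.csv"), dtype={"hcpcs_code": str})
    return CodeMaps(ae_map=ae, drug_map=drug)


@dataclass(frozen=True)
class ExtendedCovariateVector:
    values: np.ndarray
    names: tuple
    n_fixed: int  # the first n_fixed entries are the time-fixed block
    as_of_month: int

    @property
    def fixed_block(self) -> np.ndarray:
        return self.values[: self.n_fixed]

    @property
    def history_block(self) -> np.ndarray:
        return self.values[self.n_fixed:]

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


@dataclass
class EncodedDataset:
    """Model-ready matrix plus outcome columns and bookkeeping.

    ``durations`` are integer month indices on ``grid`` (residual time from
    the landmark for extended encodings); ``events`` are 0/1.  ``patient_ids``
    and ``landmark_months`` identify the source row so cross-validation can
    split by patient and evaluation can pick one landmark per patient.
    Standardization parameters, when fitted, are stored per feature.
    """

    features: np.ndarray
    durations: np.ndarray
    events: np.ndarray
    feature_names: tuple
    grid: TimeGrid
    patient_ids: np.ndarray
    landmark_months: np.ndarray
    mode: str = "fixed_only"
    standardization: dict | None = None

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, mask: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            features=self.features[mask],
            durations=self.durations[mask],
            events=self.events[mask],
            feature_names=self.feature_names,
            grid=self.grid,
            patient_ids=self.patient_ids[mask],
            landmark_months=self.landmark_months[mask],
            mode=self.mode,
            standardization=self.standardization,
        )

    def fit_standardizer(self) -> "EncodedDataset":
        """Fit per-feature mean/scale on this (training) data and return a
        standardized copy carrying the parameters."""
        mean = self.features.mean(axis=0)
        sd = self.features.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        out = self.subset(np.ones(len(self), dtype=bool))
        out.standardization = {"mean": mean, "scale": sd}
        out.features = (self.features - mean) / sd
        return out

    def apply_standardizer(self, params: dict) -> "EncodedDataset":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.standardization = params
        out.features = (self.features - params["mean"]) / params["scale"]
        return out


def clean_records(cohort: Cohort) -> tuple[Cohort, dict]:
    """Deduplicate and validate a cohort; always succeeds.

    Duplicate (patient_id, month) visit rows are collapsed to one (union of
    binary flags, last comorbidity value); visits outside a patient's
    observation window are dropped; patients with negative or missing
    durations are dropped along with their visits.  Returns the cleaned
    cohort and a removal report.  Idempotent.
    """
    patients = cohort.patients.copy()
    visits = cohort.visits.copy()
    report = {"duplicate_visits": 0, "out_of_window_visits": 0, "invalid_patients": 0}

    bad = patients["duration_months"].isna() | (patients["duration_months"] < 0)
    report["invalid_patients"] = int(bad.sum())
    patients = patients.loc[~bad].reset_index(drop=True)
    visits = visits[visits["patient_id"].isin(patients["patient_id"])]

    n_before = len(visits)
    flag_cols = [c for c in visits.columns if c.startswith(("treat_", "ae_"))]
    agg = {c: "max" for c in flag_cols}
    agg["comorbidity_index"] = "last"
    visits = (
        visits.sort_values(["patient_id", "month"], kind="stable")
        .groupby(["patient_id", "month"], as_index=False, sort=True)
        .agg(agg)
    )
    report["duplicate_visits"] = n_before - len(visits)

    window = patients.set_index("patient_id")
    lo = window["diagnosis_month"].reindex(visits["patient_id"]).to_numpy()
    hi = (window["diagnosis_month"] + window["duration_months"]).reindex(visits["patient_id"]).to_numpy()
    in_window = (visits["month"].to_numpy() >= lo) & (visits["month"].to_numpy() <= hi)
    report["out_of_window_visits"] = int((~in_window).sum())
    visits = visits.loc[in_window].reset_index(drop=True)

    cols = [c for c in cohort.visits.columns]
    visits = visits[[c for c in cols if c in visits.columns]]
    return Cohort(patients=patients, visits=visits, grid=cohort.grid, config=cohort.config), report


def bucket_continuous(value, boundaries) -> np.ndarray | int:
    """Half-open bucketing: index i for values in [b_i, b_{i+1}); values below
    the first boundary map to 0 and values at/above the last boundary to the
    last bucket."""
    boundaries = np.asarray(boundaries, dtype=float)
    if boundaries.size == 0:
        raise ValueError("boundaries must be nonempty")
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly ascending")
    idx = np.searchsorted(boundaries, np.asarray(value, dtype=float), side="right") - 1
    idx = np.clip(idx, 0, boundaries.size - 1)
    return idx if np.ndim(value) else int(idx)


def history_feature_names() -> list[str]:
    return (
        [f"cum_{t}" for t in _TREATMENTS]
        + [f"cum_ae_{k:02d}" for k in range(1, N_AE_CATEGORIES + 1)]
        + ["comorbidity_bucket", "months_since_diagnosis", "months_since_last_treatment"]
    )


def extend_covariates(
    cohort: Cohort,
    patient_id: str,
    as_of_month: int,
    age_boundaries=DEFAULT_AGE_BOUNDARIES,
    comorbidity_boundaries=DEFAULT_COMORBIDITY_BOUNDARIES,
) -> ExtendedCovariateVector:
    """Covariate vector for one patient as of a given (absolute) study month.

    History summaries use only visits with month <= as_of_month.  With no
    visit yet, cumulative counts are zero, the comorbidity bucket falls back
    to the baseline value and months-since-last-treatment is a sentinel (-1).
    """
    rows = cohort.patients.loc[cohort.patients["patient_id"] == patient_id]
    if rows.empty:
        raise KeyError(f"unknown patient {patient_id!r}")
    patient = rows.iloc[0]
    if as_of_month < patient["diagnosis_month"]:
        raise ValueError("as_of_month precedes diagnosis")

    fixed_vals = [
        float(bucket_continuous(patient["age"], age_boundaries)),
        float(patient["race"]),
        float(patient["er_positive"]),
        float(patient["pr_positive"]),
        float(patient["her2_positive"]),
        float(patient["grade"]),
        float(patient["histology"]),
    ]

    v = cohort.visits
    hist = v[(v["patient_id"] == patient_id) & (v["month"] <= as_of_month)]
    cum_treat = [float(hist[f"treat_{t}"].sum()) for t in _TREATMENTS]
    cum_ae = [float(hist[f"ae_{k:02d}"].sum()) for k in range(1, N_AE_CATEGORIES + 1)]
    if len(hist):
        last = hist.sort_values("month").iloc[-1]
        comorb = float(last["comorbidity_index"])
    else:
        comorb = float(patient["comorbidity_baseline"])
    treated = hist[(hist[[f"treat_{t}" for t in _TREATMENTS]].sum(axis=1) > 0)]
    since_treat = (
        float(as_of_month - treated["month"].max()) if len(treated) else NO_TREATMENT_SENTINEL
    )
    history_vals = cum_treat + cum_ae + [
        float(bucket_continuous(comorb, comorbidity_boundaries)),
        float(as_of_month - patient["diagnosis_month"]),
        since_treat,
    ]
    names = tuple(FIXED_FEATURES + history_feature_names())
    return ExtendedCovariateVector(
        values=np.asarray(fixed_vals + history_vals, dtype=float),
        names=names,
        n_fixed=len(fixed_vals),
        as_of_month=int(as_of_month),
    )


def _fixed_matrix(patients: pd.DataFrame, age_boundaries) -> np.ndarray:
    return np.column_stack(
        [
            bucket_continuous(patients["age"].to_numpy(), age_boundaries),
            patients["race"].to_numpy(float),
            patients["er_positive"].to_numpy(float),
            patients["pr_positive"].to_numpy(float),
            patients["her2_positive"].to_numpy(float),
            patients["grade"].to_numpy(float),
            patients["histology"].to_numpy(float),
        ]
    )


def encode_dataset(
    cohort: Cohort,
    mode: Literal["fixed_only", "extended"],
    landmark_policy: Literal["per_visit", "last"] = "per_visit",
    age_boundaries=DEFAULT_AGE_BOUNDARIES,
    comorbidity_boundaries=DEFAULT_COMORBIDITY_BOUNDARIES,
) -> EncodedDataset:
    """Encode a (clean) cohort as a feature matrix with outcomes.

    fixed_only: one row per patient, fixed block only, full observed duration.
    extended: one landmark row per patient per visit month (default) carrying
    the extended covariate vector as of that month, with the residual duration
    from the landmark as outcome; ``landmark_policy='last'`` keeps only the
    final visit row per patient.
    """
    if mode not in ("fixed_only", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    patients = cohort.patients.reset_index(drop=True)
    grid = cohort.grid

    if mode == "fixed_only":
        X = _fixed_matrix(patients, age_boundaries)
        return EncodedDataset(
            features=X,
            durations=patients["duration_months"].to_numpy(int),
            events=patients["event"].to_numpy(int),
            feature_names=tuple(FIXED_FEATURES),
            grid=grid,
            patient_ids=patients["patient_id"].to_numpy(),
            landmark_months=patients["diagnosis_month"].to_numpy(int),
            mode=mode,
        )

    # extended: vectorised history accumulation over the visits table
    v = cohort.visits.sort_values(["patient_id", "month"], kind="stable").reset_index(drop=True)
    flag_cols = [f"treat_{t}" for t in _TREATMENTS] + [
        f"ae_{k:02d}" for k in range(1, N_AE_CATEGORIES + 1)
    ]
    grp = v.groupby("patient_id", sort=False)
    cum = grp[flag_cols].cumsum()
    p_idx = patients.set_index("patient_id")
    diag = p_idx["diagnosis_month"].reindex(v["patient_id"]).to_numpy()
    dur = p_idx["duration_months"].reindex(v["patient_id"]).to_numpy()
    ev = p_idx["event"].reindex(v["patient_id"]).to_numpy()

    any_treat = v[[f"treat_{t}" for t in _TREATMENTS]].sum(axis=1) > 0
    last_treat_month = (
        v["month"].where(any_treat).groupby(v["patient_id"], sort=False).ffill().to_numpy()
    )
    since_treat = np.where(
        np.isnan(last_treat_month), NO_TREATMENT_SENTINEL, v["month"].to_numpy() - last_treat_month
    )

    fixed_block = _fixed_matrix(p_idx.reindex(v["patient_id"]).reset_index(), age_boundaries)
    history_block = np.column_stack(
        [
            cum.to_numpy(float),
            bucket_continuous(v["comorbidity_index"].to_numpy(float), comorbidity_boundaries),
            v["month"].to_numpy(float) - diag,
            since_treat,
        ]
    )
    X = np.concatenate([fixed_block, history_block], axis=1)
    residual = (diag + dur - v["month"].to_numpy()).astype(int)

    keep = np.ones(len(v), dtype=bool)
    if landmark_policy == "last":
        keep = ~v.duplicated("patient_id", keep="last").to_numpy()
    elif landmark_policy != "per_visit":
        raise ValueError(f"unknown landmark_policy {landmark_policy!r}")

    return EncodedDataset(
        features=X[keep],
        durations=residual[keep],
        events=ev[keep].astype(int),
        feature_names=tuple(FIXED_FEATURES + history_feature_names()),
        grid=grid,
        patient_ids=v["patient_id"].to_numpy()[keep],
        landmark_months=v["month"].to_numpy(int)[keep],
        mode="extended",
    )


def write_dataset(ds: EncodedDataset, out_dir: str | Path) -> None:
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(ds.features, columns=list(ds.feature_names))
    df.insert(0, "patient_id", ds.patient_ids)
    df.insert(1, "landmark_month", ds.landmark_months)
    df["duration"] = ds.durations
    df["event"] = ds.events
    df.to_csv(out / "dataset.csv", index=False)
    meta = {
        "feature_names": list(ds.feature_names),
        "mode": ds.mode,
        "grid": {"origin_label": ds.grid.origin_label, "n_intervals": ds.grid.n_intervals,
                 "interval_unit": ds.grid.interval_unit},
        "standardization": None
        if ds.standardization is None
        else {k: np.asarray(val).tolist() for k, val in ds.standardization.items()},
    }
    (out / "dataset_meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(in_dir: str | Path) -> EncodedDataset:
    import json

    p = Path(in_dir)
    meta = json.loads((p / "dataset_meta.json").read_text())
    df = pd.read_csv(p / "dataset.csv")
    names = meta["feature_names"]
    std = meta["standardization"]
    return EncodedDataset(
        features=df[names].to_numpy(float),
        durations=df["duration"].to_numpy(int),
        events=df["event"].to_numpy(int),
        feature_names=tuple(names),
        grid=TimeGrid(**meta["grid"]),
        patient_ids=df["patient_id"].to_numpy(),
        landmark_months=df["landmark_month"].to_numpy(int),
        mode=meta["mode"],
        standardization=None if std is None else {k: np.asarray(v) for k, v in std.items()},
    )
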