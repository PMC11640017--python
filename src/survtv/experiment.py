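"""Experiment orchestration: patient-level cross-validation, hyperparameter
search, the time-fixed vs. extended covariate comparison and per-patient
survival-curve prediction.

Cross-validation always partitions *patients*, never landmark rows: all
landmark rows of a test patient are excluded from training and from the
standardization fit, so no information leaks across the fold boundary.  A
master seed fans out through ``numpy.random.SeedSequence`` into independent
per-fold / per-configuration seeds, making every experiment reproducible
end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .metrics import MetricReport, ctd_index, integrated_brier_score, summarize_folds
from .models import HYPERPARAMETER_SPACE, HazardModelConfig
from .prep import EncodedDataset, clean_records, encode_dataset
from .simulate import Cohort

__all__ = [
    "SearchSpace",
    "crossvalidate",
    "tune",
    "compare_covariate_sets",
    "fit_cohort_model",
    "predict_patient_curves",
    "write_manifest",
]


def _derive_seeds(master: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass(frozen=True)
class SearchSpace:
    """The tuning domains (categorical sets, an integer range for layers and
    a continuous learning-rate range)."""

    domains: Mapping[str, tuple] = field(default_factory=lambda: dict(HYPERPARAMETER_SPACE))

    def sample(self, family: str, rng: np.random.Generator, seed: int = 0) -> HazardModelConfig:
        d = self.domains
        lo, hi = d["learning_rate"]
        # learning rate is sampled log-uniformly over its continuous range
        lr = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return HazardModelConfig(
            family=family,
            n_layers=int(rng.integers(d["n_layers"][0], d["n_layers"][1] + 1)),
            n_nodes=int(rng.choice(d["n_nodes"])),
            dropout=float(rng.choice(d["dropout"])),
            batch_size=int(rng.choice(d["batch_size"])),
            epochs=int(rng.choice(d["epochs"])),
            learning_rate=lr,
            alpha=float(rng.choice(d["alpha"])),
            sigma=float(rng.choice(d["sigma"])),
            seed=seed,
        )


def _first_landmark_rows(ds: EncodedDataset) -> np.ndarray:
    """Boolean mask keeping each patient's earliest landmark row."""
    df = pd.DataFrame({"pid": ds.patient_ids, "month": ds.landmark_months})
    first = df.groupby("pid")["month"].transform("min")
    mask = (df["month"] == first).to_numpy()
    # guard against duplicate first months (cleaned cohorts cannot have them)
    dup = df[mask].duplicated("pid").to_numpy()
    if dup.any():
        keep = np.flatnonzero(mask)
        mask[keep[dup]] = False
    return mask


def _build_estimator(family: str, config, seed: int, n_intervals: int,
                     overrides: Mapping | None):
    overrides = dict(overrides or {})
    if isinstance(config, HazardModelConfig):
        return config.build_estimator(n_intervals=n_intervals, seed=seed, **overrides)
    params = dict(config or {})
    params.update(overrides)
    params.setdefault("n_intervals", n_intervals)
    params["seed"] = seed
    cfg = HazardModelConfig(family=family)
    return cfg.build_estimator(**params)


def crossvalidate(
    cohort: Cohort,
    mode: str,
    family: str,
    config: HazardModelConfig | Mapping | None = None,
    k: int = 5,
    seed: int = 0,
    eval_landmark: str = "first",
    n_intervals: int = 50,
    estimator_overrides: Mapping | None = None,
) -> tuple[MetricReport, list[dict]]:
    """Patient-level k-fold cross-validation of one family in one mode.

    Returns a summary :class:`MetricReport` and the per-fold records.  For
    extended encodings, held-out metrics are computed on one landmark row per
    test patient (the earliest by default; ``eval_landmark='all'`` evaluates
    every landmark row).  Folds whose training or test split contains no
    event are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    clean, _ = clean_records(cohort)
    ds = encode_dataset(clean, mode=mode)
    pids = clean.patients["patient_id"].to_numpy()
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold_seeds = _derive_seeds(seed, k)

    folds = []
    for fold, (tr_p, te_p) in enumerate(kf.split(pids)):
        train_ids = set(pids[tr_p])
        test_ids = set(pids[te_p])
        tr_mask = np.fromiter((p in train_ids for p in ds.patient_ids), bool, len(ds))
        te_mask = np.fromiter((p in test_ids for p in ds.patient_ids), bool, len(ds))
        if ds.mode == "extended" and eval_landmark == "first":
            te_mask &= _first_landmark_rows(ds)

        train = ds.subset(tr_mask)
        test = ds.subset(te_mask)
        if train.events.sum() == 0 or test.events.sum() == 0:
            warnings.warn(f"fold {fold}: no events in a split; skipped")
            continue
        train_std = train.fit_standardizer()
        test_std = test.apply_standardizer(train_std.standardization)

        est = _build_estimator(family, config, fold_seeds[fold], n_intervals,
                               estimator_overrides)
        est.fit(train_std.features, (train_std.durations, train_std.events))
        S = est.predict_survival_function(test_std.features)
        times = est.event_times_
        ctd = ctd_index(S, test_std.durations, test_std.events, times=times)
        ibs = integrated_brier_score(S, test_std.durations, test_std.events, times=times)
        folds.append({"fold": fold, "ctd": ctd, "ibs": ibs,
                      "n_test": int(len(te_p)), "seed": fold_seeds[fold]})
    if not folds:
        raise RuntimeError("every fold was skipped (no events)")
    report = summarize_folds([f["ctd"] for f in folds], [f["ibs"] for f in folds])
    return report, folds


def tune(
    cohort: Cohort,
    family: str,
    space: SearchSpace | None = None,
    budget: int = 10,
    scheme: str = "random",
    seed: int = 0,
    k: int = 5,
    mode: str = "extended",
    n_intervals: int = 50,
    estimator_overrides: Mapping | None = None,
) -> tuple[HazardModelConfig, pd.DataFrame]:
    """Hyperparameter search by mean cross-validated concordance.

    ``scheme='random'`` samples ``budget`` configurations independently;
    ``scheme='model_based'`` spends half the budget at random, then proposes
    each remaining candidate by drawing several random configurations and
    keeping the one closest (in normalised hyperparameter space) to the
    top-quantile configurations of the trace so far — a deliberately simple
    sequential surrogate.  Ties break toward the earliest evaluated
    configuration.  Returns the best configuration and the full trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if scheme not in ("random", "model_based"):
        raise ValueError("scheme must be 'random' or 'model_based'")
    space = space or SearchSpace()
    if not space.domains:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    cfg_seeds = _derive_seeds(seed + 1, budget)

    trace_rows, configs = [], []
    n_random = budget if scheme == "random" else max(1, budget // 2)
    for b in range(budget):
        if b < n_random:
            cfg = space.sample(family, rng, seed=cfg_seeds[b])
        else:
            cfg = _propose_near_best(space, family, rng, cfg_seeds[b],
                                     configs, [r["mean_ctd"] for r in trace_rows])
        try:
            report, _ = crossvalidate(cohort, mode, family, cfg, k=k, seed=seed,
                                      n_intervals=n_intervals,
                                      estimator_overrides=estimator_overrides)
            mean_ctd = report.ctd_mean
        except RuntimeError as exc:  # diverged (non-finite loss) or degenerate
            warnings.warn(f"configuration {b} failed: {exc}")
            mean_ctd = float("nan")
        configs.append(cfg)
        row = {"config_index": b, "mean_ctd": mean_ctd}
        row.update({f: getattr(cfg, f) for f in
                    ("n_layers", "n_nodes", "dropout", "batch_size", "epochs",
                     "learning_rate", "alpha", "sigma")})
        trace_rows.append(row)

    trace = pd.DataFrame(trace_rows)
    scores = trace["mean_ctd"].to_numpy()
    finite = np.where(np.isfinite(scores), scores, -np.inf)
    best = int(np.argmax(finite))  # argmax keeps the first of tied maxima
    return configs[best], trace


def _config_coords(cfg: HazardModelConfig, space: SearchSpace) -> np.ndarray:
    d = space.domains
    lo, hi = d["learning_rate"]
    return np.array([
        (cfg.n_layers - d["n_layers"][0]) / max(d["n_layers"][1] - d["n_layers"][0], 1),
        d["n_nodes"].index(cfg.n_nodes) / (len(d["n_nodes"]) - 1),
        d["dropout"].index(cfg.dropout) / (len(d["dropout"]) - 1),
        d["batch_size"].index(cfg.batch_size) / (len(d["batch_size"]) - 1),
        d["epochs"].index(cfg.epochs) / (len(d["epochs"]) - 1),
        (np.log(cfg.learning_rate) - np.log(lo)) / (np.log(hi) - np.log(lo)),
    ])


def _propose_near_best(space, family, rng, seed, configs, scores):
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if not finite.any():
        return space.sample(family, rng, seed=seed)
    cut = np.nanquantile(scores[finite], 0.75)
    top = [c for c, s in zip(configs, scores) if np.isfinite(s) and s >= cut]
    candidates = [space.sample(family, rng, seed=seed) for _ in range(8)]
    top_coords = np.stack([_config_coords(c, space) for c in top])
    dists = [
        float(np.min(np.linalg.norm(top_coords - _config_coords(c, space), axis=1)))
        for c in candidates
    ]
    return candidates[int(np.argmin(dists))]


def compare_covariate_sets(
    cohort: Cohort,
    families: Sequence[str],
    config_per_family: Mapping[str, HazardModelConfig | Mapping] | None = None,
    k: int = 5,
    seed: int = 0,
    n_intervals: int = 50,
    estimator_overrides: Mapping | None = None,
) -> pd.DataFrame:
    """Concordance and IBS for every family under both covariate encodings.

    One row per family with mean +/- fold-SD columns for each (metric,
    encoding) pair.  A family whose run fails is flagged in an ``error``
    column; the others are still returned.
    """
    config_per_family = config_per_family or {}
    rows = []
    seeds = _derive_seeds(seed, 2 * len(families))
    for fi, family in enumerate(families):
        row: dict = {"family": family, "error": ""}
        cfg = config_per_family.get(family)
        for mi, mode in enumerate(("fixed_only", "extended")):
            tag = "fixed" if mode == "fixed_only" else "extended"
            try:
                report, folds = crossvalidate(
                    cohort, mode, family, cfg, k=k, seed=seeds[2 * fi + mi],
                    n_intervals=n_intervals, estimator_overrides=estimator_overrides,
                )
                row[f"ctd_{tag}"] = report.ctd_mean
                row[f"ctd_{tag}_sd"] = report.ctd_sd
                row[f"ibs_{tag}"] = report.ibs_mean
                row[f"ibs_{tag}_sd"] = report.ibs_sd
                row[f"n_folds_{tag}"] = len(folds)
            except (RuntimeError, ValueError) as exc:
                row["error"] = f"{mode}: {exc}"
                for col in (f"ctd_{tag}", f"ctd_{tag}_sd", f"ibs_{tag}", f"ibs_{tag}_sd"):
                    row[col] = float("nan")
                row[f"n_folds_{tag}"] = 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("family")


def fit_cohort_model(
    cohort: Cohort,
    mode: str,
    family: str,
    config: HazardModelConfig | Mapping | None = None,
    seed: int = 0,
    n_intervals: int = 50,
    estimator_overrides: Mapping | None = None,
) -> dict:
    """Fit one model on the whole cohort; returns a bundle carrying the
    estimator, the standardization parameters and the encoding mode, which
    is what per-patient prediction needs."""
    clean, _ = clean_records(cohort)
    ds = encode_dataset(clean, mode=mode).fit_standardizer()
    est = _build_estimator(family, config, seed, n_intervals, estimator_overrides)
    est.fit(ds.features, (ds.durations, ds.events))
    est.feature_names_ = ds.feature_names
    return {"estimator": est, "standardization": ds.standardization,
            "mode": mode, "cohort_grid": clean.grid}


def predict_patient_curves(
    bundle: dict, cohort: Cohort, patient_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-patient survival curves and median survival.

    For extended-mode bundles each patient is represented by their *latest*
    landmark (full history).  Median survival is the first grid time with
    S(t) <= 0.5; patients whose curve never crosses 0.5 get a null median
    with ``median_defined = False``.  Returns a long-format frame
    (patient_id, time, survival) joined with a per-patient median table in
    ``DataFrame.attrs['medians']``.
    """
    clean, _ = clean_records(cohort)
    ds = encode_dataset(clean, mode=bundle["mode"])
    est = bundle["estimator"]
    rows, medians = [], []
    for pid in patient_ids:
        mask = ds.patient_ids == pid
        if not mask.any():
            raise KeyError(f"unknown patient {pid!r}")
        idx = np.flatnonzero(mask)
        if bundle["mode"] == "extended":
            idx = idx[np.argmax(ds.landmark_months[idx])]
        else:
            idx = idx[0]
        x = (ds.features[idx] - bundle["standardization"]["mean"]) / bundle[
            "standardization"]["scale"]
        curve = est.predict_survival_curves(x.reshape(1, -1))[0]
        med = curve.median()
        medians.append({"patient_id": pid, "median_survival_months": med,
                        "median_defined": med is not None})
        rows.extend(
            {"patient_id": pid, "time": float(t), "survival": float(s)}
            for t, s in zip(curve.times, curve.survival)
        )
    out = pd.DataFrame(rows)
    out.attrs["medians"] = pd.DataFrame(medians)
    return out


def write_manifest(path: str | Path, **entries) -> None:
    """Record configuration, seeds and package version for a run."""
    from . import __version__

    payload = {"survtv_version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
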