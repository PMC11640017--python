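"""Deep survival models: estimators, losses and checkpoint I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..metrics import SurvivalCurve
from ..prep import EncodedDataset
from .config import FAMILIES, HYPERPARAMETER_SPACE, HazardModelConfig
from .estimators import CoxTime, DeepHitSingle, DeepSurv, LogisticHazardNet
from .losses import loss_cox_time, loss_deephit, loss_deepsurv, loss_logistic_hazard

__all__ = [
    "DeepSurv", "DeepHitSingle", "LogisticHazardNet", "CoxTime",
    "HazardModelConfig", "FAMILIES", "HYPERPARAMETER_SPACE",
    "loss_deepsurv", "loss_deephit", "loss_logistic_hazard", "loss_cox_time",
    "fit", "predict_survival", "save_model", "load_model",
]

_FAMILY_OF = {
    DeepSurv: "deepsurv",
    DeepHitSingle: "deephit",
    LogisticHazardNet: "logistic_hazard",
    CoxTime: "cox_time",
}


def fit(dataset: EncodedDataset, config: HazardModelConfig, n_intervals: int = 50):
    """Train the configured family on an encoded dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot fit on an empty dataset")
    est = config.build_estimator(n_intervals=n_intervals)
    est.fit(dataset.features, (dataset.durations, dataset.events))
    est.feature_names_ = dataset.feature_names
    return est


def predict_survival(model, x) -> SurvivalCurve:
    """Survival curve for a single covariate vector."""
    values = np.asarray(getattr(x, "values", x), dtype=float).reshape(1, -1)
    return model.predict_survival_curves(values)[0]


def save_model(model, out_dir) -> None:
    """Checkpoint: weight blob plus JSON metadata (and, for the proportional
    hazards family, the baseline cumulative hazard as CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    family = _FAMILY_OF[type(model)]
    arrays = {f"W{i}": w for i, w in enumerate(model.net_.W)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.net_.b)})
    arrays["time_grid"] = model.time_grid_
    if family == "deepsurv":
        import pandas as pd

        pd.DataFrame({
            "time": model.baseline_event_times_,
            "cumulative_hazard": model.baseline_cumhaz_,
        }).to_csv(out / "baseline_hazard.csv", index=False)
        arrays["score_shift"] = np.array([model._score_shift])
    if family == "cox_time":
        arrays["baseline_increments"] = model.baseline_increments_
        arrays["train_X"] = model._train_X
        arrays["train_durations"] = model._train_durations
    np.savez(out / "weights.npz", **arrays)
    meta = {
        "family": family,
        "params": {k: v for k, v in model.get_params().items()},
        "n_features_in": int(model.n_features_in_),
        "feature_names": list(getattr(model, "feature_names_", [])),
        "t_scale": float(model.t_scale_),
    }
    (out / "model_meta.json").write_text(json.dumps(meta, indent=2, default=float))


def load_model(in_dir):
    import pandas as pd

    p = Path(in_dir)
    meta = json.loads((p / "model_meta.json").read_text())
    cls = {v: k for k, v in _FAMILY_OF.items()}[meta["family"]]
    model = cls(**meta["params"])
    blob = np.load(p / "weights.npz")
    model.time_grid_ = blob["time_grid"]
    model.t_scale_ = meta["t_scale"]
    model.n_features_in_ = meta["n_features_in"]
    model.feature_names_ = tuple(meta["feature_names"])
    n_in = meta["n_features_in"] + (1 if cls is CoxTime else 0)
    from ._mlp import MLP

    model.net_ = MLP(n_in, 1, model.n_layers, model.n_nodes, model.dropout,
                     np.random.default_rng(0))
    k = len([key for key in blob.files if key.startswith("W")])
    model.net_.W = [blob[f"W{i}"] for i in range(k)]
    model.net_.b = [blob[f"b{i}"] for i in range(k)]
    if meta["family"] == "deepsurv":
        tbl = pd.read_csv(p / "baseline_hazard.csv")
        model.baseline_event_times_ = tbl["time"].to_numpy(float)
        model.baseline_cumhaz_ = tbl["cumulative_hazard"].to_numpy(float)
        model._score_shift = float(blob["score_shift"][0])
    if meta["family"] == "cox_time":
        model.baseline_increments_ = blob["baseline_increments"]
        model._train_X = blob["train_X"]
        model._train_durations = blob["train_durations"]
    return model
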