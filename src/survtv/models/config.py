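"""Hyperparameter configuration validated against the tuning search space."""

from __future__ import annotations

from dataclasses import dataclass

from .estimators import CoxTime, DeepHitSingle, DeepSurv, LogisticHazardNet

__all__ = ["HazardModelConfig", "FAMILIES", "HYPERPARAMETER_SPACE"]

FAMILIES = ("deepsurv", "deephit", "logistic_hazard", "cox_time")

_ESTIMATORS = {
    "deepsurv": DeepSurv,
    "deephit": DeepHitSingle,
    "logistic_hazard": LogisticHazardNet,
    "cox_time": CoxTime,
}

#: the tuning domains: categorical sets, an integer range for layers and a
#: continuous range for the learning rate
HYPERPARAMETER_SPACE = {
    "batch_size": (32, 64, 128, 256, 512),
    "epochs": (100, 200, 300, 500),
    "dropout": (0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    "n_layers": (2, 5),          # inclusive integer range
    "n_nodes": (32, 64, 128, 256, 512),
    "alpha": (0.0, 0.001, 0.1, 0.2, 0.5, 0.8, 0.9, 0.99, 1.0),
    "sigma": (0.01, 0.1, 0.25, 0.5, 1.0, 10, 100),
    "learning_rate": (0.0001, 0.1),  # continuous range
}


@dataclass(frozen=True)
class HazardModelConfig:
    """A point in the hyperparameter search space for one model family.

    ``alpha`` (likelihood/ranking trade-off) and ``sigma`` (ranking kernel
    width) only apply to the DeepHit family and are ignored elsewhere.
    """

    family: str
    n_layers: int = 2
    n_nodes: int = 64
    dropout: float = 0.1
    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 0.01
    alpha: float = 0.5
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        sp = HYPERPARAMETER_SPACE
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not sp["n_layers"][0] <= self.n_layers <= sp["n_layers"][1]:
            raise ValueError("n_layers outside the search range")
        for name in ("n_nodes", "dropout", "batch_size", "epochs", "alpha", "sigma"):
            if getattr(self, name) not in sp[name]:
                raise ValueError(f"{name}={getattr(self, name)} not in the search set")
        lo, hi = sp["learning_rate"]
        if not lo <= self.learning_rate <= hi:
            raise ValueError("learning_rate outside the search range")

    def build_estimator(self, n_intervals: int = 50, **overrides):
        kwargs = dict(
            n_layers=self.n_layers, n_nodes=self.n_nodes, dropout=self.dropout,
            batch_size=self.batch_size, epochs=self.epochs,
            learning_rate=self.learning_rate, n_intervals=n_intervals,
            seed=self.seed,
        )
        if self.family == "deephit":
            kwargs.update(alpha=self.alpha, sigma=self.sigma)
        kwargs.update(overrides)
        return _ESTIMATORS[self.family](**kwargs)
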