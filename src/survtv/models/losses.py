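"""The four survival objectives, as pure array functions.

These are the reference definitions the estimators train against; they are
written for clarity and testability, not speed.  Conventions:

* ``loss_deepsurv`` — mean negative Cox partial log-likelihood of per-row
  risk scores g(x), Breslow handling of ties (tied event times share the
  full risk set).
* ``loss_logistic_hazard`` — mean Bernoulli negative log-likelihood of
  per-interval discrete hazards: a subject surviving intervals 0..T-1 and
  then dying (event) or being censored (no event) in interval T.
* ``loss_deephit`` — convex combination alpha * likelihood + (1 - alpha) *
  ranking of a discrete event-time probability mass function; the ranking
  term sums exp(-(F_i(T_i) - F_j(T_i)) / sigma) over comparable pairs.
* ``loss_cox_time`` — case-control sampled partial likelihood for scores
  that may depend on time, log-sum-exp over each event plus sampled
  controls from its risk set.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "loss_deepsurv",
    "loss_logistic_hazard",
    "loss_deephit",
    "loss_cox_time",
]

EPS = 1e-7


def loss_deepsurv(scores, durations, events) -> float:
    """Mean negative Cox partial log-likelihood (Breslow ties).

    For each event row i: -g(x_i) + log sum_{j: T_j >= T_i} exp(g(x_j)).
    Invariant to adding a constant to all scores.  Returns 0 (with a
    warning) when no row has an event.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    ev_idx = np.flatnonzero(events == 1)
    if ev_idx.size == 0:
        warnings.warn("no events: partial likelihood is 0 by convention")
        return 0.0
    total = 0.0
    smax = scores.max()
    for i in ev_idx:
        risk = durations >= durations[i]
        lse = smax + np.log(np.sum(np.exp(scores[risk] - smax)))
        total += -scores[i] + lse
    return float(total / ev_idx.size)


def loss_logistic_hazard(hazards, durations, events, eps: float = EPS) -> float:
    """Mean discrete-time Bernoulli NLL.

    -sum_{t<T} log(1-h_t) - D log(h_T) - (1-D) log(1-h_T), per row, meaned.
    Hazards exactly 0 at an event interval (or 1 at a survived one) are
    clamped to ``eps`` and flagged.
    """
    h = np.atleast_2d(np.asarray(hazards, dtype=float))
    durations = np.asarray(durations, dtype=int)
    events = np.asarray(events, dtype=int)
    n, k = h.shape
    if np.any(durations < 0) or np.any(durations >= k):
        raise ValueError("durations must index hazard intervals")
    clamped = False
    total = 0.0
    for i in range(n):
        t = durations[i]
        surv_h = h[i, :t]
        final_h = h[i, t]
        need_clamp = (events[i] == 1 and final_h <= 0.0) or (
            events[i] == 0 and final_h >= 1.0
        ) or np.any(surv_h >= 1.0)
        clamped = clamped or need_clamp
        surv_h = np.clip(surv_h, 0.0, 1.0 - eps)
        if events[i] == 1:
            final_h = np.clip(final_h, eps, 1.0)
        else:
            final_h = np.clip(final_h, 0.0, 1.0 - eps)
        ll = np.sum(np.log1p(-surv_h))
        ll += np.log(final_h) if events[i] == 1 else np.log1p(-final_h)
        total += -ll
    if clamped:
        warnings.warn("degenerate hazards clamped by epsilon")
    return float(total / n)


def loss_deephit(pmf, durations, events, alpha: float, sigma: float) -> float:
    """Likelihood/ranking trade-off for a discrete event-time PMF.

    ``pmf`` rows are probabilities over K intervals; the survival remainder
    is 1 - sum(pmf row).  Likelihood: mean over rows of -log f(T) for events
    and -log S(T) for censored rows, with S(T) = 1 - F(T) and F the running
    cumulative of the PMF.  Ranking: sum over comparable pairs (i an event,
    T_i < T_j, or T_i = T_j with j censored) of
    exp(-(F_i(T_i) - F_j(T_i)) / sigma).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    f = np.atleast_2d(np.asarray(pmf, dtype=float))
    durations = np.asarray(durations, dtype=int)
    events = np.asarray(events, dtype=int)
    if np.any(f < -1e-12) or np.any(f.sum(axis=1) > 1.0 + 1e-9):
        raise ValueError("pmf rows must be nonnegative with total <= 1")
    n, k = f.shape
    F = np.cumsum(f, axis=1)

    lik = 0.0
    for i in range(n):
        t = durations[i]
        if events[i] == 1:
            lik -= np.log(max(f[i, t], EPS))
        else:
            lik -= np.log(max(1.0 - F[i, t], EPS))
    lik /= n

    rank = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            comparable = durations[j] > durations[i] or (
                durations[j] == durations[i] and events[j] == 0
            )
            if comparable:
                rank += np.exp(-(F[i, durations[i]] - F[j, durations[i]]) / sigma)
    return float(alpha * lik + (1.0 - alpha) * rank)


def loss_cox_time(score_fn, X, durations, events, n_control_samples: int = 1,
                  seed: int = 0) -> float:
    """Sampled partial-likelihood loss for time-dependent risk scores.

    For each event i, controls are drawn without replacement from the risk
    set {j != i : T_j >= T_i} (the whole risk set when it is smaller than the
    requested sample); the contribution is
    log sum_{j in {i} u controls} exp(g(T_i, x_j) - g(T_i, x_i)), meaned over
    events.  Deterministic given ``seed``.  Events whose risk set contains no
    other subject contribute 0 (flagged).
    """
    if n_control_samples < 1:
        raise ValueError("n_control_samples must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    rng = np.random.default_rng(seed)
    ev_idx = np.flatnonzero(events == 1)
    total, n_used = 0.0, 0
    empty = False
    for i in ev_idx:
        risk = np.flatnonzero((durations >= durations[i]))
        risk = risk[risk != i]
        if risk.size == 0:
            empty = True
            total += 0.0
            n_used += 1
            continue
        if n_control_samples >= risk.size:
            controls = risk
        else:
            controls = rng.choice(risk, size=n_control_samples, replace=False)
        gi = float(score_fn(durations[i], X[i]))
        diffs = np.array([float(score_fn(durations[i], X[j])) - gi for j in controls])
        total += np.logaddexp.reduce(np.concatenate([[0.0], diffs]))
        n_used += 1
    if empty:
        warnings.warn("some events had empty risk sets and contributed 0")
    if n_used == 0:
        return 0.0
    return float(total / n_used)
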