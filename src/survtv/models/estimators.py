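"""Scikit-learn-style deep survival estimators.

Four objectives over a shared fully connected network:

* :class:`DeepSurv` — Cox partial likelihood (Breslow ties) on a
  time-constant risk score g(x), with a Breslow baseline cumulative hazard
  estimated on the training data, so h(t|x) = h0(t) exp(g(x)).
* :class:`LogisticHazardNet` — discrete-time logistic hazard (Nnet-survival
  style): per-interval conditional event probabilities trained with the
  Bernoulli likelihood; S(t) = prod_{s<=t} (1 - h_s).
* :class:`DeepHitSingle` — a probability mass function over intervals plus a
  survival remainder, trained with alpha * likelihood + (1 - alpha) *
  ranking (kernel width sigma); single event, no competing risks.
* :class:`CoxTime` — a relative-risk score g(t, x) that may depend on time,
  trained with a case-control sampled partial likelihood and predicted
  through Breslow-type baseline increments scored at each grid time.

All estimators accept ``fit(X, y)`` with ``y`` either a ``(durations,
events)`` tuple, an (n, 2) array, or a structured array with ``event`` /
``time`` fields (scikit-survival convention).  Durations are continuous
(months); discrete-output families coarsen them onto an internal grid of
``n_intervals`` interval endpoints placed at quantiles of the observed
training durations — the monthly grid remains the data-level truth.
Training is deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ..metrics import SurvivalCurve
from ._mlp import MLP, Adam

__all__ = ["DeepSurv", "LogisticHazardNet", "DeepHitSingle", "CoxTime"]


def _unpack_y(y):
    if isinstance(y, tuple) and len(y) == 2:
        d, e = y
    elif hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        ename = "event" if "event" in names else names[0]
        tname = "time" if "time" in names else names[1]
        d, e = y[tname], y[ename]
    else:
        arr = np.asarray(y)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("y must be (durations, events), an (n,2) array, "
                             "or a structured event/time array")
        d, e = arr[:, 0], arr[:, 1]
    return np.asarray(d, dtype=float), np.asarray(e, dtype=int)


def _quantile_grid(durations: np.ndarray, n_intervals: int) -> np.ndarray:
    """Ascending interval endpoints at duration quantiles (always ending at
    the maximum observed duration; strictly positive first endpoint)."""
    qs = np.linspace(0.0, 1.0, n_intervals + 1)[1:]
    cuts = np.unique(np.quantile(durations, qs))
    cuts = cuts[cuts > 0]
    if cuts.size == 0:
        cuts = np.array([max(durations.max(), 1.0)])
    return cuts.astype(float)


class BaseSurvivalNet(BaseEstimator):
    """Shared training scaffold; subclasses define the output head and the
    gradient of their loss with respect to the network outputs."""

    _time_input = False  # CoxTime appends a time column to the network input

    def __init__(self, n_layers=2, n_nodes=32, dropout=0.1, batch_size=256,
                 epochs=100, learning_rate=0.01, n_intervals=50, seed=0,
                 early_stopping=False, validation_fraction=0.1, patience=10,
                 verbose=0):
        self.n_layers = n_layers
        self.n_nodes = n_nodes
        self.dropout = dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.n_intervals = n_intervals
        self.seed = seed
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.verbose = verbose

    # -- subclass hooks -----------------------------------------------------
    def _n_outputs(self) -> int:
        raise NotImplementedError

    def _batch_loss_grad(self, out, d, e, rng):
        """(loss, dL/dout) for one minibatch."""
        raise NotImplementedError

    def _post_fit(self, X, durations, events):
        pass

    # -- training -----------------------------------------------------------
    def fit(self, X, y):
        X = check_array(X, dtype=float)
        durations, events = _unpack_y(y)
        if len(durations) != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)

        self.time_grid_ = _quantile_grid(durations, self.n_intervals)
        self.t_scale_ = float(max(self.time_grid_[-1], 1.0))
        d_idx = np.searchsorted(self.time_grid_, durations, side="left")
        d_idx = np.clip(d_idx, 0, self.time_grid_.size - 1)
        self._d_idx = d_idx

        n_in = X.shape[1] + (1 if self._time_input else 0)
        self.net_ = MLP(n_in, self._n_outputs(), self.n_layers, self.n_nodes,
                        self.dropout, rng)
        opt = Adam(self.net_.params(), lr=self.learning_rate)

        n = X.shape[0]
        if self.early_stopping and n >= 20:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            tr_idx, val_idx = np.arange(n), np.array([], dtype=int)

        best_val, best_params, stall = np.inf, None, 0
        self.training_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, order.size, self.batch_size):
                idx = order[start:start + self.batch_size]
                if idx.size < 2:
                    continue
                loss, gW, gb = self._train_step(X, idx, rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: lower the learning "
                        f"rate (currently {self.learning_rate})"
                    )
                opt.step(self.net_.params(), gW + gb)
                epoch_loss += loss
                n_batches += 1
            mean_loss = epoch_loss / max(n_batches, 1)
            self.training_log_.append(mean_loss)
            if val_idx.size:
                val_loss, _, _ = self._eval_loss(X, val_idx, rng)
                if val_loss < best_val - 1e-6:
                    best_val, stall = val_loss, 0
                    best_params = [p.copy() for p in self.net_.params()]
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_params is not None:
            self.net_.set_flat(best_params)

        self._post_fit(X, durations, events)
        del self._d_idx
        return self

    def _net_input(self, X, d=None):
        if not self._time_input:
            return X
        t = np.asarray(d, dtype=float).reshape(-1, 1) / self.t_scale_
        return np.concatenate([X, t], axis=1)

    def _train_step(self, X, idx, rng):
        xb = self._net_input(X[idx], self._grid_times(idx))
        out, cache = self.net_.forward(xb, training=True, rng=rng)
        loss, dout = self._batch_loss_grad(out, self._grid_times(idx),
                                           self._events_of(idx), rng)
        gW, gb = self.net_.backward(cache, dout)
        return loss, gW, gb

    def _eval_loss(self, X, idx, rng):
        xb = self._net_input(X[idx], self._grid_times(idx))
        out, _ = self.net_.forward(xb, training=False)
        loss, _ = self._batch_loss_grad(out, self._grid_times(idx),
                                        self._events_of(idx), rng)
        return loss, None, None

    def _grid_times(self, idx):
        return self._d_idx[idx]

    def _events_of(self, idx):
        return self._events[idx]

    # -- prediction ---------------------------------------------------------
    def predict_survival_function(self, X) -> np.ndarray:
        """Survival probabilities, shape (n, len(event_times_))."""
        raise NotImplementedError

    @property
    def event_times_(self) -> np.ndarray:
        check_is_fitted(self, "time_grid_")
        return self.time_grid_

    def predict_survival_curves(self, X) -> list[SurvivalCurve]:
        S = self.predict_survival_function(X)
        return [SurvivalCurve(times=self.event_times_, survival=s) for s in S]

    def predict(self, X) -> np.ndarray:
        """Risk score: negative expected survival time (area under S)."""
        S = self.predict_survival_function(X)
        dt = np.diff(np.concatenate([[0.0], self.event_times_]))
        return -(S * dt).sum(axis=1)


def _softplusish_check(X, n_features):
    if X.shape[1] != n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {n_features}, got {X.shape[1]}"
        )


class LogisticHazardNet(BaseSurvivalNet):
    """Discrete-time logistic (Bernoulli) hazard network."""

    def _n_outputs(self):
        return self.time_grid_.size

    def fit(self, X, y):
        _, events = _unpack_y(y)
        self._events = events
        return super().fit(X, y)

    def _batch_loss_grad(self, out, d, e, rng):
        n, k = out.shape
        h = 1.0 / (1.0 + np.exp(-out))
        cols = np.arange(k)
        mask = cols[None, :] <= d[:, None]
        target = np.zeros_like(h)
        target[np.arange(n), d] = e
        eps = 1e-7
        hc = np.clip(h, eps, 1 - eps)
        nll = -(target * np.log(hc) + (1 - target) * np.log1p(-hc)) * mask
        loss = nll.sum() / n
        dout = (h - target) * mask / n
        return loss, dout

    def predict_hazard(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        _softplusish_check(X, self.n_features_in_)
        out, _ = self.net_.forward(X)
        return 1.0 / (1.0 + np.exp(-out))

    def predict_survival_function(self, X) -> np.ndarray:
        h = self.predict_hazard(X)
        return np.cumprod(1.0 - h, axis=1)


class DeepHitSingle(BaseSurvivalNet):
    """Single-event DeepHit: softmax PMF over intervals + survival remainder.

    ``alpha`` trades likelihood (1.0) against ranking (0.0); ``sigma`` is the
    ranking kernel width.  The ranking term is averaged over comparable pairs
    within each minibatch so its scale is batch-size independent.
    """

    def __init__(self, n_layers=2, n_nodes=32, dropout=0.1, batch_size=256,
                 epochs=100, learning_rate=0.01, n_intervals=50, seed=0,
                 early_stopping=False, validation_fraction=0.1, patience=10,
                 verbose=0, alpha=0.5, sigma=1.0):
        super().__init__(n_layers=n_layers, n_nodes=n_nodes, dropout=dropout,
                         batch_size=batch_size, epochs=epochs,
                         learning_rate=learning_rate, n_intervals=n_intervals,
                         seed=seed, early_stopping=early_stopping,
                         validation_fraction=validation_fraction,
                         patience=patience, verbose=verbose)
        self.alpha = alpha
        self.sigma = sigma

    def _n_outputs(self):
        return self.time_grid_.size + 1  # K intervals + survival remainder

    def fit(self, X, y):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        _, events = _unpack_y(y)
        self._events = events
        return super().fit(X, y)

    def _batch_loss_grad(self, out, d, e, rng):
        z = out - out.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        loss, dp = self._loss_grad_wrt_pmf(p, d, e)
        # softmax chain rule: dL/dz = p * (dL/dp - <dL/dp, p>)
        dout = p * (dp - (dp * p).sum(axis=1, keepdims=True))
        return loss, dout

    def _loss_grad_wrt_pmf(self, p, d, e):
        """Combined loss and its gradient with respect to the PMF rows."""
        n, km = p.shape
        k = km - 1
        f, F = p[:, :k], np.cumsum(p[:, :k], axis=1)
        eps = 1e-7
        rows = np.arange(n)
        cols = np.arange(k)
        ev = e == 1
        ft = f[rows, d]
        St = 1.0 - F[rows, d]

        lik = (-np.sum(np.log(np.maximum(ft[ev], eps)))
               - np.sum(np.log(np.maximum(St[~ev], eps)))) / n
        dlik = np.zeros_like(p)
        dlik[rows[ev], d[ev]] = -1.0 / np.maximum(ft[ev], eps) / n
        if (~ev).any():
            inv = 1.0 / np.maximum(St[~ev], eps) / n
            gt_mask = (cols[None, :] > d[~ev, None]).astype(float)
            dlik[~ev, :k] = -inv[:, None] * gt_mask
            dlik[~ev, k] = -inv

        comp = (d[None, :] > d[:, None]) | ((d[None, :] == d[:, None]) & (e[None, :] == 0))
        comp &= ev[:, None]
        np.fill_diagonal(comp, False)
        n_pairs = int(comp.sum())
        rank = 0.0
        drank = np.zeros_like(p)
        if n_pairs > 0:
            Fi = F[rows, d][:, None]
            Fj = F[:, d].T
            A = np.exp(-(Fi - Fj) / self.sigma) * comp
            rank = A.sum() / n_pairs
            dFi = -A.sum(axis=1) / (self.sigma * n_pairs)
            dFj_mat = A / (self.sigma * n_pairs)
            le_mask = (cols[None, :] <= d[:, None]).astype(float)
            drank[:, :k] = dFi[:, None] * le_mask + dFj_mat.T @ le_mask
        loss = self.alpha * lik + (1.0 - self.alpha) * rank
        return loss, self.alpha * dlik + (1.0 - self.alpha) * drank

    def predict_pmf(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        _softplusish_check(X, self.n_features_in_)
        out, _ = self.net_.forward(X)
        z = out - out.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def predict_survival_function(self, X) -> np.ndarray:
        p = self.predict_pmf(X)
        k = p.shape[1] - 1
        S = 1.0 - np.cumsum(p[:, :k], axis=1)
        return np.clip(S, 0.0, 1.0)


class DeepSurv(BaseSurvivalNet):
    """Cox proportional hazards with a neural risk score and Breslow baseline."""

    def _n_outputs(self):
        return 1

    def fit(self, X, y):
        durations, events = _unpack_y(y)
        self._events = events
        self._durations = durations
        return super().fit(X, y)

    @staticmethod
    def _cox_loss_grad(scores, d, e):
        """Mean negative partial log-likelihood and its gradient (Breslow)."""
        n = scores.size
        order = np.argsort(d, kind="stable")
        s_ord, d_ord, e_ord = scores[order], d[order], e[order]
        smax = s_ord.max()
        exp_s = np.exp(s_ord - smax)
        suffix = np.cumsum(exp_s[::-1])[::-1]  # sum_{j: pos >= i} exp
        # Breslow: risk set of an event at time t starts at the first
        # position of t's tie group
        first_pos = np.searchsorted(d_ord, d_ord, side="left")
        denom = suffix[first_pos]  # scaled by exp(-smax)
        ev = e_ord == 1
        nev = int(ev.sum())
        if nev == 0:
            return 0.0, np.zeros(n)
        loss = np.sum(-(s_ord[ev] - smax) + np.log(denom[ev])) / nev
        # gradient: dL/ds_j = exp(s_j) * sum_{events i: j in risk_i} 1/denom_i
        #                     - 1[event_j], all / nev
        inv = np.where(ev, 1.0 / denom, 0.0)
        # event i covers positions >= first_pos[i]; accumulate via prefix sums
        # over tie-group starts
        cover = np.zeros(n + 1)
        np.add.at(cover, first_pos[ev], inv[ev])
        cover = np.cumsum(cover[:-1])
        grad_ord = (exp_s * cover - ev) / nev
        grad = np.empty(n)
        grad[order] = grad_ord
        return float(loss), grad

    def _train_step(self, X, idx, rng):
        xb = X[idx]
        out, cache = self.net_.forward(xb, training=True, rng=rng)
        scores = out[:, 0]
        loss, gs = self._cox_loss_grad(scores, self._durations[idx], self._events[idx])
        gW, gb = self.net_.backward(cache, gs[:, None])
        return loss, gW, gb

    def _eval_loss(self, X, idx, rng):
        out, _ = self.net_.forward(X[idx], training=False)
        loss, _ = self._cox_loss_grad(out[:, 0], self._durations[idx], self._events[idx])
        return loss, None, None

    def _post_fit(self, X, durations, events):
        # Breslow baseline cumulative hazard on the full training set
        out, _ = self.net_.forward(X, training=False)
        scores = out[:, 0]
        scores = scores - scores.mean()  # identifiability: centre the score
        self._score_shift = float(out[:, 0].mean())
        order = np.argsort(durations, kind="stable")
        d_ord, e_ord, s_ord = durations[order], events[order], scores[order]
        exp_s = np.exp(s_ord)
        suffix = np.cumsum(exp_s[::-1])[::-1]
        uniq, start = np.unique(d_ord, return_index=True)
        denom = suffix[start]
        d_count = np.add.reduceat(e_ord, start)
        increments = d_count / denom
        keep = d_count > 0
        self.baseline_event_times_ = uniq[keep]
        self.baseline_cumhaz_ = np.cumsum(increments[keep])

    def predict(self, X) -> np.ndarray:
        """Centred risk score g(x); higher means higher hazard."""
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        _softplusish_check(X, self.n_features_in_)
        out, _ = self.net_.forward(X)
        return out[:, 0] - self._score_shift

    def predict_survival_function(self, X) -> np.ndarray:
        g = self.predict(X)
        idx = np.searchsorted(self.baseline_event_times_, self.time_grid_, side="right")
        H0 = np.concatenate([[0.0], self.baseline_cumhaz_])[idx]
        return np.exp(-np.outer(np.exp(g), H0))


class CoxTime(BaseSurvivalNet):
    """Relative-risk model whose score g(t, x) depends on time.

    Trained with a sampled case-control partial likelihood: each event is
    compared against ``n_control_samples`` controls drawn from its risk set,
    all scored at the event's time.  Prediction uses Breslow-type baseline
    increments with the training subjects rescored at every grid time.
    """

    _time_input = True

    def __init__(self, n_layers=2, n_nodes=32, dropout=0.1, batch_size=256,
                 epochs=100, learning_rate=0.01, n_intervals=50, seed=0,
                 early_stopping=False, validation_fraction=0.1, patience=10,
                 verbose=0, n_control_samples=2):
        super().__init__(n_layers=n_layers, n_nodes=n_nodes, dropout=dropout,
                         batch_size=batch_size, epochs=epochs,
                         learning_rate=learning_rate, n_intervals=n_intervals,
                         seed=seed, early_stopping=early_stopping,
                         validation_fraction=validation_fraction,
                         patience=patience, verbose=verbose)
        self.n_control_samples = n_control_samples

    def _n_outputs(self):
        return 1

    def fit(self, X, y):
        durations, events = _unpack_y(y)
        self._events = events
        self._durations = durations
        self._sort_idx = np.argsort(durations, kind="stable")
        self._sorted_d = durations[self._sort_idx]
        self._rank_of = np.empty_like(self._sort_idx)
        self._rank_of[self._sort_idx] = np.arange(durations.size)
        return super().fit(X, y)

    def _score(self, X, t, training=False, rng=None):
        t = np.broadcast_to(np.asarray(t, dtype=float), (X.shape[0],))
        inp = np.concatenate([X, (t / self.t_scale_)[:, None]], axis=1)
        out, cache = self.net_.forward(inp, training=training, rng=rng)
        return out[:, 0], cache

    def _zero_grads(self):
        return ([np.zeros_like(w) for w in self.net_.W],
                [np.zeros_like(b) for b in self.net_.b])

    def _train_step(self, X, idx, rng):
        d_b, e_b = self._durations[idx], self._events[idx]
        ev_local = np.flatnonzero(e_b == 1)
        if ev_local.size == 0:
            zW, zb = self._zero_grads()
            return 0.0, zW, zb
        n_all = self._sorted_d.size
        gi = idx[ev_local]
        t_i = d_b[ev_local]
        pos = np.searchsorted(self._sorted_d, t_i, side="left")
        navail = n_all - pos  # risk-set size including the case itself
        usable = navail >= 2
        if not usable.any():
            zW, zb = self._zero_grads()
            return 0.0, zW, zb
        gi, t_i, pos, navail = gi[usable], t_i[usable], pos[usable], navail[usable]
        nev = gi.size
        m = self.n_control_samples
        # controls: uniform positions in the risk set, self-collisions bumped
        ctrl_pos = pos[:, None] + (rng.random((nev, m)) * navail[:, None]).astype(int)
        self_pos = self._rank_of[gi][:, None]
        alt = np.where(pos[:, None] == self_pos, pos[:, None] + 1, pos[:, None])
        ctrl_pos = np.where(ctrl_pos == self_pos, alt, ctrl_pos)
        ctrl_idx = self._sort_idx[ctrl_pos]  # (nev, m) global indices

        members = np.concatenate([gi[:, None], ctrl_idx], axis=1)  # (nev, m+1)
        ts = np.repeat(t_i, m + 1)
        scores, cache = self._score(X[members.ravel()], ts, training=True, rng=rng)
        G = scores.reshape(nev, m + 1)
        z = G - G.max(axis=1, keepdims=True)
        w = np.exp(z)
        w /= w.sum(axis=1, keepdims=True)
        # log sum_j exp(g_j - g_case) per event
        loss = float(np.mean(np.log(np.sum(np.exp(G - G[:, :1]), axis=1))))
        dG = w / nev
        dG[:, 0] -= 1.0 / nev
        gW, gb = self.net_.backward(cache, dG.reshape(-1, 1))
        return loss, gW, gb

    def _eval_loss(self, X, idx, rng):
        # validation uses the same sampled objective with a fixed stream
        loss, _, _ = self._train_step(X, idx, np.random.default_rng(self.seed + 1))
        return loss, None, None

    def _post_fit(self, X, durations, events):
        self._train_X = X
        self._train_durations = durations
        # Breslow-type increments on the coarse grid, rescoring the risk set
        # of each grid time at that time
        edges = np.concatenate([[0.0], self.time_grid_])
        increments = np.zeros(self.time_grid_.size)
        for k, t_k in enumerate(self.time_grid_):
            d_k = int(np.sum((durations > edges[k]) & (durations <= t_k) & (events == 1)))
            if d_k == 0:
                continue
            at_risk = durations > edges[k]
            if not at_risk.any():
                continue
            g, _ = self._score(X[at_risk], t_k)
            gmax = g.max()
            increments[k] = d_k / (np.exp(gmax) * np.sum(np.exp(g - gmax)))
        self.baseline_increments_ = increments

    def predict_survival_function(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        _softplusish_check(X, self.n_features_in_)
        n = X.shape[0]
        H = np.zeros((n, self.time_grid_.size))
        for k, t_k in enumerate(self.time_grid_):
            if self.baseline_increments_[k] == 0.0:
                continue
            g, _ = self._score(X, t_k)
            H[:, k] = self.baseline_increments_[k] * np.exp(g)
        return np.exp(-np.cumsum(H, axis=1))
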