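"""Metric correctness against hand computations, brute-force oracles and
independent implementations (lifelines, scikit-survival)."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as harrell_c

from survtv import (
    SurvivalCurve,
    brier_score,
    ctd_index,
    integrated_brier_score,
    km_estimator,
    summarize_folds,
)
from conftest import random_survival_matrix


def brute_force_ctd(times, S, durations, events):
    """Exhaustive O(n^2) pairwise oracle for the time-dependent concordance."""

    def s_at(i, t):
        idx = np.searchsorted(times, t, side="right")
        return 1.0 if idx == 0 else S[i, idx - 1]

    conc = total = 0.0
    n = len(durations)
    for i in range(n):
        for j in range(n):
            if i == j or events[i] != 1:
                continue
            if not (durations[i] < durations[j]
                    or (durations[i] == durations[j] and events[j] == 0)):
                continue
            si, sj = s_at(i, durations[i]), s_at(j, durations[i])
            total += 1
            conc += 1.0 if si < sj else (0.5 if si == sj else 0.0)
    return conc / total


def brute_force_brier(times, S, durations, events, t, G):
    """Fully enumerated IPCW weighted sum at one time t."""
    total = 0.0
    for i in range(len(durations)):
        s_i = 1.0 if t < times[0] else S[i, np.searchsorted(times, t, side="right") - 1]
        if durations[i] <= t and events[i] == 1:
            total += s_i**2 / G.left_limit(durations[i])
        elif durations[i] > t:
            total += (1.0 - s_i) ** 2 / float(G(t))
    return total / len(durations)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimator([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.values, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_constant_one(self):
        km = km_estimator([4, 9], [0, 0])
        assert float(km(100)) == 1.0

    def test_censoring_distribution_by_hand(self):
        # flipped indicators on {(2, event), (3, censored), (5, event)}:
        # G has its only drop at t=3 where 2 remain at risk -> 1/2
        G = km_estimator([2, 3, 5], [0, 1, 0])
        assert float(G(2.5)) == 1.0
        assert float(G(3)) == 0.5
        assert float(G(10)) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([], [])

    def test_matches_lifelines_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(2, 25)
            d = rng.integers(1, 15, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            km = km_estimator(d, e)
            ll = KaplanMeierFitter().fit(d, e)
            grid = np.arange(0, 16, dtype=float)
            ours = km(grid)
            theirs = ll.survival_function_at_times(grid).to_numpy()
            assert np.allclose(ours, theirs, atol=1e-12)


class TestCtdIndex:
    def test_perfect_oracle_scores_one(self):
        times = np.arange(1.0, 11.0)
        durations = np.arange(1.0, 6.0)
        events = np.ones(5, dtype=int)
        # curve ordering strictly inverse to event time at every grid point
        S = np.array([np.full(10, 0.1 * (k + 1)) for k in range(5)])
        S = np.minimum.accumulate(S, axis=1)
        assert ctd_index(S, durations, events, times=times) == 1.0

    def test_reversed_oracle_scores_zero(self):
        times = np.arange(1.0, 11.0)
        durations = np.arange(1.0, 6.0)
        events = np.ones(5, dtype=int)
        S = np.array([np.full(10, 1.0 - 0.1 * (k + 1)) for k in range(5)])
        assert ctd_index(S, durations, events, times=times) == 0.0

    def test_matches_brute_force_on_censored_toy(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        S = np.array([
            [0.9, 0.7, 0.5, 0.3],
            [0.8, 0.6, 0.5, 0.4],
            [0.95, 0.9, 0.85, 0.8],
            [0.5, 0.4, 0.3, 0.2],
        ])
        durations = np.array([2.0, 3.0, 3.0, 1.0])
        events = np.array([1, 0, 1, 1])
        got = ctd_index(S, durations, events, times=times)
        assert got == pytest.approx(brute_force_ctd(times, S, durations, events), abs=1e-15)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        times = np.arange(1.0, 13.0)
        S = random_survival_matrix(rng, 15, times)
        d = rng.integers(1, 12, size=15).astype(float)
        e = rng.integers(0, 2, size=15)
        e[:5] = 1
        base = ctd_index(S, d, e, times=times)
        assert ctd_index(S**2, d, e, times=times) == pytest.approx(base, abs=1e-15)
        assert ctd_index(np.sqrt(S), d, e, times=times) == pytest.approx(base, abs=1e-15)

    def test_equals_harrell_for_proportional_curves(self):
        # crossing-free curves S_i(t) = S0(t)^exp(r_i) on uncensored data
        rng = np.random.default_rng(6)
        n = 40
        r = rng.normal(size=n)
        times = np.arange(1.0, 31.0)
        S0 = np.cumprod(np.full(30, 0.93))
        S = S0[None, :] ** np.exp(r)[:, None]
        d = rng.integers(1, 30, size=n).astype(float)
        e = np.ones(n, dtype=int)
        ours = ctd_index(S, d, e, times=times)
        theirs = harrell_c(d, -r, e)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            ctd_index(np.array([[0.5], [0.4]]), [1.0, 1.0], [0, 0], times=[1.0])

    def test_accepts_curve_objects(self):
        curves = [
            SurvivalCurve(times=np.array([1.0, 2.0]), survival=np.array([0.9, 0.5])),
            SurvivalCurve(times=np.array([1.0, 2.0]), survival=np.array([0.5, 0.2])),
        ]
        assert ctd_index(curves, [2.0, 1.0], [1, 1]) == 1.0


class TestBrierScore:
    def test_perfect_step_predictions_zero(self):
        times = np.arange(1.0, 6.0)
        durations = np.array([2.0, 4.0])
        events = np.array([1, 1])
        S = np.array([(times < d).astype(float) for d in durations])
        G = km_estimator(durations, 1 - events)
        for t in (1.0, 2.5, 3.0):
            assert brier_score(S, durations, events, t, G, times=times) == 0.0

    def test_constant_half_scores_quarter(self):
        times = np.arange(1.0, 6.0)
        durations = np.array([2.0, 4.0, 5.0])
        events = np.array([1, 1, 1])
        S = np.full((3, 5), 0.5)
        G = km_estimator(durations, 1 - events)
        assert brier_score(S, durations, events, 3.0, G, times=times) == pytest.approx(0.25)

    def test_censored_toy_matches_hand_enumeration(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        durations = np.array([2.0, 3.0, 5.0])
        events = np.array([1, 0, 1])
        rng = np.random.default_rng(7)
        S = random_survival_matrix(rng, 3, times)
        G = km_estimator(durations, 1 - events)
        for t in (1.0, 2.0, 3.5, 4.0):
            got = brier_score(S, durations, events, t, G, times=times)
            want = brute_force_brier(times, S, durations, events, t, G)
            assert got == pytest.approx(want, abs=1e-15)

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(8)
        times = np.arange(1.0, 9.0)
        for _ in range(25):
            n = rng.integers(3, 20)
            S = random_survival_matrix(rng, n, times)
            d = rng.integers(1, 8, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            G = km_estimator(d, 1 - e)
            t = float(rng.integers(1, 7))
            got = brier_score(S, d, e, t, G, times=times)
            want = brute_force_brier(times, S, d, e, t, G)
            assert got == pytest.approx(want, abs=1e-12)


class TestIntegratedBrierScore:
    def test_perfect_predictions_zero(self):
        times = np.arange(1.0, 6.0)
        durations = np.array([2.0, 4.0])
        events = np.array([1, 1])
        S = np.array([(times < d).astype(float) for d in durations])
        assert integrated_brier_score(S, durations, events, times=times) == 0.0

    def test_constant_half_integrand(self):
        times = np.arange(1.0, 21.0)
        durations = np.arange(1.0, 21.0)
        events = np.ones(20, dtype=int)
        S = np.full((20, 20), 0.5)
        grid = np.linspace(1.0, 15.0, 50)
        got = integrated_brier_score(S, durations, events, grid=grid, times=times)
        assert got == pytest.approx(0.25, abs=1e-12)

    def test_grid_refinement_agreement(self):
        rng = np.random.default_rng(9)
        times = np.arange(1.0, 31.0)
        n = 60
        S = random_survival_matrix(rng, n, times)
        d = rng.integers(1, 30, size=n).astype(float)
        e = rng.integers(0, 2, size=n)
        coarse = integrated_brier_score(S, d, e, grid=np.linspace(0, 25, 100), times=times)
        fine = integrated_brier_score(S, d, e, grid=np.linspace(0, 25, 1000), times=times)
        assert coarse == pytest.approx(fine, abs=5e-3)

    def test_single_point_grid_warns(self):
        times = np.array([1.0, 2.0])
        S = np.array([[0.8, 0.6]])
        with pytest.warns(UserWarning):
            integrated_brier_score(S, [2.0], [1], grid=np.array([1.0]), times=times)

    def test_matches_scikit_survival_uncensored(self):
        from sksurv.metrics import integrated_brier_score as sks_ibs
        from sksurv.util import Surv

        rng = np.random.default_rng(10)
        times = np.arange(1.0, 21.0)
        n = 50
        S = random_survival_matrix(rng, n, times)
        d = rng.integers(2, 20, size=n).astype(float)
        e = np.ones(n, dtype=int)
        y = Surv.from_arrays(event=e.astype(bool), time=d)
        grid = np.arange(float(d.min()), float(d.max()))  # within follow-up
        ours = integrated_brier_score(S, d, e, grid=grid, times=times)
        idx = np.searchsorted(times, grid, side="right") - 1
        theirs = sks_ibs(y, y, S[:, idx], grid)
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSummarizeFolds:
    def test_identical_folds(self):
        r = summarize_folds([0.9, 0.9, 0.9], [0.1, 0.1, 0.1])
        assert (r.ctd_mean, r.ctd_sd) == (0.9, 0.0)

    def test_two_folds_sample_sd(self):
        r = summarize_folds([0.8, 1.0], [0.1, 0.3])
        assert r.ctd_mean == pytest.approx(0.9)
        assert r.ctd_sd == pytest.approx(0.14142135623, abs=1e-9)

    def test_single_fold_flagged(self):
        r = summarize_folds([0.7], [0.2])
        assert r.single_fold and r.ctd_sd == 0.0


def test_survival_curve_median():
    c = SurvivalCurve(times=np.array([1.0, 2.0, 3.0]), survival=np.array([0.9, 0.6, 0.4]))
    assert c.median() == 3.0
    flat = SurvivalCurve(times=np.array([1.0, 2.0]), survival=np.array([1.0, 1.0]))
    assert flat.median() is None
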