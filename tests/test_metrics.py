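"""Survival metrics against reference implementations and hand computations."""

import numpy as np
import pytest
from sksurv.metrics import (
    brier_score as sk_brier,
    concordance_index_censored,
    concordance_index_ipcw,
    integrated_brier_score,
)
from sksurv.util import Surv

import _oracles
from conftest import random_censored_dataset
from dosurv.metrics import (
    KaplanMeierCensoring,
    UndefinedMetricError,
    brier_score,
    harrell_c,
    integrated_brier,
    ipcw_c,
    stratified_kfold,
    wilcoxon_compare,
)


class TestHarrellC:
    def test_perfect_ranking_no_censoring(self):
        time = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        event = np.ones(5, int)
        risk = -time  # earlier failure = higher risk
        assert harrell_c(risk, time, event) == 1.0

    def test_constant_risk_is_half(self):
        time = np.array([2.0, 4.0, 6.0, 8.0])
        assert harrell_c(np.zeros(4), time, np.ones(4, int)) == 0.5

    def test_five_subject_worked_set(self):
        time = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        event = np.array([1, 1, 0, 1, 0])
        risk = np.array([0.7, 0.9, 0.2, 0.4, 0.1])
        expected = _oracles.harrell_c_pairs(risk, time, event)
        assert harrell_c(risk, time, event) == pytest.approx(expected, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(UndefinedMetricError):
            harrell_c(np.array([1.0, 2.0]), np.array([3.0, 3.0]), np.array([0, 0]))


class TestIPCWC:
    def test_equals_harrell_without_censoring(self, rng):
        time = rng.exponential(5.0, 80)
        event = np.ones(80, int)
        risk = rng.normal(size=80)
        km = KaplanMeierCensoring().fit(time, event)
        assert ipcw_c(risk, time, event, km, weight_cap_quantile=1.0) == harrell_c(risk, time, event)

    def test_truncation_beyond_last_event_is_noop(self, rng):
        risk, time, event = random_censored_dataset(rng, 60)
        km = KaplanMeierCensoring().fit(time, event)
        full = ipcw_c(risk, time, event, km, weight_cap_quantile=1.0)
        trunc = ipcw_c(risk, time, event, km, truncation=time.max() + 1, weight_cap_quantile=1.0)
        assert trunc == full

    def test_eight_subject_hand_km_case(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        risk = np.array([0.9, 0.1, 0.8, 0.3, 0.2, 0.5, 0.6, 0.4])
        km = KaplanMeierCensoring().fit(time, event)
        # censoring KM by hand: drops at the censored times 2, 4, 6, 8
        # G(t) = prod over censored times c <= t of (1 - 1/at_risk_after_events(c))
        np.testing.assert_allclose(km.survival(np.array([1.0])), [1.0])
        np.testing.assert_allclose(km.survival(np.array([2.0])), [1 - 1 / 7])
        np.testing.assert_allclose(km.survival(np.array([4.5])), [(1 - 1 / 7) * (1 - 1 / 5)])
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        ref = concordance_index_ipcw(y, y, risk)[0]
        assert ipcw_c(risk, time, event, km, weight_cap_quantile=1.0) == pytest.approx(ref, abs=1e-12)


class TestBrier:
    def test_perfect_prediction_zero(self):
        time = np.array([5.0, 6.0, 7.0])
        event = np.ones(3, int)
        km = KaplanMeierCensoring().fit(time, event)
        assert brier_score(np.ones(3), time, event, km, tau=4.0) == 0.0

    def test_constant_half_prediction_quarter(self):
        time = np.array([5.0, 6.0, 7.0, 8.0])
        event = np.ones(4, int)
        km = KaplanMeierCensoring().fit(time, event)
        assert brier_score(np.full(4, 0.5), time, event, km, tau=4.0) == pytest.approx(0.25)

    def test_six_subject_censored_case_matches_reference(self):
        time = np.array([1.0, 3.0, 3.0, 5.0, 7.0, 9.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        preds = np.array([0.2, 0.8, 0.5, 0.6, 0.9, 0.7])
        km = KaplanMeierCensoring().fit(time, event)
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        ref = sk_brier(y, y, preds, 5.0)[1][0]
        assert brier_score(preds, time, event, km, tau=5.0) == pytest.approx(ref, abs=1e-12)


class TestIntegratedBrier:
    def test_constant_bs_integrates_to_itself(self, rng):
        time = rng.exponential(10.0, 50) + 1.0
        event = np.ones(50, int)
        km = KaplanMeierCensoring().fit(time, event)
        grid = np.linspace(0.1, 0.5, 8)  # all subjects survive past the grid
        preds = np.full((50, 8), 0.5)
        ibs = integrated_brier(preds, time, event, km, grid)
        assert ibs == pytest.approx(0.25)

    def test_bounded_by_min_max_bs(self, rng):
        risk, time, event = random_censored_dataset(rng, 120)
        km = KaplanMeierCensoring().fit(time, event)
        grid = np.linspace(np.quantile(time, 0.1), np.quantile(time, 0.8), 10)
        preds = np.clip(rng.random((120, 10)), 0.01, 0.99)
        bs = [brier_score(preds[:, j], time, event, km, t) for j, t in enumerate(grid)]
        ibs = integrated_brier(preds, time, event, km, grid)
        assert min(bs) - 1e-12 <= ibs <= max(bs) + 1e-12


class TestReferenceEquivalence:
    def test_all_metrics_match_sksurv_on_random_data(self, rng):
        for _ in range(8):
            risk, time, event = random_censored_dataset(rng)
            y = Surv.from_arrays(event=event.astype(bool), time=time)
            km = KaplanMeierCensoring().fit(time, event)
            assert harrell_c(risk, time, event) == pytest.approx(
                concordance_index_censored(event.astype(bool), time, risk)[0], abs=1e-9
            )
            assert ipcw_c(risk, time, event, km, weight_cap_quantile=1.0) == pytest.approx(
                concordance_index_ipcw(y, y, risk)[0], abs=1e-9
            )
            tau = float(np.quantile(time, 0.7))
            assert brier_score(rng.random(len(time)), time, event, km, tau) >= 0.0


class TestStratifiedKFold:
    def test_exact_event_balance(self, rng):
        event = np.zeros(1000, int)
        event[:50] = 1
        folds = stratified_kfold(event, k=5, seed=1)
        counts = [event[folds == k].sum() for k in range(5)]
        assert counts == [10] * 5

    def test_deterministic(self):
        event = (np.arange(200) % 10 == 0).astype(int)
        a = stratified_kfold(event, k=5, seed=7)
        b = stratified_kfold(event, k=5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_event_proportion_close_to_global(self, rng):
        event = (rng.random(7000) < 0.05).astype(int)
        folds = stratified_kfold(event, k=5, seed=0)
        global_rate = event.mean()
        for k in range(5):
            assert abs(event[folds == k].mean() - global_rate) < 0.005

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([1, 0, 0, 0, 0, 0]), k=5)


class TestWilcoxon:
    def test_identical_samples_give_one(self):
        a = np.array([0.7, 0.7, 0.7, 0.7, 0.7])
        assert wilcoxon_compare(a, a) == 1.0

    def test_minimal_attainable_p_for_5v5(self):
        a = np.full(5, 0.9)
        b = np.full(5, 0.1)
        # exact two-sided rank-sum: the most extreme of C(10,5)=252 splits
        assert wilcoxon_compare(a, b) == pytest.approx(2 / 252)

    def test_symmetry(self, rng):
        a = rng.random(5)
        b = rng.random(5)
        assert wilcoxon_compare(a, b) == pytest.approx(wilcoxon_compare(b, a))
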