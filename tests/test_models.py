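"""The four survival models: recovery, selection, contracts, determinism."""

import numpy as np
import pandas as pd
import pytest

from dosurv.models import (
    CoxModel,
    _newton_cox,
    fit_cox,
    fit_cox_bootstrap_lasso,
    fit_cox_lasso,
    fit_rsf,
    tune_hyperparameters,
)


def simulate_ph_data(rng, n, beta, censor_scale=3.0):
    """Exponential proportional-hazards data with independent censoring."""
    p = len(beta)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    lp = X.to_numpy() @ np.asarray(beta)
    t_event = rng.exponential(np.exp(-lp))
    c = rng.exponential(censor_scale, n)
    return X, np.minimum(t_event, c), (t_event <= c).astype(int)


class TestCox:
    def test_recovers_hazard_ratio_two(self, rng):
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        lp = np.log(2.0) * x
        t_event = rng.exponential(np.exp(-lp))
        c = rng.exponential(3.0, n)
        X = pd.DataFrame({"exposed": x})
        model = fit_cox(X, np.minimum(t_event, c), (t_event <= c).astype(int))
        hr = float(np.exp(model.beta["exposed"]))
        assert 1.8 < hr < 2.2

    def test_null_covariate_coefficient_near_zero(self, rng):
        X, time, event = simulate_ph_data(rng, 5000, [0.0])
        model = fit_cox(X, time, event)
        assert abs(model.beta["x0"]) < 0.1

    def test_constant_column_rejected(self, rng):
        X = pd.DataFrame({"zero": np.zeros(100)})
        with pytest.raises(ValueError, match="constant"):
            fit_cox(X, rng.exponential(1, 100), np.ones(100, int))

    def test_survival_curves_valid(self, rng):
        X, time, event = simulate_ph_data(rng, 400, [0.5, -0.3])
        model = fit_cox(X, time, event)
        times = np.linspace(0.0, time.max(), 30)
        surv = model.predict_survival(X.iloc[:5], times)
        assert surv.shape == (5, 30)
        assert np.all((surv >= 0) & (surv <= 1))
        assert np.all(np.diff(surv, axis=1) <= 1e-12)
        assert np.allclose(surv[:, 0], 1.0)  # S(0) = 1 before the first event

    def test_agrees_with_lifelines_and_sksurv(self, rng):
        """Dual-route check of the Cox solver against two references."""
        from lifelines import CoxPHFitter
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        X, time, event = simulate_ph_data(rng, 600, [0.8, -0.5, 0.0])
        model = fit_cox(X, time, event)
        df = X.copy()
        df["_t"], df["_e"] = time, event
        ll = CoxPHFitter().fit(df, "_t", "_e")
        np.testing.assert_allclose(model.beta.to_numpy(), ll.params_.to_numpy(), atol=1e-4)
        assert model.training_meta["log_likelihood"] == pytest.approx(ll.log_likelihood_, abs=1e-5)
        sk = CoxPHSurvivalAnalysis().fit(
            X.to_numpy(), Surv.from_arrays(event=event.astype(bool), time=time)
        )
        np.testing.assert_allclose(model.beta.to_numpy(), sk.coef_, atol=1e-4)
        se_ll = ll.standard_errors_.to_numpy()
        se_mine = np.array([model.training_meta["standard_errors"][c] for c in X.columns])
        np.testing.assert_allclose(se_mine, se_ll, rtol=1e-3)

    def test_json_round_trip(self, rng, tmp_path):
        X, time, event = simulate_ph_data(rng, 300, [0.5])
        model = fit_cox(X, time, event)
        path = tmp_path / "cox.json"
        model.to_json(path)
        loaded = CoxModel.from_json(path)
        np.testing.assert_allclose(loaded.beta, model.beta)
        times = np.linspace(0.1, 3.0, 7)
        np.testing.assert_allclose(
            loaded.predict_survival(X.iloc[:3], times), model.predict_survival(X.iloc[:3], times)
        )


class TestCoxLasso:
    def test_signal_features_selected(self, rng):
        beta = np.zeros(12)
        beta[:2] = [1.0, -1.0]
        X, time, event = simulate_ph_data(rng, 1500, beta)
        model = fit_cox_lasso(X, time, event, seed=0)
        assert {"x0", "x1"} <= set(model.selected_features)

    def test_refit_removes_shrinkage(self, rng):
        beta = np.zeros(8)
        beta[0] = 1.0
        X, time, event = simulate_ph_data(rng, 1200, beta)
        model = fit_cox_lasso(X, time, event, seed=1)
        # the unpenalized refit coefficient exceeds the shrunken path value
        assert abs(model.beta["x0"]) > 0.5

    def test_empty_selection_gives_baseline_model(self, rng):
        # pure noise, tiny n: the 1-SE rule typically selects nothing
        X, time, event = simulate_ph_data(rng, 150, [0.0, 0.0, 0.0])
        model = fit_cox_lasso(X, time, event, seed=2)
        if not model.selected_features:
            times = np.linspace(0.1, 2.0, 5)
            surv = model.predict_survival(X.iloc[:4], times)
            assert np.allclose(surv, surv[0])  # identical curve for every subject
        else:  # selection can legitimately be non-empty; contract still holds
            assert set(model.selected_features) <= set(X.columns)


class TestBootstrapLasso:
    def test_trace_deterministic_and_row_order_invariant(self, rng):
        beta = np.zeros(6)
        beta[0] = 1.2
        X, time, event = simulate_ph_data(rng, 400, beta)
        kwargs = dict(n_boot=10, cv_folds=1, n_alphas=20, seed=5)
        _, trace_a = fit_cox_bootstrap_lasso(X, time, event, **kwargs)
        _, trace_b = fit_cox_bootstrap_lasso(X, time, event, **kwargs)
        assert trace_a.selection_frequency == trace_b.selection_frequency
        perm = rng.permutation(len(X))
        _, trace_c = fit_cox_bootstrap_lasso(X.iloc[perm], time[perm], event[perm], **kwargs)
        assert trace_c.selection_frequency == trace_a.selection_frequency

    def test_pure_noise_final_selection_small(self, rng):
        X, time, event = simulate_ph_data(rng, 400, np.zeros(10))
        model, trace = fit_cox_bootstrap_lasso(
            X, time, event, n_boot=10, cv_folds=1, n_alphas=20, seed=3
        )
        assert len(trace.final_features) <= 2
        freqs = np.array(list(trace.selection_frequency.values()))
        assert np.median(freqs) < 0.9


class TestRSF:
    def test_dose_driving_feature_ranks_first(self, rng):
        n = 600
        dose = rng.gamma(2.0, 5.0, n)
        X = pd.DataFrame({"mean_dose": dose, "noise1": rng.normal(size=n), "noise2": rng.normal(size=n)})
        lp = 0.15 * dose
        t_event = rng.exponential(np.exp(-(lp - lp.mean())))
        c = rng.exponential(2.0, n)
        time, event = np.minimum(t_event, c), (t_event <= c).astype(int)
        model = fit_rsf(X, time, event, {"n_trees": 100, "min_node_size": 10}, seed=0)
        importance = model.permutation_importance(X, time, event, n_repeats=2, seed=1)
        assert importance.index[0] == "mean_dose"

    def test_predicted_curves_monotone_from_one(self, rng):
        X, time, event = simulate_ph_data(rng, 300, [0.5, 0.0])
        model = fit_rsf(X, time, event, {"n_trees": 30}, seed=2)
        times = np.concatenate([[0.0], np.linspace(0.05, time.max(), 20)])
        surv = model.predict_survival(X.iloc[:4], times)
        assert np.all(surv[:, 0] == 1.0)
        assert np.all(np.diff(surv, axis=1) <= 1e-12)
        assert np.all((surv >= 0) & (surv <= 1))

    def test_more_trees_do_not_hurt_heldout_concordance(self, rng):
        from dosurv.metrics import harrell_c

        X, time, event = simulate_ph_data(rng, 700, [1.0, -0.8, 0.0, 0.0])
        tr = np.arange(500)
        te = np.arange(500, 700)
        scores = {}
        for n_trees in (1, 200):
            m = fit_rsf(X.iloc[tr], time[tr], event[tr], {"n_trees": n_trees, "min_node_size": 10}, seed=4)
            scores[n_trees] = harrell_c(m.risk_score(X.iloc[te]), time[te], event[te])
        assert scores[200] >= scores[1] - 0.02

    def test_invalid_hyperparameters_rejected(self, rng):
        X, time, event = simulate_ph_data(rng, 100, [0.5])
        with pytest.raises(ValueError):
            fit_rsf(X, time, event, {"mtry": -3}, seed=0)
        with pytest.raises(ValueError):
            fit_rsf(X, time, event, {"n_trees": 0}, seed=0)


class TestTuning:
    def test_single_point_grid_returned_unchanged(self, rng):
        X, time, event = simulate_ph_data(rng, 200, [0.5])
        point = {"n_trees": 25, "min_node_size": 20}
        assert tune_hyperparameters("rsf", X, time, event, [point]) == point

    def test_best_point_is_cv_argmax(self, rng):
        from dosurv.metrics import harrell_c, stratified_kfold
        from dosurv.models import fit_model

        X, time, event = simulate_ph_data(rng, 500, [1.0, 0.0])
        grid = [{"n_trees": 25, "min_node_size": 100}, {"n_trees": 25, "min_node_size": 10}]
        best = tune_hyperparameters("rsf", X, time, event, grid, cv_folds=3, seed=9)
        # recompute every grid point's cross-validated C the same way
        folds = stratified_kfold(event, k=3, seed=9)
        means = []
        for point in grid:
            scores = []
            for k in range(3):
                tr, te = folds != k, folds == k
                m = fit_model("rsf", X.iloc[tr], time[tr], event[tr], hyperparams=point, seed=9 + k)
                scores.append(harrell_c(m.risk_score(X.iloc[te]), time[te], event[te]))
            means.append(np.mean(scores))
        assert best == grid[int(np.argmax(means))]
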