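"""Cross-validated and bootstrap performance estimation.

``run_cv`` runs the full train-side procedure (screening, optional
hyperparameter tuning, model fit, censoring-model fit) inside each stratified
fold and scores the held-out fold with Harrell's C, the IPCW C-index and the
integrated Brier score on a 1-60 year grid.  ``bootstrap_error_curves``
refits models on bootstrap resamples and traces BS(tau) and the bounded
IPCW C-index C_tau on the out-of-bag patients across the time grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features.table import FeatureTable
from .metrics import (
    CoxCensoringModel,
    UndefinedMetricError,
    harrell_c,
    integrated_brier,
    ipcw_c,
    stratified_kfold,
)
from .models import CoxNonConvergenceError, fit_model, tune_hyperparameters
from .screening import ScreeningConfig, ScreeningResult, fit_screening

#: Evaluation horizon grid: 1 to 60 years, yearly.
DEFAULT_TIME_GRID = np.arange(1.0, 61.0)

#: Covariates of the censoring model: clinical variables except the
#: first-cancer diagnosis group.
IPCW_COVARIATES = ("sex", "age_6_10", "age_11_15", "age_gt15", "anthracyclines", "alkylating_agents")


def _censor_model(table_df: pd.DataFrame, time: np.ndarray, event: np.ndarray) -> CoxCensoringModel:
    cols = [c for c in IPCW_COVARIATES if c in table_df.columns]
    return CoxCensoringModel(columns=cols).fit(table_df, time, event)


@dataclass
class CVResult:
    """Per-fold metrics of one pipeline configuration."""

    frame: pd.DataFrame  # columns: fold, harrell_c, ipcw_c, ibs
    fold_assignments: np.ndarray
    selected_features: dict[int, list[str]] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        out = {}
        for col in ("harrell_c", "ipcw_c", "ibs"):
            out[f"{col}_mean"] = float(self.frame[col].mean())
            out[f"{col}_sd"] = float(self.frame[col].std(ddof=1))
        return out

    def formatted_summary(self) -> dict[str, str]:
        s = self.summary()
        return {
            col: f"{s[f'{col}_mean']:.3f} ± {s[f'{col}_sd']:.3f}"
            for col in ("harrell_c", "ipcw_c", "ibs")
        }


def _fit_fold_model(
    model_type: str,
    X_tr: pd.DataFrame,
    t_tr: np.ndarray,
    e_tr: np.ndarray,
    hyperparams: dict | None,
    grid: list[dict] | None,
    cv_folds: int,
    seed: int,
):
    hp = dict(hyperparams or {})
    if grid and len(grid) > 1:
        tuned = tune_hyperparameters(model_type, X_tr, t_tr, e_tr, grid, cv_folds=cv_folds, seed=seed)
        hp = {**hp, **tuned} if model_type == "rsf" else {**hp, **tuned}
    return fit_model(model_type, X_tr, t_tr, e_tr, hyperparams=hp, seed=seed)


def run_cv(
    table: FeatureTable,
    time: np.ndarray,
    event: np.ndarray,
    model_type: str,
    screening: bool = False,
    hyperparams: dict | None = None,
    tuning_grid: list[dict] | None = None,
    k: int = 5,
    seed: int = 0,
    time_grid: np.ndarray = DEFAULT_TIME_GRID,
    folds: np.ndarray | None = None,
    screenings: list[ScreeningResult] | None = None,
) -> CVResult:
    """Stratified k-fold evaluation of one model/feature configuration.

    Everything fitted — screening, tuning, the model, the censoring model for
    the IPCW weights — sees the train folds only.  ``screening`` toggles the
    clustering-based dosiomics redundancy elimination; degenerate and
    diagnosis-indicator screening always run, as they are part of feature
    inclusion.  Folds whose fit fails are recorded and skipped.

    ``folds`` (a precomputed assignment) and ``screenings`` (one fitted
    :class:`ScreeningResult` per fold) let several models share identical
    fold splits and screening output, which makes fold-wise model
    comparisons paired and avoids recomputing the feature clustering.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    if folds is None:
        folds = stratified_kfold(event, k=k, seed=seed)
    rows = []
    selected: dict[int, list[str]] = {}
    failures: dict[int, str] = {}
    for fold in range(k):
        tr = folds != fold
        te = folds == fold
        if screenings is not None:
            screen: ScreeningResult = screenings[fold]
        else:
            train_tbl = FeatureTable(table.data.iloc[tr], table.column_meta)
            scfg = ScreeningConfig(cluster_dosiomics=screening)
            screen = fit_screening(train_tbl, time[tr], event[tr], scfg)
        X_tr = screen.apply(table.data.iloc[tr])
        X_te = screen.apply(table.data.iloc[te])
        try:
            model = _fit_fold_model(
                model_type, X_tr, time[tr], event[tr], hyperparams, tuning_grid, k, seed + 1000 + fold
            )
        except (CoxNonConvergenceError, ValueError, ArithmeticError) as exc:
            warnings.warn(f"fold {fold} fit failed: {exc}")
            failures[fold] = str(exc)
            continue
        selected[fold] = getattr(model, "selected_features", getattr(model, "feature_names", []))
        censor = _censor_model(table.data.iloc[tr], time[tr], event[tr])

        risk = model.risk_score(X_te)
        surv = model.predict_survival(X_te, time_grid)
        clin_te = table.data.iloc[te]
        try:
            h = harrell_c(risk, time[te], event[te])
            c = ipcw_c(risk, time[te], event[te], censor, X=clin_te)
            ibs = integrated_brier(surv, time[te], event[te], censor, time_grid, X=clin_te)
        except UndefinedMetricError as exc:
            failures[fold] = f"metric undefined: {exc}"
            continue
        rows.append({"fold": fold, "harrell_c": h, "ipcw_c": c, "ibs": ibs})
    frame = pd.DataFrame(rows, columns=["fold", "harrell_c", "ipcw_c", "ibs"])
    return CVResult(frame=frame, fold_assignments=folds, selected_features=selected, failures=failures)


@dataclass
class ErrorCurves:
    """Bootstrap out-of-bag time-dependent error curves per model."""

    grid: np.ndarray
    brier: dict[str, np.ndarray]  # name -> (n_boot, n_tau), NaN where undefined
    ctau: dict[str, np.ndarray]

    def mean_frame(self) -> pd.DataFrame:
        """Tidy per-tau mean curves (NaN-aware) for plotting/export."""
        rows = []
        for name in self.brier:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bs_mean = np.nanmean(self.brier[name], axis=0)
                c_mean = np.nanmean(self.ctau[name], axis=0)
            for tau, b, c in zip(self.grid, bs_mean, c_mean):
                rows.append({"model": name, "tau": tau, "brier": b, "ctau": c})
        return pd.DataFrame(rows)


def bootstrap_error_curves(
    pipeline_specs: dict[str, dict],
    table: FeatureTable,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 100,
    grid: np.ndarray = DEFAULT_TIME_GRID,
    seed: int = 0,
) -> ErrorCurves:
    """Bootstrap prediction-error curves on out-of-bag patients.

    ``pipeline_specs`` maps a display name to a dict with keys ``model_type``,
    ``screening`` (bool), optional ``hyperparams`` (the values tuned in the
    cross-validation are passed here and held fixed) and optional ``table``
    (a spec-specific feature slice; ``table`` is the fallback).  For each
    bootstrap the models are fitted on the in-bag rows and BS(tau) / bounded
    C_tau are computed over the out-of-bag rows for every tau; horizons with
    no usable out-of-bag information stay NaN and are excluded from means.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    rng = np.random.default_rng(seed)
    n = len(time)
    grid = np.asarray(grid, float)
    brier = {name: np.full((n_boot, grid.size), np.nan) for name in pipeline_specs}
    ctau = {name: np.full((n_boot, grid.size), np.nan) for name in pipeline_specs}

    for b in range(n_boot):
        for _ in range(100):
            inbag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), inbag)
            if event[inbag].sum() >= 2 and oob.size >= 2 and event[oob].sum() >= 1:
                break
        t_tr, e_tr = time[inbag], event[inbag]
        t_te, e_te = time[oob], event[oob]
        censor = _censor_model(table.data.iloc[inbag], t_tr, e_tr)
        for name, spec in pipeline_specs.items():
            spec_table: FeatureTable = spec.get("table", table)
            tr_tbl = FeatureTable(
                spec_table.data.iloc[inbag].reset_index(drop=True), spec_table.column_meta
            )
            te_df = spec_table.data.iloc[oob]
            scfg = ScreeningConfig(cluster_dosiomics=bool(spec.get("screening", False)))
            try:
                screen = fit_screening(tr_tbl, t_tr, e_tr, scfg)
                model = fit_model(
                    spec["model_type"],
                    screen.apply(tr_tbl.data),
                    t_tr,
                    e_tr,
                    hyperparams=spec.get("hyperparams"),
                    seed=seed + 7919 * b,
                )
            except (CoxNonConvergenceError, ValueError, ArithmeticError) as exc:
                warnings.warn(f"bootstrap {b}, {name}: fit failed ({exc})")
                continue
            X_te = screen.apply(te_df)
            risk = model.risk_score(X_te)
            surv = model.predict_survival(X_te, grid)
            for j, tau in enumerate(grid):
                if tau > t_te.max():
                    continue
                try:
                    brier[name][b, j] = np.clip(
                        _brier_at(surv[:, j], t_te, e_te, censor, tau, te_df), 0.0, 1.0
                    )
                except UndefinedMetricError:
                    pass
                try:
                    ctau[name][b, j] = ipcw_c(risk, t_te, e_te, censor, truncation=tau, X=te_df)
                except UndefinedMetricError:
                    pass
    return ErrorCurves(grid=grid, brier=brier, ctau=ctau)


def _brier_at(surv_col, t, e, censor, tau, X):
    from .metrics import brier_score

    return brier_score(surv_col, t, e, censor, tau, X=X)
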