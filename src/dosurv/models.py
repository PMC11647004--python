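"""The four survival models behind one prediction contract.

* ``fit_cox`` — Cox proportional hazards, partial likelihood with Efron tie
  handling, Breslow baseline cumulative hazard.
* ``fit_cox_lasso`` — L1-penalized Cox path; the penalty is the largest one
  whose cross-validated partial-likelihood deviance is within one standard
  error of the minimum (the glmnet ``lambda.1se`` rule), followed by an
  unpenalized refit on the surviving features.
* ``fit_cox_bootstrap_lasso`` — stability selection: per bootstrap sample a
  Cox Lasso is fitted, the penalty relaxed to the sparsest model not rejected
  by a likelihood-ratio test against the deviance-minimizing one, and the
  features kept in >= 90% of bootstraps enter a final unpenalized Cox fit.
* ``fit_rsf`` — random survival forest with log-rank splitting.

All models expose ``predict_survival(X, times) -> (n, len(times))`` survival
curves and a scalar ``risk_score(X)``; higher scores mean earlier failure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import harrell_c, stratified_kfold

MODEL_TYPES = ("cox", "cox_lasso", "cox_bootstrap_lasso", "rsf")


class CoxNonConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (separation, collinearity...)."""


# ---------------------------------------------------------------------------
# Partial likelihood and baseline hazard helpers
# ---------------------------------------------------------------------------

def cox_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of a fixed linear predictor.

    Used to compare nested fitted models on one dataset; matches the value
    the package's Cox solver maximizes.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    lp = np.asarray(lp, float)
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    shift = x.max()
    w = np.exp(x - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    uniq, first_idx, inverse = np.unique(t, return_index=True, return_inverse=True)
    # per unique time: number of events and risk-set sum at the group start
    d_per = np.bincount(inverse, weights=e.astype(float), minlength=uniq.size)
    ll = float(np.sum((x - shift)[e]))
    single = d_per == 1
    if single.any():
        ll -= float(np.sum(np.log(s0[first_idx[single]])))
    for g in np.flatnonzero(d_per > 1):  # tied event times: Efron correction
        start = first_idx[g]
        stop = first_idx[g + 1] if g + 1 < uniq.size else len(t)
        ev_rows = np.flatnonzero(e[start:stop]) + start
        d = ev_rows.size
        s0t = w[ev_rows].sum()
        ll -= float(np.sum(np.log(s0[start] - (np.arange(d) / d) * s0t)))
    return float(ll)


def _newton_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton-Raphson maximizer of the Cox partial likelihood (Efron ties).

    Returns ``(beta, loglik, hessian)``; standard errors follow from the
    inverse of the negated Hessian.  ``ridge`` adds a small L2 penalty
    (scaled by the event count) as a stabilizer for near-collinear designs.
    Raises :class:`CoxNonConvergenceError` on failure.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    order = np.argsort(np.asarray(time, float), kind="stable")
    t = np.asarray(time, float)[order]
    e = np.asarray(event).astype(bool)[order]
    x = X[order]
    uniq, first_idx = np.unique(t, return_index=True)
    bounds = np.r_[first_idx, n]
    # per unique time: indices of tied event rows
    groups = []
    for g, start in enumerate(first_idx):
        ev_rows = np.flatnonzero(e[start : bounds[g + 1]]) + start
        if ev_rows.size:
            groups.append((start, ev_rows))
    if not groups:
        raise CoxNonConvergenceError("no events")
    r_eff = ridge * max(1, int(e.sum()))

    def loglik_grad_hess(beta: np.ndarray):
        lp = x @ beta
        shift = lp.max()  # guard overflow; cancels in ratios, constant in ll
        w = np.exp(lp - shift)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        # S2 suffix sums evaluated at each group start, accumulated in reverse
        s2 = np.zeros((p, p))
        prev = n
        s2_at = {}
        for start, _ in reversed(groups):
            if start < prev:
                seg = x[start:prev]
                s2 += seg.T @ (w[start:prev, None] * seg)
                prev = start
            s2_at[start] = s2.copy()
        for start, ev_rows in groups:
            d = ev_rows.size
            xe = x[ev_rows]
            we = w[ev_rows]
            s0t = we.sum()
            s1t = we @ xe
            s2t = xe.T @ (we[:, None] * xe)
            ll += float(np.sum(lp[ev_rows] - shift))
            grad += xe.sum(axis=0)
            s2r = s2_at[start]
            for l in range(d):
                f = l / d
                phi = s0[start] - f * s0t
                psi1 = (s1[start] - f * s1t) / phi
                ll -= np.log(phi)
                grad -= psi1
                hess -= (s2r - f * s2t) / phi - np.outer(psi1, psi1)
        if r_eff:
            ll -= 0.5 * r_eff * float(beta @ beta)
            grad -= r_eff * beta
            hess -= r_eff * np.eye(p)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess - 1e-9 * np.eye(p), -grad)
        except np.linalg.LinAlgError as exc:
            raise CoxNonConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving line search on the (penalized) partial likelihood
        scale = 1.0
        for _ in range(35):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = loglik_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise CoxNonConvergenceError("line search failed")
        delta = np.abs(cand - beta).max()
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if delta < tol or np.abs(grad).max() < 1e-7:
            break
    else:
        raise CoxNonConvergenceError(f"no convergence in {max_iter} iterations")
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 50:
        raise CoxNonConvergenceError("estimates diverged (separation?)")
    return beta, float(ll), hess


def _breslow_baseline(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard H0(t) at lp = 0."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], np.asarray(lp, float)[order]
    rev_cumsum = np.cumsum(np.exp(x)[::-1])[::-1]
    uniq, first_idx = np.unique(t, return_index=True)
    deaths = np.add.reduceat(e.astype(float), first_idx)
    increments = deaths / rev_cumsum[first_idx]
    keep = deaths > 0
    return uniq[keep], np.cumsum(increments[keep])


def _step_eval(times: np.ndarray, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Right-continuous step function evaluation; 0 before the first step."""
    idx = np.searchsorted(times, np.asarray(t, float), side="right") - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], 0.0)


# ---------------------------------------------------------------------------
# Cox model
# ---------------------------------------------------------------------------

@dataclass
class CoxModel:
    """Fitted Cox PH model with Breslow baseline cumulative hazard."""

    beta: pd.Series
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    selected_features: list[str]
    training_meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.beta.index)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        if len(self.beta) == 0:
            return np.zeros(len(X))
        return X[self.feature_names].to_numpy(dtype=float) @ self.beta.to_numpy()

    def risk_score(self, X: pd.DataFrame) -> np.ndarray:
        return self.linear_predictor(X)

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """S(t|X) = exp(-H0(t) exp(beta'X)) on the requested time grid."""
        times = np.atleast_1d(np.asarray(times, float))
        h0 = _step_eval(self.baseline_times, self.baseline_cumhaz, times)
        lp = self.linear_predictor(X)
        return np.exp(-np.outer(np.exp(lp), h0))

    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.beta)

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.to_dict(),
            "feature_order": self.feature_names,
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "selected_features": self.selected_features,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CoxModel":
        with open(path) as fh:
            d = json.load(fh)
        beta = pd.Series({k: d["beta"][k] for k in d["feature_order"]}, dtype=float)
        return cls(
            beta=beta,
            baseline_times=np.asarray(d["baseline_times"], float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], float),
            selected_features=d["selected_features"],
            training_meta=d["training_meta"],
        )


def _validate_design(X: pd.DataFrame, time: np.ndarray, event: np.ndarray) -> None:
    if np.asarray(event).sum() < 2:
        raise ValueError("need at least 2 events to fit a survival model")
    nunique = X.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ValueError(f"constant columns in design matrix: {constant}")


def _baseline_only_model(time: np.ndarray, event: np.ndarray, meta: dict) -> CoxModel:
    bt, bh = _breslow_baseline(time, event, np.zeros(len(time)))
    return CoxModel(
        beta=pd.Series(dtype=float),
        baseline_times=bt,
        baseline_cumhaz=bh,
        selected_features=[],
        training_meta={**meta, "baseline_only": True},
    )


def fit_cox(X: pd.DataFrame, time: np.ndarray, event: np.ndarray, meta: dict | None = None) -> CoxModel:
    """Maximum partial likelihood Cox fit (Efron ties) with Breslow baseline.

    Near-collinear designs are retried with a whisper of L2 stabilization.
    Raises :class:`CoxNonConvergenceError` with diagnostics when the
    optimizer fails or produces non-finite estimates.
    """
    meta = dict(meta or {})
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    if X.shape[1] == 0:
        return _baseline_only_model(time, event, meta)
    _validate_design(X, time, event)
    xv = X.to_numpy(dtype=float)
    last_exc: Exception | None = None
    for ridge in (0.0, 1e-6, 1e-4):
        try:
            b, ll, hess = _newton_cox(xv, time, event, ridge=ridge)
        except CoxNonConvergenceError as exc:
            last_exc = exc
            continue
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError as exc:
            last_exc = CoxNonConvergenceError(f"singular information at optimum: {exc}")
            continue
        if not np.all(np.isfinite(se)):
            last_exc = CoxNonConvergenceError("non-finite standard errors")
            continue
        if ridge:
            meta["ridge_stabilizer"] = ridge
        break
    else:
        raise CoxNonConvergenceError(
            f"Cox fit failed on p={X.shape[1]}: {last_exc}"
        ) from last_exc
    beta = pd.Series(b, index=list(X.columns), dtype=float)
    lp = xv @ b
    bt, bh = _breslow_baseline(time, event, lp)
    meta.setdefault("model_type", "cox")
    meta["log_likelihood"] = ll
    meta["standard_errors"] = dict(zip(X.columns, se.tolist()))
    return CoxModel(
        beta=beta,
        baseline_times=bt,
        baseline_cumhaz=bh,
        selected_features=list(X.columns),
        training_meta=meta,
    )


def cox_coefficients(X: pd.DataFrame, time: np.ndarray, event: np.ndarray) -> dict[str, float]:
    """Multivariate Cox log-hazard coefficients (fast internal solver)."""
    beta, _, _ = _newton_cox(X.to_numpy(dtype=float), time, event)
    return dict(zip(X.columns, beta.tolist()))


# ---------------------------------------------------------------------------
# Cox Lasso
# ---------------------------------------------------------------------------

def _surv_array(time: np.ndarray, event: np.ndarray):
    from sksurv.util import Surv

    return Surv.from_arrays(event=np.asarray(event).astype(bool), time=np.asarray(time, float))


def _coxnet_path(
    Xs: np.ndarray,
    time,
    event,
    alphas=None,
    n_alphas: int = 50,
    tol: float = 1e-7,
    alpha_min_ratio: float = 0.01,
):
    """Fit an L1 Cox path, trimming the small-penalty end if it fails."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    y = _surv_array(time, event)
    kwargs = dict(l1_ratio=1.0, normalize=False, fit_baseline_model=False, tol=tol)
    attempt_alphas = None if alphas is None else list(alphas)
    for _ in range(6):
        try:
            model = CoxnetSurvivalAnalysis(
                alphas=attempt_alphas,
                n_alphas=n_alphas,
                alpha_min_ratio=alpha_min_ratio,
                **kwargs,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xs, y)
            return model
        except (ArithmeticError, ValueError):
            if attempt_alphas is None:
                attempt_alphas = list(
                    np.geomspace(1.0, 0.05, n_alphas) * _max_alpha_guess(Xs, event)
                )
            if len(attempt_alphas) <= 4:
                raise
            attempt_alphas = attempt_alphas[: max(4, int(len(attempt_alphas) * 0.8))]
    raise CoxNonConvergenceError("Cox Lasso path failed to converge")


def _max_alpha_guess(Xs: np.ndarray, event: np.ndarray) -> float:
    e = np.asarray(event, float)
    score = np.abs(Xs.T @ (e - e.mean()))
    return float(score.max() / len(e) + 1e-12)


def _cv_deviance(
    Xs: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    cv_folds: int,
    seed: int,
    tol: float = 1e-7,
    alpha_min_ratio: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated partial-likelihood deviance per penalty.

    Uses the Verweij-van Houwelingen construction: the fold contribution is
    -2 [ ll(beta_{-k}; all) - ll(beta_{-k}; train_{-k}) ].
    """
    if cv_folds == 1:
        # single stratified 75/25 holdout (cheap penalty selection)
        quarter = stratified_kfold(event, k=4, seed=seed)
        folds = np.where(quarter == 0, 0, -1)  # fold 0 = validation split
        eval_folds = [0]
    else:
        folds = stratified_kfold(event, k=cv_folds, seed=seed)
        eval_folds = list(range(cv_folds))
    dev = np.full((len(eval_folds), len(alphas)), np.nan)
    for k in eval_folds:
        tr = folds != k
        try:
            path = _coxnet_path(
                Xs[tr], time[tr], event[tr], alphas=alphas, tol=tol, alpha_min_ratio=alpha_min_ratio
            )
        except (CoxNonConvergenceError, ArithmeticError, ValueError):
            continue
        fitted = {round(float(a), 12): i for i, a in enumerate(path.alphas_)}
        for j, a in enumerate(alphas):
            idx = fitted.get(round(float(a), 12))
            if idx is None:
                continue
            coef = path.coef_[:, idx]
            ll_all = cox_partial_loglik(Xs @ coef, time, event)
            ll_tr = cox_partial_loglik(Xs[tr] @ coef, time[tr], event[tr])
            dev[k, j] = -2.0 * (ll_all - ll_tr)
    if np.all(np.isnan(dev)):
        raise CoxNonConvergenceError("all cross-validation folds failed on the Lasso path")
    mean = np.nanmean(dev, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev), axis=0))
    return mean, se


def _standardize(X: pd.DataFrame) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return ((X - mu) / sd).to_numpy(dtype=float)


def fit_cox_lasso(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    n_alphas: int = 50,
    path_tol: float = 1e-7,
    alpha_min_ratio: float = 0.01,
    meta: dict | None = None,
) -> CoxModel:
    """Cox Lasso with the 1-SE penalty rule and an unpenalized refit.

    Columns are standardized for the penalized path; the refit runs on the
    original scale, so reported coefficients are per original unit.  An empty
    selection yields a baseline-only model.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    _validate_design(X, time, event)
    Xs = _standardize(X)
    path = _coxnet_path(Xs, time, event, n_alphas=n_alphas, tol=path_tol, alpha_min_ratio=alpha_min_ratio)
    alphas = np.asarray(path.alphas_)  # descending
    mean_dev, se_dev = _cv_deviance(
        Xs, time, event, alphas, cv_folds, seed, tol=path_tol, alpha_min_ratio=alpha_min_ratio
    )
    best = int(np.nanargmin(mean_dev))
    se_best = se_dev[best] if np.isfinite(se_dev[best]) else 0.0
    threshold = mean_dev[best] + se_best
    ok = np.flatnonzero(np.nan_to_num(mean_dev, nan=np.inf) <= threshold)
    one_se = int(ok.min())  # alphas descending -> smallest index = largest penalty
    selected = [c for c, b in zip(X.columns, path.coef_[:, one_se]) if b != 0]
    meta = {
        **(meta or {}),
        "model_type": "cox_lasso",
        "alpha_min": float(alphas[best]),
        "alpha_1se": float(alphas[one_se]),
        "cv_folds": cv_folds,
        "seed": seed,
    }
    if not selected:
        return _baseline_only_model(time, event, meta)
    model = fit_cox(X[selected], time, event, meta=meta)
    model.training_meta["model_type"] = "cox_lasso"
    return model


# ---------------------------------------------------------------------------
# Cox Bootstrap Lasso (stability selection)
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSelectionTrace:
    """Audit trail of the bootstrap stability selection."""

    n_bootstraps: int
    selection_frequency: dict[str, float]
    frequency_threshold: float
    final_features: list[str]
    redraws: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_bootstraps": self.n_bootstraps,
                    "selection_frequency": self.selection_frequency,
                    "frequency_threshold": self.frequency_threshold,
                    "final_features": self.final_features,
                    "redraws": self.redraws,
                },
                fh,
                indent=1,
            )


def _lrt_penalty_selection(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cv_folds: int,
    seed: int,
    lrt_level: float = 0.05,
    n_alphas: int = 50,
    path_tol: float = 1e-7,
    alpha_min_ratio: float = 0.01,
) -> list[str]:
    """Feature set of the sparsest penalty not rejected by a LRT.

    The reference penalty minimizes the cross-validated deviance; walking
    toward larger penalties, each distinct selected feature set is refitted
    without penalty and compared to the reference refit by a likelihood-ratio
    test with df equal to the difference in feature counts.
    """
    Xs = _standardize(X)
    path = _coxnet_path(Xs, time, event, n_alphas=n_alphas, tol=path_tol, alpha_min_ratio=alpha_min_ratio)
    alphas = np.asarray(path.alphas_)
    mean_dev, _ = _cv_deviance(
        Xs, time, event, alphas, cv_folds, seed, tol=path_tol, alpha_min_ratio=alpha_min_ratio
    )
    best = int(np.nanargmin(mean_dev))

    def feature_set(idx: int) -> tuple[str, ...]:
        return tuple(c for c, b in zip(X.columns, path.coef_[:, idx]) if b != 0)

    ll_cache: dict[tuple[str, ...], float] = {}

    def refit_ll(features: tuple[str, ...]) -> float:
        if features not in ll_cache:
            if not features:
                ll_cache[features] = cox_partial_loglik(np.zeros(len(time)), time, event)
            else:
                _, ll, _ = _newton_cox(X[list(features)].to_numpy(dtype=float), time, event)
                ll_cache[features] = ll
        return ll_cache[features]

    ref_set = feature_set(best)
    try:
        ll_ref = refit_ll(ref_set)
    except CoxNonConvergenceError:
        return list(ref_set)
    chosen = ref_set
    for idx in range(best - 1, -1, -1):  # toward larger penalties / sparser models
        cand = feature_set(idx)
        if cand == chosen:
            continue
        df = len(ref_set) - len(cand)
        if df <= 0:
            chosen = cand
            continue
        try:
            ll_cand = refit_ll(cand)
        except CoxNonConvergenceError:
            break
        stat = max(0.0, 2.0 * (ll_ref - ll_cand))
        if stats.chi2.sf(stat, df) >= lrt_level:
            chosen = cand
        else:
            break
    return list(chosen)


def fit_cox_bootstrap_lasso(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_boot: int = 100,
    threshold: float = 0.9,
    cv_folds: int = 5,
    seed: int = 0,
    lrt_level: float = 0.05,
    n_alphas: int = 50,
    path_tol: float = 1e-7,
    alpha_min_ratio: float = 0.01,
) -> tuple[CoxModel, BootstrapSelectionTrace]:
    """Bootstrap stability selection around the LRT-relaxed Cox Lasso.

    Rows are put in a canonical (index-sorted) order first, so selection
    frequencies do not depend on how the table was shuffled.
    """
    order = np.argsort(X.index.to_numpy(), kind="stable")
    X = X.iloc[order]
    time = np.asarray(time, float)[order]
    event = np.asarray(event).astype(int)[order]
    _validate_design(X, time, event)

    rng = np.random.default_rng(seed)
    n = len(X)
    counts: dict[str, int] = {c: 0 for c in X.columns}
    redraws = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if event[idx].sum() >= 2:
                break
            redraws += 1
        xb = X.iloc[idx]
        # drop columns that became constant inside the bootstrap sample
        live = [c for c in xb.columns if xb[c].nunique() > 1]
        try:
            selected = _lrt_penalty_selection(
                xb[live].reset_index(drop=True),
                time[idx],
                event[idx],
                cv_folds=cv_folds,
                seed=int(rng.integers(0, 2**31 - 1)),
                lrt_level=lrt_level,
                n_alphas=n_alphas,
                path_tol=path_tol,
                alpha_min_ratio=alpha_min_ratio,
            )
        except (CoxNonConvergenceError, ArithmeticError, ValueError):
            redraws += 1
            continue
        for c in selected:
            counts[c] += 1

    freq = {c: counts[c] / n_boot for c in X.columns}
    final = [c for c in X.columns if freq[c] >= threshold]
    trace = BootstrapSelectionTrace(
        n_bootstraps=n_boot,
        selection_frequency=freq,
        frequency_threshold=threshold,
        final_features=final,
        redraws=redraws,
    )
    meta = {"model_type": "cox_bootstrap_lasso", "n_boot": n_boot, "threshold": threshold, "seed": seed}
    if final:
        model = fit_cox(X[final], time, event, meta=meta)
        model.training_meta["model_type"] = "cox_bootstrap_lasso"
    else:
        model = _baseline_only_model(time, event, meta)
    return model, trace


# ---------------------------------------------------------------------------
# Random survival forest
# ---------------------------------------------------------------------------

@dataclass
class RSFModel:
    """Random survival forest with the shared prediction contract."""

    forest: object
    feature_names: list[str]
    n_trees: int
    mtry: object
    min_node_size: int
    training_meta: dict = field(default_factory=dict)

    def risk_score(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.forest.predict(X[self.feature_names].to_numpy(dtype=float)))

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, float))
        surv = self.forest.predict_survival_function(
            X[self.feature_names].to_numpy(dtype=float), return_array=True
        )
        event_times = np.asarray(self.forest.unique_times_)
        idx = np.searchsorted(event_times, times, side="right") - 1
        out = np.ones((len(X), times.size))
        inside = idx >= 0
        out[:, inside] = surv[:, idx[inside]]
        return out

    def save(self, path) -> None:
        """Persist the fitted ensemble and its metadata (joblib format)."""
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "RSFModel":
        import joblib

        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a fitted forest model")
        return model

    def permutation_importance(
        self, X: pd.DataFrame, time: np.ndarray, event: np.ndarray, n_repeats: int = 3, seed: int = 0
    ) -> pd.Series:
        """Mean drop in Harrell C when one feature column is permuted."""
        rng = np.random.default_rng(seed)
        base = harrell_c(self.risk_score(X), time, event)
        drops = {}
        for col in self.feature_names:
            vals = []
            for _ in range(n_repeats):
                xp = X.copy()
                xp[col] = rng.permutation(xp[col].to_numpy())
                vals.append(base - harrell_c(self.risk_score(xp), time, event))
            drops[col] = float(np.mean(vals))
        return pd.Series(drops).sort_values(ascending=False)


def fit_rsf(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> RSFModel:
    """Fit a random survival forest (log-rank splits, bootstrap per tree)."""
    from sksurv.ensemble import RandomSurvivalForest

    hp = {"n_trees": 500, "mtry": "sqrt", "min_node_size": 15, **(hyperparams or {})}
    p = X.shape[1]
    mtry = hp["mtry"]
    if mtry == "sqrt":
        max_features = max(1, int(np.sqrt(p)))
    elif mtry == "third":
        max_features = max(1, p // 3)
    elif isinstance(mtry, (int, np.integer)) and mtry >= 1:
        max_features = min(int(mtry), p)
    else:
        raise ValueError(f"invalid mtry {mtry!r}")
    if hp["n_trees"] < 1 or hp["min_node_size"] < 1:
        raise ValueError("n_trees and min_node_size must be positive")
    forest = RandomSurvivalForest(
        n_estimators=int(hp["n_trees"]),
        min_samples_leaf=int(hp["min_node_size"]),
        max_features=max_features,
        random_state=int(seed),
        n_jobs=1,
    )
    forest.fit(X.to_numpy(dtype=float), _surv_array(time, event))
    return RSFModel(
        forest=forest,
        feature_names=list(X.columns),
        n_trees=int(hp["n_trees"]),
        mtry=mtry,
        min_node_size=int(hp["min_node_size"]),
        training_meta={"model_type": "rsf", "seed": seed, **hp},
    )


# ---------------------------------------------------------------------------
# Dispatch and tuning
# ---------------------------------------------------------------------------

def fit_model(
    model_type: str,
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit any of the four model types with a common signature."""
    hp = dict(hyperparams or {})
    if model_type == "cox":
        return fit_cox(X, time, event)
    if model_type == "cox_lasso":
        return fit_cox_lasso(X, time, event, seed=seed, **hp)
    if model_type == "cox_bootstrap_lasso":
        model, _ = fit_cox_bootstrap_lasso(X, time, event, seed=seed, **hp)
        return model
    if model_type == "rsf":
        return fit_rsf(X, time, event, hyperparams=hp, seed=seed)
    raise ValueError(f"unknown model type {model_type!r}; expected one of {MODEL_TYPES}")


DEFAULT_RSF_GRID = [
    {"n_trees": 500, "mtry": "sqrt", "min_node_size": 50},
    {"n_trees": 500, "mtry": "sqrt", "min_node_size": 15},
    {"n_trees": 500, "mtry": "sqrt", "min_node_size": 5},
    {"n_trees": 500, "mtry": "third", "min_node_size": 50},
    {"n_trees": 500, "mtry": "third", "min_node_size": 15},
    {"n_trees": 500, "mtry": "third", "min_node_size": 5},
]


def tune_hyperparameters(
    model_type: str,
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    grid: list[dict],
    cv_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Pick the grid point maximizing mean cross-validated Harrell C.

    Ties go to the earlier grid point, so grids should be ordered from the
    least to the most complex candidate.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if len(grid) == 1:
        return dict(grid[0])
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    folds = stratified_kfold(event, k=cv_folds, seed=seed)
    best_score, best_point = -np.inf, None
    for point in grid:
        scores = []
        for k in range(cv_folds):
            tr, te = folds != k, folds == k
            try:
                model = fit_model(
                    model_type, X.iloc[tr], time[tr], event[tr], hyperparams=point, seed=seed + k
                )
                scores.append(harrell_c(model.risk_score(X.iloc[te]), time[te], event[te]))
            except (CoxNonConvergenceError, ValueError, ArithmeticError):
                continue
        if not scores:
            continue
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score, best_point = mean_score, point
    if best_point is None:
        raise CoxNonConvergenceError("every grid point failed during tuning")
    return dict(best_point)
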