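"""Censoring-aware prediction metrics.

Implements Harrell's concordance index, the IPCW (inverse probability of
censoring weighting) concordance index with optional horizon truncation, the
IPCW Brier score BS(tau) and its normalized integral over a time grid (IBS),
plus stratified k-fold assignment for rare-event cohorts and the rank-sum
comparison of fold-wise metrics.

Weighting conventions follow the Uno-type estimators: concordance weights are
1/G(T_i)^2 at the earlier (event) time of a pair, Brier weights 1/G(T_i) for
observed events before tau and 1/G(tau) for survivors, where G is the
censoring survival function estimated on training data (reverse Kaplan-Meier,
or a Cox model on clinical covariates) and evaluated right-continuously with
same-time events leaving the risk set first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class UndefinedMetricError(ValueError):
    """Raised when a metric has no comparable pairs / no usable observations."""


# ---------------------------------------------------------------------------
# Censoring models
# ---------------------------------------------------------------------------

def _reverse_km(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Follows the standard reverse-KM tie convention: subjects whose event
    falls on a time point leave the risk set before the censorings at that
    same time are counted.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, first_idx = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first_idx
    n_events = np.add.reduceat(e.astype(int), first_idx)
    n_censored = np.add.reduceat((~e).astype(int), first_idx)
    denom = at_risk - n_events
    factor = np.where(n_censored > 0, 1.0 - n_censored / np.where(denom > 0, denom, 1), 1.0)
    return uniq, np.cumprod(factor)


@dataclass
class KaplanMeierCensoring:
    """Covariate-free censoring distribution Ghat(t) from training data."""

    times: np.ndarray = None
    surv: np.ndarray = None

    def fit(self, time: np.ndarray, event: np.ndarray) -> "KaplanMeierCensoring":
        self.times, self.surv = _reverse_km(time, event)
        return self

    def survival(self, t: np.ndarray, X=None) -> np.ndarray:
        """Ghat(t), right-continuous; 1 before the first observed time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return np.broadcast_to(out, t.shape).copy()


@dataclass
class CoxCensoringModel:
    """Cox model for the censoring distribution on clinical covariates.

    G(t|Z) = exp(-H0(t) * exp(beta' Z)).  Falls back to Kaplan-Meier when the
    Cox fit does not converge (flat censoring, constant columns, ...).
    """

    columns: list[str] | None = None

    def fit(self, X, time: np.ndarray, event: np.ndarray) -> "CoxCensoringModel":
        from .models import CoxNonConvergenceError, fit_cox

        censor = 1 - np.asarray(event)
        cols = self.columns or list(X.columns)
        cols = [c for c in cols if c in X.columns and X[c].nunique() > 1]
        self._km = KaplanMeierCensoring().fit(time, event)
        self._cox = None
        if cols and censor.sum() >= 2:
            try:
                self._cox = fit_cox(X[cols], time, censor)
                self._cols = cols
            except CoxNonConvergenceError:
                self._cox = None
        return self

    def survival(self, t: np.ndarray, X=None) -> np.ndarray:
        """G(t|Z) evaluated right-continuously, per subject when t is a vector."""
        if self._cox is None or X is None:
            return self._km.survival(t)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        curves = self._cox.predict_survival(X[self._cols], t)
        if len(curves) == t.size:
            return np.diagonal(curves).copy()
        return curves[0]


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _concordance(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    tied_tol: float = 1e-8,
) -> float:
    """(Weighted) concordance over comparable pairs.

    A pair is comparable when the earlier time is an observed event; at tied
    times an event is compared against same-time censored subjects.  Risk
    ties score 0.5.  Pair weight is the weight of the event member.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    risk = np.asarray(risk, float)
    w = np.ones_like(time) if weights is None else np.asarray(weights, float)
    num = 0.0
    den = 0.0
    n = time.size
    for i in np.flatnonzero(event):
        later = time > time[i]
        tied_censored = (time == time[i]) & ~event
        others = later | tied_censored
        if not others.any():
            continue
        diff = risk[i] - risk[others]
        conc = (diff > tied_tol).sum() + 0.5 * (np.abs(diff) <= tied_tol).sum()
        num += w[i] ** 2 * conc
        den += w[i] ** 2 * others.sum()
    if den == 0:
        raise UndefinedMetricError("no comparable pairs")
    return float(num / den)


def harrell_c(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index: concordant / comparable pairs, ties 0.5."""
    return _concordance(risk, time, event, weights=None)


def ipcw_c(
    risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    censor_model,
    truncation: float | None = None,
    X=None,
    weight_cap_quantile: float = 0.99,
) -> float:
    """IPCW concordance index, optionally bounded at horizon ``truncation``.

    Event members of a pair are weighted by 1/Ghat(T)^2 with G from
    ``censor_model`` (fitted on training data).  With a horizon tau, events
    from tau onwards are discarded (the bounded index C_tau).  Weights can be
    capped at a quantile to guard against Ghat -> 0; the default cap is the
    99th percentile, pass 1.0 for the uncapped canonical estimator.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    g = np.asarray(censor_model.survival(time, X), float)
    if np.any((g <= 0) & (event == 1)):
        positive = g[g > 0]
        floor = positive.min() if positive.size else 1.0
        g = np.where(g <= 0, floor, g)
    w = np.divide(1.0, g, out=np.zeros_like(g), where=g > 0)
    ev = event == 1
    if ev.any() and weight_cap_quantile < 1.0:
        cap = np.quantile(w[ev], weight_cap_quantile)
        w = np.minimum(w, cap)
    eff_event = event.copy()
    if truncation is not None:
        eff_event = np.where(time >= truncation, 0, eff_event)
        if eff_event.sum() == 0:
            raise UndefinedMetricError(f"no events before horizon {truncation}")
    return _concordance(risk, time, eff_event, weights=w)


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------

def brier_score(
    surv_at_tau: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    censor_model,
    tau: float,
    X=None,
) -> float:
    """IPCW Brier score at horizon ``tau``.

    BS(tau) = n^-1 sum_i [ Shat(tau|X_i)^2 1{T_i <= tau, event} / Ghat(T_i)
                         + (1 - Shat(tau|X_i))^2 1{T_i > tau} / Ghat(tau) ].
    Subjects censored before tau contribute only through the weights.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    s = np.asarray(surv_at_tau, float)
    n = time.size
    had_event = (time <= tau) & event
    survivor = time > tau
    g_event = np.asarray(censor_model.survival(time, X), float)
    g_tau = np.asarray(censor_model.survival(np.full(n, tau), X), float)
    total = 0.0
    if had_event.any():
        ge = g_event[had_event]
        if np.any(ge <= 0):
            raise UndefinedMetricError("censoring survival zero at an event time")
        total += np.sum(s[had_event] ** 2 / ge)
    if survivor.any():
        gt = g_tau[survivor]
        if np.any(gt <= 0):
            raise UndefinedMetricError(f"censoring survival zero at horizon {tau}")
        total += np.sum((1.0 - s[survivor]) ** 2 / gt)
    return float(total / n)


def integrated_brier(
    surv_predictions: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    censor_model,
    grid: np.ndarray,
    X=None,
) -> float:
    """Trapezoidal integral of BS(tau) over ``grid``, normalized by its span.

    ``surv_predictions`` has one row per subject and one column per grid
    time.  Grid points beyond the largest observed time are dropped (the
    censoring distribution is unidentified there).
    """
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("time grid must be strictly increasing and positive")
    surv_predictions = np.asarray(surv_predictions, float)
    usable = grid <= np.max(time)
    if usable.sum() < 2:
        raise UndefinedMetricError("time grid lies outside the follow-up support")
    g = grid[usable]
    bs = np.array(
        [
            brier_score(surv_predictions[:, j], time, event, censor_model, tau, X=X)
            for j, tau in zip(np.flatnonzero(usable), g)
        ]
    )
    return float(np.trapezoid(bs, g) / (g[-1] - g[0]))


# ---------------------------------------------------------------------------
# Folds and model comparison
# ---------------------------------------------------------------------------

def stratified_kfold(event: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Event-stratified fold assignment; per-fold event counts differ by <= 1.

    Events and non-events are partitioned separately, uniformly at random.
    Returns an integer fold label in [0, k) per subject.
    """
    event = np.asarray(event).astype(int)
    if event.sum() < k or (1 - event).sum() < k:
        raise ValueError(f"need at least {k} events and {k} censored subjects")
    rng = np.random.default_rng(seed)
    folds = np.empty(event.size, dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def wilcoxon_compare(metric_a: np.ndarray, metric_b: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney U) p-value on fold-wise metrics.

    For the small samples that fold-wise comparison produces (up to 12
    values in total) the null distribution is enumerated exactly over all
    group assignments of the midranks, which handles ties; larger samples
    fall back to scipy.  Returns 1.0 when every value is tied.
    """
    from itertools import combinations

    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length samples of at least 3 folds")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = a.size
    if pooled.size <= 12:
        ranks = stats.rankdata(pooled)
        obs = ranks[:n].sum()
        mu = ranks.sum() * n / pooled.size
        dev = abs(obs - mu)
        hits = total = 0
        for comb in combinations(range(pooled.size), n):
            r = ranks[list(comb)].sum()
            total += 1
            hits += abs(r - mu) >= dev - 1e-12
        return float(hits / total)
    method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
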