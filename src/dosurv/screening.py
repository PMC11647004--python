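"""Train-set feature screening.

Three stages, always fitted on training data only:

1. degenerate removal — constant columns and exact duplicates (pairwise
   correlation 1) are dropped;
2. diagnosis-indicator selection — each first-cancer indicator is tested
   against the event with a Pearson chi-square test (Fisher's exact test when
   there are fewer than ten exposed cases) and kept at p < 0.01;
3. clustering-based redundancy elimination for dosiomics — complete-linkage
   hierarchical clustering with distance 1 - Kendall's tau-b, cut at 0.2 (so
   any two features in one cluster have tau >= 0.8), each multi-member
   cluster represented by the member with the highest per-SD hazard ratio in
   a multivariate Cox model fitted on the cluster.

A fitted :class:`ScreeningResult` is a pure column selection; applying it to
a test table never recomputes a statistic.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .features.table import FeatureTable


@dataclass
class ScreeningConfig:
    p_threshold: float = 0.01
    fisher_min_cases: int = 10
    cluster_distance_threshold: float = 0.2
    drop_degenerate: bool = True
    select_indicators: bool = True
    cluster_dosiomics: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 < self.cluster_distance_threshold < 1:
            raise ValueError("cluster_distance_threshold must be in (0, 1)")


@dataclass
class ScreeningResult:
    """Column selection fitted on a train set."""

    kept_columns: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    clusters: list[tuple[list[str], str]] = field(default_factory=list)

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        """Project a (train or test) table onto the kept columns."""
        return data[self.kept_columns]

    def to_json(self, path) -> None:
        payload = {
            "kept_columns": self.kept_columns,
            "dropped": self.dropped,
            "clusters": [{"members": m, "representative": r} for m, r in self.clusters],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, FeatureTable) else table


def drop_degenerate(table) -> ScreeningResult:
    """Drop constant columns and exact duplicates (correlation 1).

    For a duplicated pair the column that comes later in the table's column
    order is dropped, which makes the result deterministic.
    """
    data = _as_frame(table)
    if len(data) < 2:
        raise ValueError("degenerate screening needs at least 2 rows")
    dropped: dict[str, str] = {}
    values = data.to_numpy(dtype=float)
    std = values.std(axis=0)
    cols = list(data.columns)
    for j, c in enumerate(cols):
        if std[j] == 0:
            dropped[c] = "constant"
    live = [j for j, c in enumerate(cols) if c not in dropped]
    if len(live) >= 2:
        sub = values[:, live]
        corr = np.corrcoef(sub, rowvar=False)
        for a in range(len(live)):
            ca = cols[live[a]]
            if ca in dropped:
                continue
            for b in range(a + 1, len(live)):
                cb = cols[live[b]]
                if cb in dropped:
                    continue
                if corr[a, b] >= 1.0 - 1e-12:
                    dropped[cb] = f"duplicate of {ca}"
    kept = [c for c in cols if c not in dropped]
    return ScreeningResult(kept_columns=kept, dropped=dropped)


def indicator_test_pvalue(indicator: np.ndarray, events: np.ndarray, fisher_min_cases: int = 10) -> tuple[float, str]:
    """p-value of the indicator-event association and the test branch used.

    Builds the 2x2 exposure-by-event table; Fisher's exact test when the
    exposed-with-event cell holds fewer than ``fisher_min_cases`` patients,
    Pearson chi-square without continuity correction otherwise.
    """
    indicator = np.asarray(indicator)
    events = np.asarray(events)
    for arr, name in ((indicator, "indicator"), (events, "events")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    a = int(np.sum((indicator == 1) & (events == 1)))
    b = int(np.sum((indicator == 1) & (events == 0)))
    c = int(np.sum((indicator == 0) & (events == 1)))
    d = int(np.sum((indicator == 0) & (events == 0)))
    table = np.array([[a, b], [c, d]])
    if a < fisher_min_cases:
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), "fisher"
    return float(stats.chi2_contingency(table, correction=False)[1]), "chi2"


def select_diagnosis_indicators(
    indicators: pd.DataFrame, events: np.ndarray, config: ScreeningConfig | None = None
) -> list[str]:
    """Names of the indicator columns significantly associated with the event."""
    config = config or ScreeningConfig()
    kept = []
    for col in indicators.columns:
        p, _ = indicator_test_pvalue(
            indicators[col].to_numpy(), events, fisher_min_cases=config.fisher_min_cases
        )
        if p < config.p_threshold:
            kept.append(col)
    return kept


def kendall_distance_matrix(data: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Kendall tau-b distances between columns."""
    cols = list(data.columns)
    k = len(cols)
    values = data.to_numpy(dtype=float)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            tau = stats.kendalltau(values[:, a], values[:, b]).statistic
            if not np.isfinite(tau):
                tau = 0.0
            dist[a, b] = dist[b, a] = 1.0 - tau
    return dist


def _cox_representative(
    members: pd.DataFrame, time: np.ndarray, event: np.ndarray
) -> tuple[str, str]:
    """Member with the highest hazard ratio in a multivariate Cox fit.

    Members are standardized to unit variance first, so hazard ratios are
    per-SD and comparable across scales.  Falls back to univariate Cox fits
    when the multivariate model does not converge (near-collinear clusters).
    """
    from .models import CoxNonConvergenceError, cox_coefficients

    std = members / members.std(axis=0, ddof=1)
    try:
        coefs = cox_coefficients(std, time, event)
        mode = "multivariate"
    except CoxNonConvergenceError:
        coefs = {}
        for col in std.columns:
            try:
                coefs[col] = cox_coefficients(std[[col]], time, event)[col]
            except CoxNonConvergenceError:
                coefs[col] = -np.inf
        mode = "univariate-fallback"
    best = max(coefs, key=lambda c: (coefs[c], -list(members.columns).index(c)))
    return best, mode


def cluster_redundancy_elimination(
    table,
    time: np.ndarray,
    event: np.ndarray,
    config: ScreeningConfig | None = None,
    groups: dict[str, list[str]] | None = None,
) -> ScreeningResult:
    """Complete-linkage redundancy elimination over feature columns.

    ``groups`` optionally maps a label (e.g. a heart subpart) to its columns;
    clustering is then run within each group separately.  Every pair of
    columns that ends up in one cluster is guaranteed a Kendall tau of at
    least ``1 - cluster_distance_threshold``.
    """
    config = config or ScreeningConfig()
    data = _as_frame(table)
    if groups is None:
        groups = {"all": list(data.columns)}

    kept: list[str] = []
    dropped: dict[str, str] = {}
    clusters_out: list[tuple[list[str], str]] = []
    for _, cols in groups.items():
        sub = data[cols]
        if len(cols) < 2:
            kept.extend(cols)
            continue
        dist = kendall_distance_matrix(sub)
        z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(z, t=config.cluster_distance_threshold, criterion="distance")
        for lab in np.unique(labels):
            members = [c for c, l in zip(cols, labels) if l == lab]
            if len(members) == 1:
                kept.append(members[0])
                continue
            rep, mode = _cox_representative(sub[members], time, event)
            clusters_out.append((members, rep))
            kept.append(rep)
            for m in members:
                if m != rep:
                    dropped[m] = f"clustered with representative {rep} ({mode})"
    kept = [c for c in data.columns if c in set(kept)]  # preserve column order
    return ScreeningResult(kept_columns=kept, dropped=dropped, clusters=clusters_out)


def fit_screening(
    table: FeatureTable,
    time: np.ndarray,
    event: np.ndarray,
    config: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Full train-set screening over a feature table.

    Degenerate removal runs over all columns, the association screen over the
    diagnosis indicators, and — when enabled — redundancy clustering over the
    dosiomics columns (first-order/texture families), per region.
    """
    config = config or ScreeningConfig()
    data = table.data
    dropped: dict[str, str] = {}
    kept = list(data.columns)

    if config.drop_degenerate:
        res = drop_degenerate(data)
        dropped.update(res.dropped)
        kept = res.kept_columns

    if config.select_indicators:
        diag_cols = [c for c in table.diagnosis_columns() if c in kept]
        if diag_cols:
            selected = set(select_diagnosis_indicators(data[diag_cols], event, config))
            for c in diag_cols:
                if c not in selected:
                    dropped[c] = "indicator not associated with event"
            kept = [c for c in kept if c not in dropped]

    clusters: list[tuple[list[str], str]] = []
    if config.cluster_dosiomics:
        dosio = [
            c
            for c in kept
            if table.column_meta[c]["kind"] == "dosimetric"
            and table.column_meta[c]["family"] not in (None, "dvh")
            and not c.endswith("__mean_dose")
        ]
        if len(dosio) >= 2:
            groups: dict[str, list[str]] = {}
            for c in dosio:
                groups.setdefault(table.column_meta[c]["region"], []).append(c)
            res = cluster_redundancy_elimination(
                data[dosio], time, event, config=config, groups=groups
            )
            dropped.update(res.dropped)
            clusters = res.clusters
            keep_set = set(res.kept_columns)
            kept = [c for c in kept if c not in set(dosio) - keep_set]

    return ScreeningResult(kept_columns=kept, dropped=dropped, clusters=clusters)
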