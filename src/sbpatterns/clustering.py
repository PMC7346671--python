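"""Two-phase clustering of diurnal sedentary-behavior trajectories.

Phase I runs k-means for longitudinal data on the (n_days x 14) matrix of
completed daily trajectories: Lloyd's algorithm with squared Euclidean
distance, five random restarts, and the restart with the highest
Calinski-Harabasz criterion retained. Phase II clusters participants on the
proportions of their adherent days falling in each day cluster, using
agglomerative clustering with complete linkage; the number of participant
patterns is the cut that maximises average silhouette width.

The Calinski-Harabasz criterion and silhouette widths are implemented here
from their definitions (with explicit degenerate-case conventions); tests
cross-check them against independent library and brute-force computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from ._rng import substream

__all__ = [
    "DayClusterModel",
    "PatternAssignment",
    "kml_fit",
    "calinski_harabasz",
    "select_k_phase1",
    "profiles_from_assignments",
    "hier_cluster",
    "silhouette",
    "concordance",
]

KML_MAX_ITER = 100
DEFAULT_RESTARTS = 5


# ---------------------------------------------------------------------------
# Phase I: longitudinal k-means over day trajectories
# ---------------------------------------------------------------------------


@dataclass
class DayClusterModel:
    """Fitted Phase I partition of days."""

    k: int
    centroids: np.ndarray  # k x 14
    assignments: np.ndarray  # day index -> cluster index (0-based)
    ch_value: float
    restart_scores: list[float]
    labels: dict[int, str] = field(default_factory=dict)  # cluster -> letter
    sse: float = np.nan
    sse_history: list[float] = field(default_factory=list)  # per-iteration, best restart

    def letter_assignments(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.assignments])


def calinski_harabasz(X: np.ndarray, assignments: np.ndarray) -> float:
    """Calinski-Harabasz criterion: [tr(B)/(k-1)] / [tr(W)/(n-k)].

    B is the between-cluster scatter about the grand mean, W the pooled
    within-cluster scatter about the centroids. Perfect separation (W = 0
    with distinct centroids) returns +inf as a documented sentinel.
    """
    X = np.asarray(X, float)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    k, n = len(clusters), X.shape[0]
    if k < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    if n <= k:
        raise ValueError("Calinski-Harabasz requires n > k")
    grand = X.mean(axis=0)
    trace_b = 0.0
    trace_w = 0.0
    for c in clusters:
        pts = X[assignments == c]
        if pts.shape[0] == 0:
            raise ValueError(f"empty cluster {c}")
        centroid = pts.mean(axis=0)
        trace_b += pts.shape[0] * float(np.sum((centroid - grand) ** 2))
        trace_w += float(np.sum((pts - centroid) ** 2))
    if trace_w == 0.0:
        return np.inf
    return (trace_b / (k - 1)) / (trace_w / (n - k))


def _lloyd(
    X: np.ndarray, init: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    centroids = init.copy()
    assignments = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(KML_MAX_ITER):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_assign = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_assign == c):
                # Re-seed an empty cluster with the point farthest from its
                # current centroid.
                far = d2[np.arange(X.shape[0]), new_assign].argmax()
                centroids[c] = X[far]
                new_assign[far] = c
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        for c in range(k):
            centroids[c] = X[assignments == c].mean(axis=0)
        history.append(float(np.sum((X - centroids[assignments]) ** 2)))
    sse = float(np.sum((X - centroids[assignments]) ** 2))
    return centroids, assignments, sse, history


def _order_labels(centroids: np.ndarray) -> dict[int, str]:
    """Letters A, B, ... by descending centroid total sedentary minutes."""
    order = np.argsort(-centroids.sum(axis=1), kind="stable")
    return {int(c): ascii_uppercase[rank] for rank, c in enumerate(order)}


def kml_fit(
    X: np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> DayClusterModel:
    """Fit longitudinal k-means on completed trajectories.

    Each restart draws k distinct observed trajectories as initial centroids;
    the restart with the highest Calinski-Harabasz value is returned (ties
    resolved to the earliest restart).
    """
    X = np.asarray(X, float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_restarts < 1:
        raise ValueError("need at least one restart")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {distinct.shape[0]} distinct trajectories")
    rng = substream(seed, "kml-restarts")
    best = None
    scores: list[float] = []
    for _ in range(n_restarts):
        init = distinct[rng.choice(distinct.shape[0], size=k, replace=False)]
        centroids, assignments, sse, history = _lloyd(X, init, k)
        ch = calinski_harabasz(X, assignments)
        scores.append(ch)
        if best is None or ch > best[0]:
            best = (ch, centroids, assignments, sse, history)
    ch, centroids, assignments, sse, history = best
    return DayClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        ch_value=float(ch),
        restart_scores=scores,
        labels=_order_labels(centroids),
        sse=sse,
        sse_history=history,
    )


def _spherical_ic(X: np.ndarray, model: DayClusterModel) -> tuple[float, float]:
    """AIC/BIC of the partition under a spherical-Gaussian equivalence.

    Parameters: k x d centroid means + one shared variance. Reported as
    diagnostics only; selection is by the Calinski-Harabasz criterion.
    """
    n, d = X.shape
    sigma2 = max(model.sse / (n * d), 1e-12)
    loglik = -0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
    p = model.k * d + 1
    return -2 * loglik + 2 * p, -2 * loglik + p * np.log(n)


def select_k_phase1(
    X: np.ndarray,
    k_range: range | list[int] = range(2, 7),
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, dict[int, DayClusterModel]]:
    """Fit every candidate k and choose the highest Calinski-Harabasz value.

    Returns ``(chosen_k, diagnostics, models)``; the diagnostics table (one
    row per k: CH, AIC, BIC, SSE) is exposed so a manual override remains
    possible, and a ``stable`` flag is False when the criterion favours the
    smallest candidate and decays monotonically, the signature of an
    unclustered sample.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    rows = []
    models: dict[int, DayClusterModel] = {}
    for k in k_range:
        model = kml_fit(X, k, n_restarts=n_restarts, seed=seed + k)
        aic, bic = _spherical_ic(X, model)
        models[k] = model
        rows.append({"k": k, "ch": model.ch_value, "aic": aic, "bic": bic, "sse": model.sse})
    diag = pd.DataFrame(rows)
    chosen = int(diag.loc[diag["ch"].idxmax(), "k"])  # idxmax: first max -> smallest k
    ch_vals = diag["ch"].to_numpy()
    unstable = chosen == min(k_range) and np.all(np.diff(ch_vals) < 0)
    diag["stable"] = not unstable
    return chosen, diag, models


# ---------------------------------------------------------------------------
# Phase II: hierarchical clustering of participant profiles
# ---------------------------------------------------------------------------


def profiles_from_assignments(
    model: DayClusterModel, participant_ids: np.ndarray | list[str]
) -> pd.DataFrame:
    """Per-participant fractions of days in each day cluster.

    Proportions are used (rather than counts) because participants
    contribute different numbers of adherent days.
    """
    pids = np.asarray(participant_ids)
    if pids.shape[0] != model.assignments.shape[0]:
        raise ValueError("one participant id per assigned day is required")
    frame = pd.DataFrame({"participant_id": pids, "cluster": model.assignments})
    tally = frame.groupby("participant_id")["cluster"].value_counts().unstack(fill_value=0)
    tally = tally.reindex(columns=range(model.k), fill_value=0)
    totals = tally.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("participant with zero assigned days")
    props = tally.div(totals, axis=0)
    props.columns = [f"prop_{model.labels[c]}" for c in props.columns]
    props = props[sorted(props.columns)]
    return props.reset_index()


def silhouette(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-observation silhouette widths s(i) = (b - a) / max(a, b).

    a(i): mean distance to own cluster excluding self; b(i): smallest mean
    distance to another cluster. Singletons take s = 0, as do points with
    a = b = 0 (identical points split across clusters).
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    widths = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths, float(widths.mean())


@dataclass
class PatternAssignment:
    """Phase II result: participant -> diurnal SB pattern."""

    patterns: pd.Series  # participant_id -> pattern index 1..K
    K: int
    avg_silhouette: float
    silhouette_by_K: dict[int, float]
    linkage: str = "complete"
    dominant_cluster: dict[int, str] = field(default_factory=dict)  # pattern -> letter


def _relabel_by_dominant_cluster(
    profiles: pd.DataFrame, raw_labels: np.ndarray
) -> tuple[np.ndarray, dict[int, str]]:
    """Order patterns 1..K by the day-cluster letter each is dominated by.

    Pattern 1 corresponds to day cluster A, pattern 2 to B, and so on; when
    two raw clusters share a dominant letter, the one with the higher mean
    dominant proportion takes the earlier pattern index.
    """
    prop_cols = [c for c in profiles.columns if c.startswith("prop_")]
    means = pd.DataFrame(
        {c: [profiles.loc[raw_labels == g, c].mean() for g in np.unique(raw_labels)]
         for c in prop_cols},
        index=np.unique(raw_labels),
    )
    dominant = means.idxmax(axis=1)
    strength = means.max(axis=1)
    order = sorted(means.index, key=lambda g: (dominant[g], -strength[g], g))
    mapping = {g: i + 1 for i, g in enumerate(order)}
    letters = {mapping[g]: dominant[g].removeprefix("prop_") for g in means.index}
    return np.array([mapping[g] for g in raw_labels]), letters


def hier_cluster(
    profiles: pd.DataFrame, K_range: range | list[int] = range(2, 9)
) -> PatternAssignment:
    """Complete-linkage hierarchical clustering on day-cluster proportions.

    The dendrogram (Euclidean distances on the raw proportion vectors) is cut
    at every K in ``K_range``; the cut maximising average silhouette width is
    returned, ties resolved to the smaller K.
    """
    K_range = list(K_range)
    prop_cols = [c for c in profiles.columns if c.startswith("prop_")]
    X = profiles[prop_cols].to_numpy(float)
    n = X.shape[0]
    if not K_range:
        raise ValueError("empty K_range")
    if n < max(K_range):
        raise ValueError("fewer participants than the largest candidate K")
    Z = linkage(X, method="complete", metric="euclidean")
    sil_by_K: dict[int, float] = {}
    labels_by_K: dict[int, np.ndarray] = {}
    for K in K_range:
        if K < 2 or K > n:
            continue
        # cut by merge order (as R's cutree), so every K yields exactly K
        # clusters even under tied merge heights
        labels = cut_tree(Z, n_clusters=K).ravel()
        _, avg = silhouette(X, labels)
        sil_by_K[K] = avg
        labels_by_K[K] = labels
    if not sil_by_K:
        raise ValueError("no valid cut in K_range")
    best_K = min(sil_by_K, key=lambda K: (-sil_by_K[K], K))
    patterns, letters = _relabel_by_dominant_cluster(profiles, labels_by_K[best_K])
    return PatternAssignment(
        patterns=pd.Series(patterns, index=profiles["participant_id"].to_numpy(), name="pattern"),
        K=int(len(np.unique(patterns))),
        avg_silhouette=sil_by_K[best_K],
        silhouette_by_K=sil_by_K,
        dominant_cluster=letters,
    )


# ---------------------------------------------------------------------------
# Concordance between alignment variants
# ---------------------------------------------------------------------------


def _matched_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """% agreement after optimally matching b's labels to a's (Hungarian)."""
    ua, ub = np.unique(a), np.unique(b)
    C = np.zeros((len(ua), len(ub)))
    for i, la in enumerate(ua):
        for j, lb in enumerate(ub):
            C[i, j] = np.sum((a == la) & (b == lb))
    rows, cols = linear_sum_assignment(-C)
    return 100.0 * C[rows, cols].sum() / a.shape[0]


def concordance(
    assign_a: pd.Series | np.ndarray,
    assign_b: pd.Series | np.ndarray,
    pattern_a: pd.Series | None = None,
    pattern_b: pd.Series | None = None,
) -> tuple[float, float | None]:
    """Day- and participant-level % classified identically across variants.

    Day assignments (and, when given, participant patterns) from variant B
    are matched to variant A by maximal overlap before comparing. Series
    inputs are aligned on their index; both variants must cover the same
    days/participants.
    """

    def aligned(x, y):
        if isinstance(x, pd.Series) and isinstance(y, pd.Series):
            if set(x.index) != set(y.index):
                raise ValueError("variants cover different units")
            y = y.reindex(x.index)
            return x.to_numpy(), y.to_numpy()
        x, y = np.asarray(x), np.asarray(y)
        if x.shape != y.shape:
            raise ValueError("variants cover different units")
        return x, y

    a, b = aligned(assign_a, assign_b)
    day_pct = _matched_agreement(a, b)
    part_pct = None
    if pattern_a is not None and pattern_b is not None:
        pa, pb = aligned(pattern_a, pattern_b)
        part_pct = _matched_agreement(pa, pb)
    return day_pct, part_pct
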