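"""Correlating divergence with transfer performance; clustering institutions.

* :func:`correlate` — Pearson r / R² between a pairwise divergence matrix and
  the matching transfer-performance cells (self cells excluded), pooled and
  per training institution.
* :class:`KMedoids` — PAM (build + swap) on a precomputed dissimilarity
  matrix. The build phase is greedy and deterministic; the swap phase applies
  best-improvement swaps until no swap lowers the total within-cluster
  dissimilarity.
* :func:`elbow_select_k` — within-cluster sum of *squared* dissimilarities
  per k, with k chosen at the point of maximum perpendicular distance to the
  chord joining the curve endpoints (ties toward the smallest k).
* :func:`mds_embed` — classical (Torgerson) multidimensional scaling to 2-D.
* :func:`intra_inter_summary`, :func:`flag_outliers` — per-cluster transfer
  summaries and institutions whose within-cluster divergence deviates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .divergence import DivergenceMatrix

__all__ = [
    "CorrelationReport",
    "ClusterAssignment",
    "KMedoids",
    "correlate",
    "kmedoids_fit",
    "symmetrize",
    "elbow_select_k",
    "ElbowResult",
    "mds_embed",
    "intra_inter_summary",
    "flag_outliers",
    "OutlierFlag",
]


# ---------------------------------------------------------------------------
# correlation


@dataclass
class CorrelationReport:
    metric_name: str
    performance_field: str
    pearson_r: float
    r_squared: float
    per_institution: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(self.r_squared - self.pearson_r**2) > 1e-12:
            raise ValueError("r_squared must equal pearson_r**2")


def correlate(divergence: DivergenceMatrix, results: pd.DataFrame,
              performance_field: str = "micro_f1",
              level: str | None = None) -> CorrelationReport:
    """Pearson correlation between divergence(A→B) and model-A-on-B transfer
    performance over all non-self pairs, plus per-training-institution r."""
    df = results
    if "design" in df.columns:
        df = df[df["design"] == "pairwise"]
    if level is not None:
        df = df[df["level"] == level]
    df = df[~df["is_self"].astype(bool)]
    insts = set(divergence.institutions)
    df = df[df["train_id"].isin(insts) & df["test_id"].isin(insts)]
    if len(df) < 3:
        raise ValueError("need at least 3 non-self pairs to correlate")
    x = np.array([divergence.values.loc[r.train_id, r.test_id]
                  for r in df.itertuples()])
    y = df[performance_field].to_numpy(dtype=float)
    r = float(stats.pearsonr(x, y).statistic)
    per_inst: dict[str, float] = {}
    for inst, sub in df.groupby("train_id"):
        if len(sub) >= 3 and sub[performance_field].nunique() > 1:
            xi = np.array([divergence.values.loc[inst, t] for t in sub["test_id"]])
            per_inst[str(inst)] = float(
                stats.pearsonr(xi, sub[performance_field].to_numpy()).statistic)
        else:
            per_inst[str(inst)] = float("nan")
    return CorrelationReport(
        metric_name=divergence.metric_name,
        performance_field=performance_field,
        pearson_r=r, r_squared=r * r,
        per_institution=per_inst, n_pairs=len(df))


# ---------------------------------------------------------------------------
# PAM k-medoids


def _check_distance(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric; "
                         "symmetrize() a directed divergence matrix first")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM clustering on a precomputed symmetric dissimilarity matrix.

    ``fit`` exposes ``medoid_indices_``, ``labels_``, ``inertia_`` (total
    within-cluster dissimilarity) and ``inertia_squared_`` (sum of squared
    within-cluster dissimilarities, used by the elbow curve). The swap phase
    (best improving swap until convergence) is run from the deterministic
    greedy build plus ``n_restarts`` seeded random initializations, keeping
    the lowest-cost solution; single-start PAM can stall in a local optimum
    even on four points. Ties break toward the lowest index.
    """

    def __init__(self, n_clusters: int = 2, random_state: int | None = 0,
                 n_restarts: int = 8, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.max_iter = max_iter

    def _greedy_build(self, D: np.ndarray, k: int) -> list[int]:
        n = D.shape[0]
        medoids = [int(np.argmin(D.sum(axis=1)))]
        while len(medoids) < k:
            dist_near = D[:, medoids].min(axis=1)
            best_gain, best_j = -np.inf, None
            for j in range(n):
                if j in medoids:
                    continue
                gain = np.maximum(dist_near - D[:, j], 0.0).sum()
                if gain > best_gain + 1e-15:
                    best_gain, best_j = gain, j
            medoids.append(int(best_j))
        return sorted(medoids)

    def _swap_to_convergence(self, D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
        n = D.shape[0]
        cost = D[:, medoids].min(axis=1).sum()
        for _ in range(self.max_iter):
            best_cost, best_pair = cost, None
            for mi in range(len(medoids)):
                for h in range(n):
                    if h in medoids:
                        continue
                    trial = medoids[:mi] + [h] + medoids[mi + 1:]
                    c = D[:, trial].min(axis=1).sum()
                    if c < best_cost - 1e-12:
                        best_cost, best_pair = c, (mi, h)
            if best_pair is None:
                break
            medoids[best_pair[0]] = best_pair[1]
            medoids = sorted(medoids)
            cost = best_cost
        return medoids, float(cost)

    def fit(self, X, y=None) -> "KMedoids":
        D = _check_distance(X)
        n = D.shape[0]
        k = int(self.n_clusters)
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        inits = [self._greedy_build(D, k)]
        rng = np.random.default_rng(self.random_state)
        for _ in range(self.n_restarts):
            inits.append(sorted(int(i) for i in
                                rng.choice(n, size=k, replace=False)))
        best_medoids, best_cost = None, np.inf
        for init in inits:
            medoids, cost = self._swap_to_convergence(D, list(init))
            if cost < best_cost - 1e-12 or (best_medoids is None):
                best_medoids, best_cost = medoids, cost
        medoids = best_medoids
        self.medoid_indices_ = np.array(medoids, dtype=int)
        assign = D[:, medoids].argmin(axis=1)
        # medoids always belong to their own cluster
        for ci, m in enumerate(medoids):
            assign[m] = ci
        self.labels_ = assign
        within = D[np.arange(n), self.medoid_indices_[assign]]
        self.inertia_ = float(within.sum())
        self.inertia_squared_ = float((within**2).sum())
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    """k-medoids output on named institutions."""

    k: int
    medoid_ids: tuple[str, ...]
    labels: dict[str, int]
    total_within_dissimilarity: float
    total_within_squared: float
    embedding: dict[str, tuple[float, float]] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    @property
    def clusters(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.labels.values())))


def symmetrize(divergence: DivergenceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Element-wise mean of M and Mᵀ; the diagonal is preserved."""
    if isinstance(divergence, DivergenceMatrix):
        return divergence.symmetrized()
    m = divergence.to_numpy(dtype=float)
    sym = (m + m.T) / 2.0
    np.fill_diagonal(sym, np.diag(m))
    return pd.DataFrame(sym, index=divergence.index, columns=divergence.columns)


def _as_frame(distance) -> pd.DataFrame:
    if isinstance(distance, DivergenceMatrix):
        return distance.symmetrized()
    if isinstance(distance, pd.DataFrame):
        return distance
    arr = np.asarray(distance, dtype=float)
    ids = [str(i) for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids, columns=ids)


def kmedoids_fit(distance, k: int, seed: int | None = 0) -> ClusterAssignment:
    """PAM on a symmetric dissimilarity matrix (DataFrame keeps names)."""
    frame = _as_frame(distance)
    est = KMedoids(n_clusters=k, random_state=seed).fit(frame.to_numpy())
    ids = list(frame.index)
    return ClusterAssignment(
        k=k,
        medoid_ids=tuple(ids[m] for m in est.medoid_indices_),
        labels={ids[i]: int(c) for i, c in enumerate(est.labels_)},
        total_within_dissimilarity=est.inertia_,
        total_within_squared=est.inertia_squared_)


@dataclass
class ElbowResult:
    k: int
    ks: tuple[int, ...]
    costs: tuple[float, ...]
    method: str


def elbow_select_k(distance, k_range: tuple[int, int] = (2, 25),
                   seed: int | None = 0) -> ElbowResult:
    """Choose k from the within-cluster sum-of-squared-dissimilarities curve.

    Primary criterion: maximum perpendicular distance to the chord joining
    the curve endpoints (ties toward smaller k). The curve is computed from
    one k below the selection range (down to k=1) so a drop *into* the
    smallest candidate k is visible; the selected k stays within ``k_range``.
    If the curve is anomalously non-decreasing somewhere, falls back to the
    maximum second difference with a warning.
    """
    frame = _as_frame(distance)
    n = len(frame)
    k_min, k_max = k_range
    k_max = min(k_max, n - 1)
    if k_max < k_min:
        raise ValueError(f"need at least {k_min + 1} points for the elbow scan")
    ks = list(range(max(1, k_min - 1), k_max + 1))
    costs = [kmedoids_fit(frame, k, seed).total_within_squared for k in ks]
    if max(costs) <= 1e-15:
        warnings.warn("all dissimilarities are ~0; elbow is degenerate, "
                      "returning k_min", stacklevel=2)
        return ElbowResult(k=k_min, ks=tuple(ks), costs=tuple(costs),
                           method="degenerate")
    method = "distance_to_chord"
    if any(costs[i + 1] > costs[i] + 1e-12 for i in range(len(costs) - 1)):
        warnings.warn("elbow curve is not non-increasing; falling back to the "
                      "maximum second difference", stacklevel=2)
        method = "second_difference"
        if len(costs) < 3:
            return ElbowResult(k=k_min, ks=tuple(ks), costs=tuple(costs), method=method)
        second = [costs[i - 1] - 2 * costs[i] + costs[i + 1]
                  if ks[i] >= k_min else -np.inf
                  for i in range(1, len(costs) - 1)]
        best = int(np.argmax(second)) + 1
        return ElbowResult(k=max(ks[best], k_min), ks=tuple(ks),
                           costs=tuple(costs), method=method)
    # normalize both axes, then perpendicular offset from the endpoint chord
    x = (np.array(ks, dtype=float) - ks[0]) / max(ks[-1] - ks[0], 1)
    c = np.array(costs, dtype=float)
    span = c[0] - c[-1]
    y = (c - c[-1]) / span if span > 0 else np.zeros_like(c)
    # chord in normalized coordinates is y = 1 - x; a convex decreasing curve
    # lies below it, so the offset (1 - x) - y is positive at the elbow
    offsets = (1.0 - x) - y
    offsets[np.array(ks) < k_min] = -np.inf
    best = int(np.argmax(offsets > np.max(offsets) - 1e-12))
    return ElbowResult(k=ks[best], ks=tuple(ks), costs=tuple(costs), method=method)


# ---------------------------------------------------------------------------
# classical MDS


def mds_embed(distance, seed: int | None = None) -> pd.DataFrame:
    """Classical (Torgerson) MDS to 2-D.

    Double-centers the squared dissimilarity matrix, takes the top-2
    eigenpairs and scales eigenvectors by sqrt(eigenvalue). Orientation is
    fixed by requiring the entry of largest magnitude in each axis to be
    positive. Warns if negative eigenvalues dominate (non-Euclidean input).
    """
    frame = _as_frame(distance)
    D = _check_distance(frame.to_numpy())
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n > 1 and -vals[-1] > max(vals[0], 0):
        warnings.warn("negative eigenvalues dominate; dissimilarities are "
                      "strongly non-Euclidean", stacklevel=2)
    coords = np.zeros((n, 2))
    for axis in range(min(2, n)):
        lam = max(vals[axis], 0.0)
        col = vecs[:, axis] * np.sqrt(lam)
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            col = -col
        coords[:, axis] = col
    return pd.DataFrame(coords, index=frame.index, columns=["x", "y"])


# ---------------------------------------------------------------------------
# cluster summaries and outliers


def intra_inter_summary(assignment: ClusterAssignment,
                        results: pd.DataFrame,
                        level: str | None = None) -> pd.DataFrame:
    """Mean [SD] transfer performance for models inside each cluster, split
    into intracluster (test in same cluster, non-self) and intercluster
    cells. Singleton clusters report intercluster only."""
    df = results
    if "design" in df.columns:
        df = df[df["design"] == "pairwise"]
    if level is not None:
        df = df[df["level"] == level]
    df = df[~df["is_self"].astype(bool)]
    rows = []
    for cluster in assignment.clusters:
        members = set(assignment.members(cluster))
        sub = df[df["train_id"].isin(members)]
        intra = sub[sub["test_id"].isin(members)]
        inter = sub[~sub["test_id"].isin(members)]
        row = {"cluster": cluster, "n_members": len(members),
               "n_intra_cells": len(intra), "n_inter_cells": len(inter)}
        for name, part in (("intra", intra), ("inter", inter)):
            for metric in ("accuracy", "micro_f1"):
                vals = part[metric].to_numpy(dtype=float)
                row[f"{name}_{metric}_mean"] = float(vals.mean()) if len(vals) else float("nan")
                row[f"{name}_{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


@dataclass(frozen=True)
class OutlierFlag:
    institution: str
    cluster: int
    mean_within_divergence: float
    cluster_mean: float
    cluster_sd: float
    deviation_sd: float  # z relative to cluster spread; inf for singletons


def flag_outliers(divergence, assignment: ClusterAssignment,
                  threshold_sd: float = 1.0) -> list[OutlierFlag]:
    """Institutions whose mean within-cluster divergence exceeds the cluster
    mean by ``threshold_sd`` cluster SDs, plus all singleton-cluster members;
    sorted by deviation (singletons first)."""
    frame = _as_frame(divergence)
    flags: list[OutlierFlag] = []
    for cluster in assignment.clusters:
        members = assignment.members(cluster)
        if len(members) == 1:
            inst = members[0]
            others = [i for i in frame.index if i != inst]
            mean_div = float(frame.loc[inst, others].mean()) if others else 0.0
            flags.append(OutlierFlag(inst, cluster, mean_div, float("nan"),
                                     float("nan"), float("inf")))
            continue
        means = {i: float(frame.loc[i, [j for j in members if j != i]].mean())
                 for i in members}
        mu = float(np.mean(list(means.values())))
        sd = float(np.std(list(means.values())))  # population SD
        if sd <= 0:
            continue
        for inst, m in means.items():
            z = (m - mu) / sd
            if z > threshold_sd:
                flags.append(OutlierFlag(inst, cluster, m, mu, sd, z))
    return sorted(flags, key=lambda f: -f.deviation_sd)
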