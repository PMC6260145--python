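"""k-means clustering of per-sample I-exon Z-score profiles.

Samples are partitioned into expression archetypes (clusters Z0..Z{k-1}) by
Lloyd's algorithm under a missing-value-aware Euclidean distance: absent
cells (RPKM = 0, masked as NaN in the Z matrix) contribute nothing, and the
partial squared distance is rescaled by D/m (D = dimension, m = observed
coordinates) so that profiles with different amounts of missingness remain
comparable. Centroid updates average only the observed contributions per
coordinate. The best of ``n_runs`` random restarts (seed + run index) by
within-cluster sum of squares is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ClusterError(ValueError):
    """Invalid clustering input."""


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 10
    n_runs: int = 100
    distance: str = "euclidean"
    seed: int = 0
    max_iter: int = 300
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ClusterError("k must be >= 1")
        if self.n_runs < 1:
            raise ClusterError("n_runs must be >= 1")
        if self.distance != "euclidean":
            raise ClusterError("only Euclidean distance is supported")


@dataclass
class ClusterModel:
    centroids: np.ndarray          # k x regions
    assignments: pd.Series         # sample_id -> "Z<j>"
    within_ss: float
    run_seeds: list[int] = field(default_factory=list)
    region_names: list[str] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Integer cluster indices in sample order."""
        return self.assignments.str.removeprefix("Z").astype(int).to_numpy()


def masked_euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance ignoring NaN coordinates of ``x``, rescaled by D/m.

    With no missing coordinates this is the ordinary Euclidean distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ClusterError("vectors must have equal length")
    observed = ~(np.isnan(x) | np.isnan(y))
    m = int(observed.sum())
    if m == 0:
        raise ClusterError("all coordinates masked; distance undefined")
    d = x.size
    sq = float(np.sum((x[observed] - y[observed]) ** 2))
    return float(np.sqrt(d / m * sq))


def _sq_distances(X: np.ndarray, observed: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Squared masked distances, samples x centroids (vectorized)."""
    D = X.shape[1]
    m = observed.sum(axis=1)  # per-sample observed count, > 0 by precondition
    X0 = np.where(observed, X, 0.0)
    # sum over observed coords of (x - c)^2, expanded to avoid NaN propagation
    x_sq = (X0**2).sum(axis=1)[:, None]
    cross = X0 @ centroids.T
    c_sq = observed.astype(float) @ (centroids.T**2)
    return (D / m)[:, None] * (x_sq - 2.0 * cross + c_sq)


def _lloyd(X: np.ndarray, observed: np.ndarray, k: int,
           rng: np.random.Generator, max_iter: int, tol: float,
           ss_history: list | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    n, D = X.shape
    sample_w = D / observed.sum(axis=1)  # the D/m rescaling weight per sample
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    # seed centroids may contain NaN at masked coords; fall back to column means
    col_means = np.nanmean(np.where(observed, X, np.nan), axis=0)
    col_means = np.nan_to_num(col_means, nan=0.0)
    centroids = np.where(np.isnan(centroids), col_means, centroids)

    labels: np.ndarray | None = None
    prev_ss = np.inf
    for _ in range(max_iter):
        sq = _sq_distances(X, observed, centroids)
        new_labels = sq.argmin(axis=1)
        # re-seed any empty cluster from the farthest point, then re-assign
        for j in range(k):
            if not np.any(new_labels == j):
                farthest = int(sq[np.arange(n), new_labels].argmax())
                centroids[j] = np.where(observed[farthest], X[farthest], col_means)
                sq = _sq_distances(X, observed, centroids)
                new_labels = sq.argmin(axis=1)
        ss = float(sq[np.arange(n), new_labels].sum())
        if ss_history is not None:
            ss_history.append(ss)
        if (labels is not None and np.array_equal(new_labels, labels)) or (
            prev_ss - ss <= tol * max(abs(prev_ss), 1.0) and np.isfinite(prev_ss)
        ):
            labels = new_labels
            break
        labels = new_labels
        prev_ss = ss
        # centroid update: per-coordinate mean over observed contributions,
        # weighted by D/m so the masked-distance objective is non-increasing
        for j in range(k):
            members = labels == j
            obs_j = observed[members]
            w_j = sample_w[members][:, None]
            counts = (w_j * obs_j).sum(axis=0)
            sums = (w_j * np.where(obs_j, X[members], 0.0)).sum(axis=0)
            with np.errstate(invalid="ignore"):
                upd = sums / counts
            centroids[j] = np.where(counts > 0, upd, centroids[j])
    sq = _sq_distances(X, observed, centroids)
    labels = sq.argmin(axis=1)
    ss = float(sq[np.arange(n), labels].sum())
    return centroids, labels, ss


def kmeans_profiles(Z: pd.DataFrame, config: ClusterConfig = ClusterConfig()) -> ClusterModel:
    """Cluster Z-score profiles; best of ``n_runs`` restarts by within-SS.

    Samples with no observed value cannot be placed and raise an error;
    callers should restrict to the non-zero (clustering) set first.
    """
    X = Z.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    if np.any(observed.sum(axis=1) == 0):
        bad = list(Z.index[observed.sum(axis=1) == 0])
        raise ClusterError(f"samples with all values masked: {bad[:5]}")
    n = X.shape[0]
    if n < config.k:
        raise ClusterError(f"need at least k={config.k} samples, got {n}")

    best: tuple[float, int, np.ndarray, np.ndarray] | None = None
    run_seeds = [config.seed + r for r in range(config.n_runs)]
    for r, s in enumerate(run_seeds):
        rng = np.random.default_rng(s)
        centroids, labels, ss = _lloyd(
            X, observed, config.k, rng, config.max_iter, config.tol
        )
        if best is None or ss < best[0]:  # ties keep the lowest run index
            best = (ss, r, centroids, labels)
    ss, _, centroids, labels = best
    assignments = pd.Series(
        [f"Z{j}" for j in labels], index=Z.index, name="cluster"
    )
    return ClusterModel(
        centroids=centroids,
        assignments=assignments,
        within_ss=ss,
        run_seeds=run_seeds,
        region_names=list(Z.columns),
    )


def within_ss(model: ClusterModel, Z: pd.DataFrame) -> float:
    """Recompute the within-cluster sum of squared masked distances."""
    X = Z.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    sq = _sq_distances(X, observed, model.centroids)
    return float(sq[np.arange(X.shape[0]), model.labels()].sum())


def cluster_summary(model: ClusterModel, Z: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster, per-region Z distribution: median, quartiles, masked
    fraction, and the high/low call (median Z > 0 means "high")."""
    rows = []
    labels = model.labels()
    X = Z.to_numpy(dtype=float)
    for j in range(model.centroids.shape[0]):
        members = X[labels == j]
        for col, name in enumerate(Z.columns):
            vals = members[:, col]
            observed = vals[~np.isnan(vals)]
            median = float(np.median(observed)) if observed.size else np.nan
            rows.append(
                {
                    "cluster": f"Z{j}",
                    "region": name,
                    "n": int(members.shape[0]),
                    "median": median,
                    "q1": float(np.percentile(observed, 25)) if observed.size else np.nan,
                    "q3": float(np.percentile(observed, 75)) if observed.size else np.nan,
                    "frac_masked": float(np.isnan(vals).mean()) if vals.size else np.nan,
                    "high": bool(observed.size and median > 0),
                }
            )
    return pd.DataFrame(rows)
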