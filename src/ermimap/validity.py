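"""Spatial-partition validity analysis.

Homes are partitioned on their standardized 36-species concentration
profiles under several distance metrics (Euclidean, Manhattan, correlation),
partitioning algorithms (k-means, k-medoids/PAM) and partition counts
(k = 2..10), and each partitioning is scored by the average silhouette
width

    s(i) = (b_i - a_i) / max(a_i, b_i)

where ``a_i`` is home i's mean distance to its own partition and ``b_i``
the smallest mean distance to another partition.  Averages near 0 across
the whole grid indicate the absence of compact, well-separated home
communities; a genuinely clustered dataset produces averages well above
that at the right k.

k-means is Lloyd's algorithm with seeded restarts; k-medoids is PAM
(greedy BUILD then SWAP, the swap scan vectorized over candidates) and
accepts an arbitrary precomputed distance matrix.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, InputError, InsufficientDataError

__all__ = [
    "standardize",
    "pairwise_distances",
    "kmeans",
    "kmedoids",
    "partition",
    "silhouette",
    "validity_scan",
    "METRICS",
    "ALGORITHMS",
]

METRICS = ("euclidean", "manhattan", "correlation")
ALGORITHMS = ("kmeans", "kmedoids")


def standardize(logm) -> pd.DataFrame:
    """Column z-scores with the population (n-denominator) standard
    deviation.  Constant columns map to all zeros with a warning."""
    df = pd.DataFrame(logm).astype(float)
    if len(df) < 2:
        raise InsufficientDataError("standardization needs >= 2 homes")
    vals = df.to_numpy()
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)  # population sd
    constant = sd == 0
    if constant.any():
        names = [c for c, flag in zip(df.columns, constant) if flag]
        warnings.warn(
            f"constant columns standardized to zero: {names}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[:, constant] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def pairwise_distances(z, metric: str = "euclidean") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix under a supported metric.

    ``correlation`` is 1 - Pearson correlation between profiles (distance 0
    for perfectly correlated profiles).
    """
    if metric not in METRICS:
        raise ConfigError(f"unknown metric {metric!r}; supported: {METRICS}")
    z = np.asarray(pd.DataFrame(z), dtype=float)
    scipy_metric = {"euclidean": "euclidean", "manhattan": "cityblock",
                    "correlation": "correlation"}[metric]
    D = squareform(pdist(z, metric=scipy_metric))
    # guard against tiny negative round-off from the correlation metric
    np.maximum(D, 0.0, out=D)
    return D


# ---------------------------------------------------------------------------
# k-means (Lloyd, seeded restarts)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers with D^2 sampling."""
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[c] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((x - centers[c]) ** 2).sum(axis=1))
    return centers


def _lloyd_once(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300):
    n = len(x)
    centers = _kmeanspp_init(x, k, rng)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # re-seed empty clusters on the point farthest from its center
        for c in range(k):
            if not (new_labels == c).any():
                far = d2[np.arange(n), new_labels].argmax()
                new_labels[far] = c
                d2[far, :] = np.inf
                d2[far, c] = 0.0
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
    inertia = ((x - centers[labels]) ** 2).sum()
    return labels, float(inertia)


def kmeans(x, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Lloyd's k-means on raw coordinates; best of ``n_restarts`` seeded
    starts by within-partition squared deviation.  Deterministic given
    ``seed``; every partition non-empty."""
    x = np.asarray(pd.DataFrame(x), dtype=float)
    n = len(x)
    if not 2 <= k <= n:
        raise ConfigError(f"k must satisfy 2 <= k <= n; got k={k}, n={n}")
    if k == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        labels, inertia = _lloyd_once(x, k, rng)
        if inertia < best_inertia - 1e-12:
            best_labels, best_inertia = labels, inertia
    return best_labels


# ---------------------------------------------------------------------------
# k-medoids (PAM)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = len(D)
    medoids = [int(D.sum(axis=1).argmin())]
    d1 = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d1[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        best = int(gain.argmax())
        medoids.append(best)
        np.minimum(d1, D[:, best], out=d1)
    return medoids


def _nearest_two(D: np.ndarray, medoids: list[int]):
    sub = D[:, medoids]
    order = np.argsort(sub, axis=1, kind="stable")
    n1 = order[:, 0]
    d1 = sub[np.arange(len(D)), n1]
    d2 = sub[np.arange(len(D)), order[:, 1]]
    return n1, d1, d2


def kmedoids(
    D: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    return_medoids: bool = False,
):
    """PAM k-medoids on a precomputed distance matrix.

    BUILD greedily accumulates medoids; SWAP repeatedly applies the single
    best (medoid, candidate) exchange until none lowers the total distance.
    The deterministic BUILD start makes ``seed`` only relevant for
    tie-shuffling of equal-cost swaps; it is accepted for interface
    symmetry with k-means.
    """
    D = np.asarray(D, dtype=float)
    n = len(D)
    if D.shape != (n, n):
        raise InputError("distance matrix must be square")
    if not 2 <= k <= n:
        raise ConfigError(f"k must satisfy 2 <= k <= n; got k={k}, n={n}")
    if k == n:
        labels = np.arange(n)
        return (labels, list(range(n))) if return_medoids else labels
    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        n1, d1, d2 = _nearest_two(D, medoids)
        # delta[m, h]: change in total distance if medoid m is replaced by h.
        g1 = np.minimum(D, d1[:, None]) - d1[:, None]      # nearest medoid kept
        g2 = np.minimum(D, d2[:, None]) - d1[:, None]      # nearest medoid removed
        base = g1.sum(axis=0)
        onehot = np.zeros((k, n))
        onehot[n1, np.arange(n)] = 1.0
        delta = base[None, :] + onehot @ (g2 - g1)
        delta[:, medoids] = np.inf
        m_idx, h = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[m_idx, h] >= -1e-10:
            break
        medoids[m_idx] = int(h)
    n1, _, _ = _nearest_two(D, medoids)
    return (n1, medoids) if return_medoids else n1


def partition(data, k: int, algorithm: str = "kmeans", seed: int = 0) -> np.ndarray:
    """Partition homes with the named algorithm.

    ``data`` is a standardized matrix for k-means or a distance matrix for
    k-medoids.  Labels are 0-based partition ids; every partition non-empty;
    deterministic given ``seed``.
    """
    if algorithm == "kmeans":
        return kmeans(data, k, seed=seed)
    if algorithm == "kmedoids":
        return kmedoids(np.asarray(data, float), k, seed=seed)
    raise ConfigError(f"unknown algorithm {algorithm!r}; supported: {ALGORITHMS}")


def silhouette(labels, D: np.ndarray):
    """Per-home silhouette widths and their average for a partitioning.

    Uses the precomputed distance matrix; singleton partitions score 0 by
    convention.  Requires at least 2 non-empty partitions.
    """
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    n = len(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise InputError("silhouette is undefined for a single partition")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = D @ onehot  # n x k: total distance from i to each partition
    own_count = counts[inv]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), inv] / np.maximum(own_count - 1, 1)
        mean_other = sums / counts[None, :]
        mean_other[np.arange(n), inv] = np.inf
        b = mean_other.min(axis=1)
        s = (b - a) / np.maximum(a, b)
    s[own_count == 1] = 0.0
    s[~np.isfinite(s)] = 0.0
    return s, float(s.mean())


def validity_scan(
    z,
    ks=range(2, 11),
    metrics=METRICS,
    algorithms=ALGORITHMS,
    seed: int = 0,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Silhouette validity over a (k, metric, algorithm) grid.

    Returns one row per combination with the average silhouette width and a
    ``flagged`` column marking configurations whose average exceeds
    ``threshold`` (evidence of a valid partitioning).  k-means runs on the
    standardized matrix and is only scored under the Euclidean metric it
    optimizes; k-medoids runs on each metric's distance matrix.
    """
    ks = list(ks)
    metrics = list(metrics)
    algorithms = list(algorithms)
    if not ks or not metrics or not algorithms:
        raise ConfigError("ks, metrics and algorithms must be non-empty")
    z = pd.DataFrame(z)
    dmats = {m: pairwise_distances(z, m) for m in metrics}
    rows = []
    for metric, algo, k in product(metrics, algorithms, ks):
        if algo == "kmeans" and metric != "euclidean":
            continue
        data = z if algo == "kmeans" else dmats[metric]
        labels = partition(data, k, algorithm=algo, seed=seed)
        _, avg = silhouette(labels, dmats[metric])
        rows.append(
            {
                "metric": metric,
                "algorithm": algo,
                "k": k,
                "avg_silhouette": avg,
                "flagged": avg > threshold,
            }
        )
    return pd.DataFrame(rows)
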