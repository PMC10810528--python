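"""Post-hoc interpretation: clustering the local models and summarising
the embedding.

With thousands of items there are thousands of local models; k-means on
the rows of the coefficient matrix condenses them into a handful of
centroid models whose bar plots a domain expert can read.  The binned
target map colours the embedding plane by median target per grid cell,
revealing whether low/high-target regions emerge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .data import Dataset, LINEAR

__all__ = [
    "ClusterReport",
    "cluster_local_models",
    "coefficients_to_raw",
    "binned_target_map",
    "cluster_target_summary",
    "silhouette_scores",
]


@dataclass
class ClusterReport:
    k: int
    labels: np.ndarray
    centroids: np.ndarray  # standardized-unit mean coefficients per cluster
    sizes: np.ndarray
    centroids_raw: np.ndarray | None = None
    per_cluster_target_median: np.ndarray | None = None
    overall_target_median: float | None = None
    extras: dict = field(default_factory=dict)


def cluster_local_models(B: np.ndarray, k: int, seed: int = 0,
                         dataset: Dataset | None = None,
                         y_raw: np.ndarray | None = None) -> ClusterReport:
    """Seeded k-means over local-model coefficient rows.

    Centroids are the mean coefficients of each cluster; when a dataset
    is supplied they are also reported on the raw (pre-standardization)
    coefficient scale, and when raw targets are supplied the per-cluster
    target medians are included.
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of items")
    distinct = np.unique(B, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct coefficient rows")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(B)
    labels = km.labels_
    centroids = np.vstack([B[labels == c].mean(axis=0) for c in range(k)])
    sizes = np.bincount(labels, minlength=k)
    report = ClusterReport(k=k, labels=labels, centroids=centroids, sizes=sizes)
    if dataset is not None and dataset.family == LINEAR and dataset.o == 1:
        report.centroids_raw = coefficients_to_raw(centroids, dataset)
    if y_raw is not None:
        y_raw = np.asarray(y_raw, dtype=float).ravel()
        report.per_cluster_target_median = np.array(
            [float(np.median(y_raw[labels == c])) for c in range(k)]
        )
        report.overall_target_median = float(np.median(y_raw))
    return report


def coefficients_to_raw(B: np.ndarray, dataset: Dataset) -> np.ndarray:
    """Re-express standardized-unit linear coefficients in raw units.

    Inverts ``y_s = a_s . x_s + b_s`` given the stored standardization:
    raw slope ``a = a_s * sy / sx`` and raw intercept
    ``b = my + sy * (b_s - sum_f a_sf * mxf / sxf)``.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    a_s, b_s = B[:, :-1], B[:, -1]
    sy = float(dataset.y_scale[0]) if dataset.y_scale is not None else 1.0
    my = float(dataset.y_mean[0]) if dataset.y_mean is not None else 0.0
    a = a_s * sy / dataset.x_scale[None, :]
    b = my + sy * b_s - a @ dataset.x_mean
    return np.column_stack([a, b])


def binned_target_map(Z: np.ndarray, y: np.ndarray, grid_size: int = 20,
                      r: float = 3.5) -> pd.DataFrame:
    """Square-grid binning of the embedding plane with median targets.

    The grid spans [-r, r]^2; individual points may lie outside the mean
    radius and are clipped into the edge bins.  Empty bins are omitted.
    Columns: bin_center_x, bin_center_y, median_target, count.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    edges = np.linspace(-r, r, grid_size + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    ix = np.clip(np.digitize(Z[:, 0], edges) - 1, 0, grid_size - 1)
    iy = np.clip(np.digitize(Z[:, 1], edges) - 1, 0, grid_size - 1)
    rows = []
    flat = ix * grid_size + iy
    for cell in np.unique(flat):
        mask = flat == cell
        rows.append({
            "bin_center_x": centers[cell // grid_size],
            "bin_center_y": centers[cell % grid_size],
            "median_target": float(np.median(y[mask])),
            "count": int(mask.sum()),
        })
    return pd.DataFrame(rows)


def cluster_target_summary(labels: np.ndarray, y_raw: np.ndarray) -> pd.DataFrame:
    """Median raw-scale target per cluster plus the overall median."""
    labels = np.asarray(labels)
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    if labels.shape[0] != y_raw.shape[0]:
        raise ValueError("labels and targets differ in length")
    rows = [
        {"cluster": int(c), "median_target": float(np.median(y_raw[labels == c])),
         "count": int((labels == c).sum())}
        for c in np.unique(labels)
    ]
    rows.append({"cluster": -1, "median_target": float(np.median(y_raw)),
                 "count": int(y_raw.shape[0])})
    return pd.DataFrame(rows)


def silhouette_scores(B: np.ndarray, k_range=range(2, 9), seed: int = 0) -> dict:
    """Silhouette score of k-means on B for each k — a helper for choosing
    k, never applied automatically."""
    B = np.asarray(B, dtype=float)
    out = {}
    for k in k_range:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(B)
        out[int(k)] = float(silhouette_score(B, km.labels_))
    return out
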