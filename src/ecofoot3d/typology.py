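"""Sustainability typology from standardized footprint size and depth.

City-years are placed on a shared standardized (z_size, z_depth) plane,
grouped by agglomerative hierarchical clustering (Ward linkage, Euclidean
distance — the usual reading of "systematic clustering"), and the four
clusters are mapped to ordered sustainability types:

* Type 1 — high size, high depth: heavy flow occupation plus heavy stock
  depletion; least sustainable.
* Type 2 — low size, moderate depth: stock is consumed faster than flow.
* Type 3 — moderate size, moderate depth: flow use outpaces stock use.
* Type 4 — moderate size, low depth: flow-dominated; most sustainable.

The cluster -> type rule is centroid-based: among clusters whose mean z_size
lies above the panel median, the one with the highest mean z_depth becomes
Type 1; the remaining clusters are ranked by decreasing mean z_depth into
Types 2, 3 and 4 (ties broken by descending mean z_size).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ValidationError
from .threedef import ThreeDEFResult


class SustainabilityType(enum.IntEnum):
    """Four ordered classes; larger value = more ecologically sustainable."""

    HIGH_SIZE_HIGH_DEPTH = 1
    LOW_SIZE_MODERATE_DEPTH = 2
    MODERATE_SIZE_MODERATE_DEPTH = 3
    MODERATE_SIZE_LOW_DEPTH = 4


@dataclass(frozen=True)
class TypedObservation:
    city: str
    year: int
    z_size: float
    z_depth: float
    cluster_id: int
    type: SustainabilityType

    def as_row(self) -> dict:
        return {
            "city": self.city,
            "year": self.year,
            "z_size": self.z_size,
            "z_depth": self.z_depth,
            "cluster_id": self.cluster_id,
            "type": int(self.type),
        }


def standardize_panel(values: Sequence[float]) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("standardization needs at least two values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValidationError("standardization undefined for zero variance")
    return (arr - arr.mean()) / sd


def cluster_observations(z_pairs: np.ndarray, k: int, method: str = "ward") -> np.ndarray:
    """Hierarchical clustering of (z_size, z_depth) pairs cut at k clusters.

    Returns integer ids 1..k; deterministic for a given input order.
    """
    pts = np.asarray(z_pairs, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("z_pairs must be an (n, 2) array")
    n = pts.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return np.ones(n, dtype=int)
    tree = linkage(pts, method=method, metric="euclidean")
    return fcluster(tree, t=k, criterion="maxclust").astype(int)


def assign_types(clusters: np.ndarray, z_pairs: np.ndarray) -> np.ndarray:
    """Map k = 4 cluster ids to SustainabilityType labels per observation."""
    clusters = np.asarray(clusters)
    pts = np.asarray(z_pairs, dtype=float)
    ids = np.unique(clusters)
    if len(ids) != 4:
        raise ValidationError(f"type assignment requires exactly 4 clusters, got {len(ids)}")

    centroids = {c: pts[clusters == c].mean(axis=0) for c in ids}
    size_median = float(np.median(pts[:, 0]))

    # Type 1: deepest centroid among the high-size clusters
    high = [c for c in ids if centroids[c][0] >= size_median]
    pool = high if high else list(ids)
    type1 = max(pool, key=lambda c: (centroids[c][1], centroids[c][0]))

    remaining = [c for c in ids if c != type1]
    remaining.sort(key=lambda c: (-centroids[c][1], -centroids[c][0]))

    mapping = {type1: SustainabilityType(1)}
    for label, c in zip((2, 3, 4), remaining):
        mapping[c] = SustainabilityType(label)

    return np.array([mapping[c] for c in clusters], dtype=object)


def classify_panel(
    results: Sequence[ThreeDEFResult], k: int = 4, method: str = "ward"
) -> list[TypedObservation]:
    """Standardize, cluster and type a panel of 3D footprint results."""
    if k != 4:
        raise ValidationError("the four-type scheme requires k = 4")
    if not results:
        raise ValidationError("cannot classify an empty panel")
    z_size = standardize_panel([r.ef_size for r in results])
    z_depth = standardize_panel([r.ef_depth for r in results])
    pts = np.column_stack([z_size, z_depth])
    clusters = cluster_observations(pts, k=k, method=method)
    types = assign_types(clusters, pts)
    return [
        TypedObservation(
            city=r.city,
            year=r.year,
            z_size=float(zs),
            z_depth=float(zd),
            cluster_id=int(c),
            type=t,
        )
        for r, zs, zd, c, t in zip(results, z_size, z_depth, clusters, types)
    ]
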