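"""Hierarchical double k-means segmentation with PBM cluster-validity selection.

Tissue spectra pooled across a cohort are clustered twice: a first k-means
over a random subsample splits the spectra into coarse populations, then a
second k-means inside each first-level cluster resolves sub-populations. At
both levels the number of clusters k ∈ [2, 5] is chosen automatically by
maximising the Pakhira-Bandyopadhyay-Maulik (PBM) index

    PBM(K) = ((1/K) · (E₁ / E_K) · D_K)²

where E₁ is the summed Euclidean distance of all points to the global
centroid, E_K the summed distance of points to their own cluster centroid
(compactness), and D_K the maximum pairwise centroid distance (separation).
Larger is better. K = 1 scores 0 (D₁ = 0); a partition with zero
within-cluster scatter scores +inf.

All tissue pixels of all images are then assigned by nearest centroid at both
levels, giving a per-pixel (level-1, level-2) label that renders as a
false-color segmentation map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core_io import HyperspectralImage, ValidationError

__all__ = [
    "pbm_index",
    "auto_kmeans",
    "double_segmentation",
    "render_false_color",
    "ClusterModel",
    "assign_nearest",
]

_LOG = logging.getLogger("chemimage")


def pbm_index(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """PBM crisp cluster-validity index; higher means a better partition.

    Euclidean distances throughout. Returns 0 for K = 1 and +inf when every
    point sits exactly on its centroid (perfect compactness).
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=np.float64))
    K = centroids.shape[0]
    if K < 1:
        raise ValidationError("pbm_index: need at least one cluster")
    if labels.shape[0] != points.shape[0]:
        raise ValidationError("pbm_index: labels and points disagree in length")
    if labels.min() < 0 or labels.max() >= K:
        raise ValidationError("pbm_index: labels inconsistent with centroids")
    if K == 1:
        return 0.0
    global_centroid = points.mean(axis=0)
    e1 = float(np.linalg.norm(points - global_centroid, axis=1).sum())
    ek = float(np.linalg.norm(points - centroids[labels], axis=1).sum())
    diffs = centroids[:, None, :] - centroids[None, :, :]
    dk = float(np.linalg.norm(diffs, axis=-1).max())
    if ek == 0.0:
        return float("inf")
    return ((e1 / ek) * dk / K) ** 2


def _fit_kmeans(points: np.ndarray, k: int, seed: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-6,
                max_iter=300, random_state=seed)
    km.fit(points)
    return km


def auto_kmeans(
    points: np.ndarray, k_min: int = 2, k_max: int = 5, seed: int = 0
) -> tuple[int, np.ndarray, np.ndarray, dict[int, float]]:
    """Seeded k-means for each k in [k_min, k_max]; keep the PBM-maximal k.

    Returns (k*, centroids, labels, {k: PBM}). If there are fewer points than
    k_max, k_max shrinks with a warning; fewer than k_min points is an error.
    Ties in PBM break toward the smaller k.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < k_min:
        raise ValidationError(f"auto_kmeans: {n} points < k_min={k_min}")
    if n < k_max:
        warnings.warn(f"auto_kmeans: shrinking k_max from {k_max} to {n}")
        k_max = n
    scores: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(k_min, k_max + 1):
        km = _fit_kmeans(points, k, seed)
        fits[k] = km
        scores[k] = pbm_index(points, km.labels_, km.cluster_centers_)
    best_k = max(sorted(scores), key=lambda k: scores[k])
    best = fits[best_k]
    _assert_consistent(points, best.labels_, best.cluster_centers_, best.inertia_)
    return best_k, best.cluster_centers_.copy(), best.labels_.copy(), scores


def _assert_consistent(points, labels, centroids, inertia) -> None:
    # nearest-centroid consistency + inertia equals recomputed WCSS
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(-1) if points.shape[0] * centroids.shape[0] * points.shape[1] < 5e7 else None
    if d2 is not None:
        own = d2[np.arange(points.shape[0]), labels]
        assert np.all(own <= d2.min(axis=1) + 1e-7 * (1 + own)), "assignment not nearest-centroid"
        assert abs(own.sum() - inertia) <= 1e-6 * (1 + inertia), "inertia mismatch"


def assign_nearest(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; ties break toward the lowest cluster id."""
    points = np.asarray(points, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; argmin returns the first minimum
    d2 = (
        (points**2).sum(axis=1, keepdims=True)
        - 2.0 * points @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


@dataclass
class ClusterModel:
    """Fitted two-level segmentation: centroids, PBM scores and assignments."""

    level1_centroids: np.ndarray  # (k1, channels)
    level2_centroids: dict[int, np.ndarray]  # per level-1 id: (k2_i, channels)
    pbm_level1: dict[int, float]
    pbm_level2: dict[int, dict[int, float]]
    assignments: dict[str, np.ndarray]  # image_id -> (rows, cols, 2) int, -1 off tissue

    @property
    def k1(self) -> int:
        return self.level1_centroids.shape[0]

    def k2(self, level1_id: int) -> int:
        return self.level2_centroids[level1_id].shape[0]

    @property
    def n_composite(self) -> int:
        """Total number of (level-1, level-2) composite clusters."""
        return sum(self.k2(i) for i in range(self.k1))

    def composite_offset(self) -> dict[int, int]:
        off, acc = {}, 0
        for i in range(self.k1):
            off[i] = acc
            acc += self.k2(i)
        return off

    def assign_spectra(self, spectra: np.ndarray) -> np.ndarray:
        """(n, 2) level-1/level-2 assignment of arbitrary spectra."""
        l1 = assign_nearest(spectra, self.level1_centroids)
        l2 = np.zeros_like(l1)
        for c in range(self.k1):
            sel = l1 == c
            if sel.any():
                l2[sel] = assign_nearest(spectra[sel], self.level2_centroids[c])
        return np.stack([l1, l2], axis=1)


def double_segmentation(
    images: list[HyperspectralImage],
    subsample: int = 20_000,
    k_min: int = 2,
    k_max: int = 5,
    seed: int = 0,
) -> ClusterModel:
    """Two-level auto-k k-means over pooled tissue spectra of a cohort.

    Level 1 fits on a random subsample of the pooled tissue spectra (all of
    them if fewer than ``subsample``); level 2 re-clusters each level-1
    cluster's subsample members. A level-1 cluster with fewer than
    ``k_min * 10`` members keeps a single sub-cluster (its own centroid) with
    a warning. Finally every tissue pixel of every image is assigned by
    nearest centroid at both levels.
    """
    if subsample < 50 * k_max:
        raise ValidationError(f"subsample must be >= {50 * k_max}")
    pooled = [img.tissue_spectra() for img in images]
    all_spectra = np.concatenate([p for p in pooled if p.size], axis=0)
    if all_spectra.shape[0] < k_max:
        raise ValidationError("not enough tissue spectra to cluster")
    rng = np.random.default_rng(seed)
    if all_spectra.shape[0] > subsample:
        idx = rng.choice(all_spectra.shape[0], size=subsample, replace=False)
        sample = all_spectra[idx]
    else:
        sample = all_spectra

    k1, c1, l1, pbm1 = auto_kmeans(sample, k_min, k_max, seed=seed)
    _LOG.info("segmentation level 1: k*=%d PBM=%s", k1,
              {k: round(v, 3) for k, v in pbm1.items()})

    c2: dict[int, np.ndarray] = {}
    pbm2: dict[int, dict[int, float]] = {}
    for c in range(k1):
        members = sample[l1 == c]
        if members.shape[0] < k_min * 10:
            warnings.warn(
                f"level-1 cluster {c} has only {members.shape[0]} members; "
                "skipping level-2 split"
            )
            c2[c] = members.mean(axis=0, keepdims=True) if members.size else c1[c][None, :]
            pbm2[c] = {1: 0.0}
            continue
        k2, cc, _, scores = auto_kmeans(members, k_min, min(k_max, members.shape[0]),
                                        seed=seed + 1 + c)
        c2[c] = cc
        pbm2[c] = scores

    model = ClusterModel(
        level1_centroids=c1, level2_centroids=c2,
        pbm_level1=pbm1, pbm_level2=pbm2, assignments={},
    )
    for img in images:
        amap = np.full(img.cube.shape[:2] + (2,), -1, dtype=np.int64)
        spectra = img.tissue_spectra()
        if spectra.size:
            amap[img.mask] = model.assign_spectra(spectra)
        model.assignments[img.image_id] = amap
    return model


def render_false_color(img: HyperspectralImage, model: ClusterModel) -> np.ndarray:
    """Composite (level-1, level-2) labels as a stable palette-index image.

    Index 0 is substrate; tissue pixels get 1 + offset(level1) + level2, so the
    palette has 1 + Σ k₂ entries.
    """
    if img.image_id not in model.assignments:
        raise ValidationError(f"model has no assignment for image {img.image_id!r}")
    amap = model.assignments[img.image_id]
    off = model.composite_offset()
    out = np.zeros(amap.shape[:2], dtype=np.int64)
    tissue = amap[:, :, 0] >= 0
    l1 = amap[:, :, 0][tissue]
    l2 = amap[:, :, 1][tissue]
    out[tissue] = 1 + np.array([off[int(a)] for a in l1]) + l2
    return out
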