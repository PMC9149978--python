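"""Fuzzy C-means segmentation of a CT slice.

Intensity-only FCM: minimizes sum_i sum_k u_ik^m (x_i - c_k)^2 subject to
sum_k u_ik = 1, by alternating the closed-form membership and centroid
updates. Deterministic given the seed (centroids start at intensity
quantiles with a small seeded jitter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateFitError, DomainError, EmptyMaskError

__all__ = ["FuzzyPartition", "fcm_segment", "extract_region_mask"]


@dataclass
class FuzzyPartition:
    """Result of an FCM run.

    memberships has shape (n_clusters, *image.shape) with per-pixel weights
    summing to 1 over clusters; labels is the hard assignment by maximum
    membership; objective_trace records the objective once per iteration
    (non-increasing).
    """

    memberships: np.ndarray
    centroids: np.ndarray
    labels: np.ndarray
    fuzziness_m: float
    objective: float
    objective_trace: np.ndarray
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return self.centroids.size


def _memberships(x: np.ndarray, c: np.ndarray, m: float) -> np.ndarray:
    """Closed-form FCM membership update; rows with a zero distance get
    crisp membership on the matching cluster(s)."""
    d2 = (x[:, None] - c[None, :]) ** 2
    zero = d2 == 0.0
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    u = np.empty_like(d2)
    rows_zero = zero.any(axis=1)
    ok = ~rows_zero
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if rows_zero.any():
        z = zero[rows_zero]
        u[rows_zero] = z / z.sum(axis=1, keepdims=True)
    return u


def fcm_segment(
    image,
    n_clusters: int,
    *,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    init_centroids=None,
) -> FuzzyPartition:
    """Cluster image intensities with fuzzy C-means.

    Parameters
    ----------
    image : array
        1D or 2D finite intensity grid (HU for CT).
    n_clusters : int
        Number of clusters (>= 2); must not exceed the number of distinct
        intensities.
    m : float
        Fuzziness exponent (> 1); 2 is the conventional choice.
    tol : float
        Convergence threshold on the maximum centroid shift.
    max_iter, seed : int
        Iteration budget and RNG seed for the quantile-jitter initialization.
    init_centroids : array, optional
        Explicit initial centroids (overrides the seeded initialization);
        useful for reproducing a run or testing label permutation.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DomainError("image must be finite")
    if n_clusters < 2:
        raise DomainError("n_clusters must be >= 2")
    if m <= 1:
        raise DomainError("fuzziness m must be > 1")
    x = img.ravel()
    if np.unique(x).size < n_clusters:
        raise DegenerateFitError(
            f"{n_clusters} clusters requested but only {np.unique(x).size} distinct intensities"
        )

    if init_centroids is not None:
        c = np.asarray(init_centroids, dtype=float).copy()
        if c.size != n_clusters:
            raise DomainError("init_centroids length must equal n_clusters")
    else:
        rng = np.random.default_rng(seed)
        qs = (np.arange(n_clusters) + 0.5) / n_clusters
        c = np.quantile(x, qs)
        c = c + rng.normal(0.0, 0.01 * np.ptp(x) / n_clusters, size=n_clusters)

    trace = []
    u = _memberships(x, c, m)
    for it in range(1, max_iter + 1):
        um = u**m
        d2 = (x[:, None] - c[None, :]) ** 2
        trace.append(float((um * d2).sum()))
        c_new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.max(np.abs(c_new - c)))
        c = c_new
        u = _memberships(x, c, m)
        if shift < tol:
            break
    labels = np.argmax(u, axis=1).reshape(img.shape)
    return FuzzyPartition(
        memberships=u.T.reshape((n_clusters,) + img.shape),
        centroids=c,
        labels=labels,
        fuzziness_m=m,
        objective=trace[-1],
        objective_trace=np.asarray(trace),
        n_iter=it,
    )


def extract_region_mask(
    partition: FuzzyPartition, rule, *, largest_component: bool = False
) -> np.ndarray:
    """Boolean mask of the pixels hard-assigned to one cluster.

    ``rule`` selects the cluster: an integer index, ``"brightest"`` /
    ``"darkest"`` (by centroid), ``("rank", i)`` for the i-th cluster in
    ascending centroid order, or ``("seed", (row, col))`` for the cluster of
    a seed pixel. With ``largest_component=True`` only the largest
    4-connected component is kept (removes speckle).
    """
    cents = partition.centroids
    if isinstance(rule, (int, np.integer)):
        idx = int(rule)
    elif rule == "brightest":
        idx = int(np.argmax(cents))
    elif rule == "darkest":
        idx = int(np.argmin(cents))
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "rank":
        order = np.argsort(cents)
        idx = int(order[int(rule[1])])
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "seed":
        r, c = rule[1]
        idx = int(partition.labels[r, c])
    else:
        raise DomainError(f"unrecognized cluster-selection rule {rule!r}")
    if not 0 <= idx < partition.n_clusters:
        raise DomainError(f"cluster index {idx} out of range")

    mask = partition.labels == idx
    if not mask.any():
        raise EmptyMaskError(f"cluster {idx} has no hard-assigned pixels")
    if largest_component:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
        lab, n = ndimage.label(mask, structure=structure)
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (int(np.argmax(sizes)) + 1)
    return mask
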