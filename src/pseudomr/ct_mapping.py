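"""Windowed CT-number features and the (mu, sigma) -> {T1, T2, rho} surfaces.

The CT-to-MR translation step: the raw CT number of a pixel maps
one-to-many onto tissue relaxometry (different tissues overlap in HU), so
each pixel is instead characterized by the mean (mu) and sample standard
deviation (sigma) of the CT numbers in a small window around it — local
first- and second-order statistics that jointly identify the tissue. Three
scattered-data surfaces over the (mu, sigma) plane, one per intrinsic
parameter, are then learned from a slice whose relaxometry maps are known,
and can be applied to the features of any co-registered CT to regenerate
parameter maps.

Two interpolation modes: ``piecewise_linear`` (Delaunay triangulation of the
training (mu, sigma) points, linear within each triangle) and ``nearest``.
Queries outside the convex hull of the training points fall back to the
nearest training node by default, or can be marked invalid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import (
    DegenerateGeometryError,
    DomainError,
    EmptyMaskError,
    StructuralError,
)
from .signal_model import ParameterMaps

__all__ = ["CTFeatureMaps", "MappingModel", "ct_window_features", "build_mapping", "apply_mapping"]

PARAM_NAMES = ("t1", "t2", "rho")


@dataclass
class CTFeatureMaps:
    """Per-pixel windowed CT-number statistics.

    mu/sigma in HU; n counts the in-mask pixels in each window; mask marks
    pixels that survived the minimum-count rule. sigma uses the sample
    (n - 1) definition.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n: np.ndarray
    mask: np.ndarray
    window_size: int


def ct_window_features(ct, mask, *, window_size: int = 5, min_count: int = 6) -> CTFeatureMaps:
    """Windowed mean and sample standard deviation of CT numbers.

    For each in-mask pixel, statistics are computed over the in-mask pixels
    inside the centered ``window_size`` x ``window_size`` window (out-of-mask
    neighbors are excluded, so features near the region boundary are not
    contaminated by other tissue). Pixels with fewer than ``min_count``
    in-mask window pixels are dropped from the output mask.
    """
    ct = np.asarray(ct, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if ct.shape != mask.shape or ct.ndim != 2:
        raise StructuralError("ct and mask must be equal-shape 2D grids")
    if window_size < 3 or window_size % 2 == 0:
        raise DomainError("window_size must be an odd integer >= 3")
    if min_count < 2:
        raise DomainError("min_count must be >= 2 (sample sd needs n >= 2)")
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")

    # center the data before accumulating moments to keep the variance
    # subtraction well conditioned
    offset = float(ct[mask].mean())
    ctm = np.where(mask, ct - offset, 0.0)
    kernel = np.ones((window_size, window_size))
    n = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    s1 = ndimage.convolve(ctm, kernel, mode="constant", cval=0.0)
    s2 = ndimage.convolve(ctm**2, kernel, mode="constant", cval=0.0)
    n = np.rint(n)

    out_mask = mask & (n >= max(min_count, 2))
    if not out_mask.any():
        raise EmptyMaskError("all pixels dropped by the minimum-count rule")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = s1 / n + offset
        var = np.clip((s2 - s1**2 / n) / (n - 1), 0.0, None)
    mu[~out_mask] = np.nan
    sigma = np.sqrt(var)
    sigma[~out_mask] = np.nan
    return CTFeatureMaps(
        mu=mu, sigma=sigma, n=n.astype(int), mask=out_mask, window_size=window_size
    )


@dataclass
class MappingModel:
    """Three scattered-data interpolants (mu, sigma) -> T1, T2, rho.

    ``points`` is the (N, 2) array of aggregated training (mu, sigma) pairs
    (duplicates averaged); ``values`` maps each parameter name to its (N,)
    training values. ``mode`` is ``"piecewise_linear"`` or ``"nearest"``;
    ``fallback`` ("nearest" or "invalid") governs queries outside the
    interpolation domain. JSON-serializable via save()/load().
    """

    points: np.ndarray
    values: dict[str, np.ndarray]
    mode: str = "piecewise_linear"
    fallback: str = "nearest"
    provenance: str | None = None
    _interp: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise StructuralError("points must have shape (N, 2)")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k in PARAM_NAMES:
            if k not in self.values:
                raise StructuralError(f"missing training values for {k!r}")
            if self.values[k].shape != (self.points.shape[0],):
                raise StructuralError(f"training values for {k!r} do not match points")
        if self.mode not in ("piecewise_linear", "nearest"):
            raise DomainError(f"unknown mapping mode {self.mode!r}")
        if self.fallback not in ("nearest", "invalid"):
            raise DomainError(f"unknown fallback rule {self.fallback!r}")
        if self.mode == "piecewise_linear":
            try:
                tri = Delaunay(self.points)
            except (QhullError, ValueError) as exc:
                raise DegenerateGeometryError(
                    "training (mu, sigma) points are collinear or too few for "
                    "piecewise-linear interpolation; consider mode='nearest'"
                ) from exc
            self._interp = {
                k: LinearNDInterpolator(tri, self.values[k]) for k in PARAM_NAMES
            }
        else:
            self._interp = {
                k: NearestNDInterpolator(self.points, self.values[k]) for k in PARAM_NAMES
            }
        if self.fallback == "nearest" and self.mode == "piecewise_linear":
            self._interp_fallback = {
                k: NearestNDInterpolator(self.points, self.values[k]) for k in PARAM_NAMES
            }

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def evaluate(self, mu, sigma) -> dict[str, np.ndarray]:
        """Evaluate the three surfaces at query features.

        Returns a dict parameter name -> array of the broadcast query shape.
        Out-of-domain queries are filled from the nearest node
        (fallback="nearest") or left NaN (fallback="invalid").
        """
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        q = np.column_stack([mu.ravel(), sigma.ravel()])
        out: dict[str, np.ndarray] = {}
        for k in PARAM_NAMES:
            v = np.asarray(self._interp[k](q), dtype=float)
            if self.mode == "piecewise_linear" and self.fallback == "nearest":
                bad = ~np.isfinite(v)
                if bad.any():
                    v[bad] = self._interp_fallback[k](q[bad])
            out[k] = v.reshape(mu.shape)
        return out

    def to_dict(self) -> dict:
        return {
            "format": "pseudomr-mapping-model",
            "mode": self.mode,
            "fallback": self.fallback,
            "provenance": self.provenance,
            "points": self.points.tolist(),
            "values": {k: self.values[k].tolist() for k in PARAM_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappingModel":
        return cls(
            points=np.asarray(d["points"], dtype=float),
            values={k: np.asarray(v, dtype=float) for k, v in d["values"].items()},
            mode=d["mode"],
            fallback=d["fallback"],
            provenance=d.get("provenance"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "MappingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_mapping(
    features: CTFeatureMaps,
    maps: ParameterMaps,
    *,
    mode: str = "piecewise_linear",
    fallback: str = "nearest",
    provenance: str | None = None,
) -> MappingModel:
    """Learn the three (mu, sigma) -> parameter surfaces from a training slice.

    Training points come from the pixels shared by the feature mask and the
    map mask. Duplicate (mu, sigma) pairs are aggregated by averaging their
    parameter values before triangulation (interpolation needs single-valued
    nodes; identical local CT statistics with differing relaxometry is the
    one-to-many ambiguity this averages over).
    """
    if features.mask.shape != maps.mask.shape:
        raise StructuralError("feature and parameter maps must share a shape")
    shared = features.mask & maps.mask
    if not shared.any():
        raise EmptyMaskError("feature and parameter masks do not overlap")
    pts = np.column_stack([features.mu[shared], features.sigma[shared]])
    vals = {k: getattr(maps, k)[shared] for k in PARAM_NAMES}

    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if uniq.shape[0] != pts.shape[0]:
        counts = np.bincount(inverse)
        vals = {
            k: np.bincount(inverse, weights=vals[k]) / counts for k in PARAM_NAMES
        }
        pts = uniq
    if mode == "piecewise_linear" and pts.shape[0] < 3:
        raise DegenerateGeometryError("piecewise-linear mode needs >= 3 training points")
    return MappingModel(
        points=pts, values=vals, mode=mode, fallback=fallback, provenance=provenance
    )


def apply_mapping(model: MappingModel, features: CTFeatureMaps) -> ParameterMaps:
    """Regenerate parameter maps from CT features via the learned surfaces.

    Evaluates the three interpolants at every in-mask feature pixel; pixels
    the fallback rule marks invalid (NaN) are removed from the output mask.
    """
    m = features.mask
    if not m.any():
        raise EmptyMaskError("feature mask selects no pixels")
    est = model.evaluate(features.mu[m], features.sigma[m])
    shape = m.shape
    grids = {k: np.full(shape, np.nan) for k in PARAM_NAMES}
    valid = np.ones(int(m.sum()), dtype=bool)
    for k in PARAM_NAMES:
        valid &= np.isfinite(est[k])
    out_mask = np.zeros(shape, dtype=bool)
    rr, cc = np.nonzero(m)
    out_mask[rr[valid], cc[valid]] = True
    for k in PARAM_NAMES:
        grids[k][rr[valid], cc[valid]] = est[k][valid]
    if not out_mask.any():
        raise EmptyMaskError("no pixel survived the fallback rule")
    return ParameterMaps(t1=grids["t1"], t2=grids["t2"], rho=grids["rho"], mask=out_mask)
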