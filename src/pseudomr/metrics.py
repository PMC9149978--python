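"""Similarity between real and synthetic image regions: slope and PRD.

Two scalar measures on vectorized region intensities:

* the slope (and intercept) of the ordinary least-squares line fitting the
  synthetic values (dependent) against the real values (independent) — 1
  (and 0) for identical regions;
* the percentage root-mean-square difference,
  PRD = 100 * sqrt(sum_i (real_i - synthetic_i)^2 / sum_i real_i^2),
  0% for identical regions.

Because scanner gain is an unknown multiplicative constant, the synthetic
vector can optionally be rescaled by its least-squares factor
sum(real*syn)/sum(syn^2) before the PRD (scale normalization, off by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import DegenerateFitError, DomainError, EmptyMaskError, StructuralError

__all__ = ["SimilarityReport", "region_to_vector", "similarity_slope", "prd", "compare_images"]


@dataclass(frozen=True)
class SimilarityReport:
    slope: float
    intercept: float
    prd: float
    n: int
    normalization: str = "none"

    def to_dict(self) -> dict:
        return asdict(self)


def region_to_vector(image, mask) -> np.ndarray:
    """In-mask values of an image in deterministic row-major order."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise StructuralError("image and mask shapes differ")
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")
    return image[mask]


def similarity_slope(real, synthetic) -> tuple[float, float]:
    """OLS slope and intercept of synthetic regressed on real."""
    r = np.asarray(real, dtype=float)
    s = np.asarray(synthetic, dtype=float)
    if r.shape != s.shape or r.ndim != 1 or r.size < 2:
        raise StructuralError("need two equal-length vectors with n >= 2")
    r_bar = r.mean()
    sxx = float(((r - r_bar) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateFitError("real vector is constant; slope undefined")
    slope = float(((r - r_bar) * (s - s.mean())).sum() / sxx)
    intercept = float(s.mean() - slope * r_bar)
    return slope, intercept


def prd(real, synthetic, *, normalization: str = "none") -> float:
    """Percentage root-mean-square difference between two vectors.

    With ``normalization="scale"`` the synthetic vector is first rescaled by
    the least-squares factor sum(real*syn)/sum(syn^2), removing any global
    gain difference.
    """
    r = np.asarray(real, dtype=float)
    s = np.asarray(synthetic, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise StructuralError("need two equal-length vectors")
    denom = float((r**2).sum())
    if denom == 0.0:
        raise DomainError("all-zero real vector: PRD undefined")
    if normalization == "scale":
        ss = float((s**2).sum())
        if ss > 0:
            s = s * float((r * s).sum() / ss)
    elif normalization != "none":
        raise DomainError(f"unknown normalization {normalization!r}")
    return float(100.0 * np.sqrt(((r - s) ** 2).sum() / denom))


def compare_images(real_image, synthetic_image, mask, *, normalization: str = "none") -> SimilarityReport:
    """Slope, intercept and PRD between two images over a shared mask."""
    r = region_to_vector(real_image, mask)
    s = region_to_vector(synthetic_image, mask)
    slope, intercept = similarity_slope(r, s)
    return SimilarityReport(
        slope=slope,
        intercept=intercept,
        prd=prd(r, s, normalization=normalization),
        n=int(r.size),
        normalization=normalization,
    )
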