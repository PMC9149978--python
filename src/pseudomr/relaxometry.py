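"""Per-pixel T1, T2 and proton-density estimation from spin-echo series.

Three estimators, applied pixel-wise:

* T1 from a variable-TR series at fixed TE. Along TR the full spin-echo
  model is exactly ``A(TR) = C1 + C2 e^{-TR/T1}``; the three coefficients
  are found by bounded nonlinear least squares. (Writing the exponential as
  ``b^{C3}`` with ``b = e^{-TR}`` is algebraically the same but underflows
  for TR in milliseconds, so the model is fitted in the stable form.)
* T2 from a variable-TE series at fixed TR. The simplified model gives
  ``ln A = C1 - TE/T2``; ordinary least squares of log-signal on TE after
  excluding non-positive signals yields T2 = -1/slope. Two optional
  refinements are available: a saturation correction that divides out the
  full model's TE-dependent saturation factor using an already-estimated T1
  (the plain log-linear fit is otherwise biased when TR is not >> T1), and
  signal^2-weighted least squares (the delta-method variance weighting for
  log-transformed data, which stops noise-dominated long-TE points from
  wrecking the line).
* rho from the variable-TR series with T1, T2 fixed at their estimates:
  ``A_i = rho * x_i`` with known design factors x_i, solved by
  zero-intercept least squares ``rho = sum(A x) / sum(x^2)``.

``compute_parameter_maps`` runs all three per masked pixel; any pixel whose
fit fails is dropped from the output mask (counted and logged) rather than
raising, so whole-map computation always completes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateFitError,
    EmptyMaskError,
    FitConvergenceError,
    InsufficientDataError,
    PseudoMRError,
    StructuralError,
)
from .signal_model import ParameterMaps, SequenceParams, saturation_factor

__all__ = [
    "AcquisitionSeries",
    "T1FitResult",
    "T2FitResult",
    "RhoFitResult",
    "fit_t1",
    "fit_t2",
    "fit_rho",
    "zero_intercept_slope",
    "compute_parameter_maps",
]

logger = logging.getLogger(__name__)

T1_BOUNDS_MS = (1.0, 20000.0)
_REL_TOL_FIXED = 1e-6  # tolerance for "the fixed parameter is identical across the series"


@dataclass
class AcquisitionSeries:
    """An ordered, co-registered stack of same-shape images with TE/TR tags.

    ``kind`` is ``"variable_tr"`` (TE fixed; >= 4 images) or
    ``"variable_te"`` (TR fixed; >= 3 images). On construction the series is
    sorted by the varying parameter, which must be strictly monotone with no
    duplicates; the fixed parameter must agree across images to relative
    tolerance 1e-6.
    """

    images: np.ndarray
    params: list[SequenceParams]
    kind: str

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise StructuralError("images must be a (n, rows, cols) stack")
        n = self.images.shape[0]
        if len(self.params) != n:
            raise StructuralError("params list length must match number of images")
        if self.kind not in ("variable_tr", "variable_te"):
            raise StructuralError(f"unknown series kind {self.kind!r}")
        min_n = 4 if self.kind == "variable_tr" else 3
        if n < min_n:
            raise StructuralError(f"{self.kind} series needs >= {min_n} images, got {n}")
        varying = np.array(
            [p.tr if self.kind == "variable_tr" else p.te for p in self.params]
        )
        fixed = np.array(
            [p.te if self.kind == "variable_tr" else p.tr for p in self.params]
        )
        if np.ptp(fixed) > _REL_TOL_FIXED * max(abs(fixed[0]), 1.0):
            name = "TE" if self.kind == "variable_tr" else "TR"
            raise StructuralError(f"fixed parameter {name} varies across the series")
        order = np.argsort(varying)
        varying = varying[order]
        if np.any(np.diff(varying) <= 0):
            raise StructuralError("varying parameter has duplicates")
        self.images = self.images[order]
        self.params = [self.params[i] for i in order]

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def tr_values(self) -> np.ndarray:
        return np.array([p.tr for p in self.params])

    @property
    def te_values(self) -> np.ndarray:
        return np.array([p.te for p in self.params])

    def signals_at(self, row: int, col: int) -> np.ndarray:
        """Pixel time-course across the series, in series order."""
        return self.images[:, row, col]


@dataclass(frozen=True)
class T1FitResult:
    """Coefficients of A(TR) = c1 + c2 e^{-TR c3} with T1 = 1/c3."""

    c1: float
    c2: float
    c3: float
    t1: float
    residual_rms: float


@dataclass(frozen=True)
class T2FitResult:
    """Log-linear fit ln A = c1 + c2 TE with T2 = -1/c2 (requires c2 < 0)."""

    c1: float
    c2: float
    t2: float
    residual_rms: float
    n_used: int


@dataclass(frozen=True)
class RhoFitResult:
    rho: float
    residual_rms: float


def fit_t1(tr_values, signals) -> T1FitResult:
    """Estimate T1 from a variable-TR series at fixed TE.

    Fits ``A = C1 + C2 e^{-TR/T1}`` by bounded nonlinear least squares
    (T1 in [1, 20000] ms). Initialization: C1 = max signal,
    C2 = min - max, T1 seeded by log-linearizing C1 - A; falls back to
    the median TR when the linearization is uninformative.
    """
    tr = np.asarray(tr_values, dtype=float)
    a = np.asarray(signals, dtype=float)
    if tr.shape != a.shape or tr.ndim != 1:
        raise StructuralError("tr_values and signals must be equal-length 1D")
    if np.unique(tr).size < 4:
        raise InsufficientDataError("T1 fit needs >= 4 distinct TR values")
    if np.any(~np.isfinite(a)) or np.any(a < 0):
        raise DegenerateFitError("signals must be finite and non-negative")
    span = float(np.ptp(a))
    if span == 0.0:
        raise DegenerateFitError("constant signal series carries no T1 information")

    c1_0 = float(a.max())
    c2_0 = float(a.min() - a.max())
    # seed T1 by log-linearizing the recovery curve
    y = c1_0 + 1e-3 * span - a
    good = y > 0
    t1_0 = float(np.median(tr))
    if good.sum() >= 2:
        slope = np.polyfit(tr[good], np.log(y[good]), 1)[0]
        if slope < 0:
            t1_0 = -1.0 / slope
    t1_0 = float(np.clip(t1_0, *T1_BOUNDS_MS))

    def resid(x):
        return x[0] + x[1] * np.exp(-tr / x[2]) - a

    def jac(x):
        e = np.exp(-tr / x[2])
        return np.column_stack([np.ones_like(tr), e, x[1] * e * tr / x[2] ** 2])

    res = least_squares(
        resid,
        x0=[c1_0, c2_0, t1_0],
        jac=jac,
        bounds=([-np.inf, -np.inf, T1_BOUNDS_MS[0]], [np.inf, np.inf, T1_BOUNDS_MS[1]]),
        method="trf",
        max_nfev=200,
    )
    if not res.success:
        raise FitConvergenceError(f"T1 fit did not converge: {res.message}")
    c1, c2, t1 = (float(v) for v in res.x)
    if not np.isfinite(t1) or t1 <= 0:
        raise DegenerateFitError(f"T1 fit produced non-physical T1={t1}")
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return T1FitResult(c1=c1, c2=c2, c3=1.0 / t1, t1=t1, residual_rms=rms)


def fit_t2(te_values, signals, *, t1=None, tr=None, weighted=False) -> T2FitResult:
    """Estimate T2 from a variable-TE series at fixed TR.

    Plain mode (default): OLS of ln(signal) on TE over points with signal > 0;
    T2 = -1/slope. With ``t1`` and ``tr`` given, the full model's saturation
    factor is divided out of each signal first (it depends weakly on TE
    through TE/2, biasing the plain fit when TR is comparable to T1). With
    ``weighted=True`` the log-domain residuals are weighted by signal^2.
    """
    te = np.asarray(te_values, dtype=float)
    a = np.asarray(signals, dtype=float)
    if te.shape != a.shape or te.ndim != 1:
        raise StructuralError("te_values and signals must be equal-length 1D")
    keep = np.isfinite(a) & (a > 0)
    if (t1 is None) != (tr is None):
        raise StructuralError("saturation correction needs both t1 and tr")
    if t1 is not None:
        sat = saturation_factor(tr, te, t1)
        keep &= sat > 0
    n_used = int(keep.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"T2 fit needs >= 3 positive-signal points, got {n_used}"
        )
    te_k, a_k = te[keep], a[keep]
    y = np.log(a_k)
    if t1 is not None:
        y = y - np.log(sat[keep])
    w = a_k**2 if weighted else np.ones_like(a_k)
    sw = w.sum()
    te_bar = (w * te_k).sum() / sw
    y_bar = (w * y).sum() / sw
    sxx = (w * (te_k - te_bar) ** 2).sum()
    if sxx == 0:
        raise DegenerateFitError("all retained TE values identical")
    c2 = float((w * (te_k - te_bar) * (y - y_bar)).sum() / sxx)
    c1 = float(y_bar - c2 * te_bar)
    if c2 >= 0:
        raise DegenerateFitError(f"non-negative log-signal slope {c2}: T2 undefined")
    rms = float(np.sqrt(np.mean((c1 + c2 * te_k - y) ** 2)))
    return T2FitResult(c1=c1, c2=c2, t2=-1.0 / c2, residual_rms=rms, n_used=n_used)


def zero_intercept_slope(x, a) -> float:
    """Least-squares slope of a = rho x through the origin: sum(ax)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    denom = float((x**2).sum())
    if denom == 0.0:
        raise DegenerateFitError("all design factors are zero")
    return float((a * x).sum() / denom)


def fit_rho(tr_values, signals, te, t1, t2) -> RhoFitResult:
    """Estimate proton density from the variable-TR series with T1, T2 known.

    Computes the design factor
    ``x_i = (1 - 2 e^{-(TR_i - TE/2)/T1} + e^{-TR_i/T1}) e^{-TE/T2}`` per
    image and returns the zero-intercept least-squares slope. A (noise-driven)
    negative estimate is clamped to 0.
    """
    tr = np.asarray(tr_values, dtype=float)
    a = np.asarray(signals, dtype=float)
    if tr.shape != a.shape or tr.size < 1:
        raise StructuralError("tr_values and signals must be equal-length, non-empty")
    if t1 <= 0 or t2 <= 0:
        raise DegenerateFitError("rho fit needs positive T1 and T2")
    x = saturation_factor(tr, te, t1) * np.exp(-te / t2)
    rho = max(zero_intercept_slope(x, a), 0.0)
    rms = float(np.sqrt(np.mean((rho * x - a) ** 2)))
    return RhoFitResult(rho=rho, residual_rms=rms)


def compute_parameter_maps(
    tr_series: AcquisitionSeries,
    te_series: AcquisitionSeries,
    mask,
    *,
    t2_saturation_correction: bool = True,
    t2_weighted: bool = True,
) -> ParameterMaps:
    """Fit T1, T2 and rho maps over a masked region.

    Per masked pixel: fit_t1 on the variable-TR series, fit_t2 on the
    variable-TE series (by default with the saturation correction using the
    just-fitted T1, and signal^2 weighting), then fit_rho on the variable-TR
    series. Pixels where any fit fails are dropped from the output mask.
    """
    if tr_series.kind != "variable_tr" or te_series.kind != "variable_te":
        raise StructuralError("need one variable_tr and one variable_te series")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tr_series.shape or mask.shape != te_series.shape:
        raise StructuralError("mask shape does not match series image shape")
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")

    tr_vals = tr_series.tr_values
    te_vals = te_series.te_values
    te_fixed = float(tr_series.te_values[0])
    tr_fixed = float(te_series.tr_values[0])

    shape = mask.shape
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    rho = np.full(shape, np.nan)
    q_t1 = np.full(shape, np.nan)
    q_t2 = np.full(shape, np.nan)
    q_rho = np.full(shape, np.nan)
    out_mask = np.zeros(shape, dtype=bool)
    n_failed = 0

    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        try:
            f1 = fit_t1(tr_vals, tr_series.images[:, r, c])
            f2 = fit_t2(
                te_vals,
                te_series.images[:, r, c],
                t1=f1.t1 if t2_saturation_correction else None,
                tr=tr_fixed if t2_saturation_correction else None,
                weighted=t2_weighted,
            )
            f3 = fit_rho(tr_vals, tr_series.images[:, r, c], te_fixed, f1.t1, f2.t2)
        except PseudoMRError:
            n_failed += 1
            continue
        t1[r, c] = f1.t1
        t2[r, c] = f2.t2
        rho[r, c] = f3.rho
        q_t1[r, c] = f1.residual_rms
        q_t2[r, c] = f2.residual_rms
        q_rho[r, c] = f3.residual_rms
        out_mask[r, c] = True

    if n_failed:
        logger.info("parameter-map fitting dropped %d of %d pixels", n_failed, rows.size)
    if not out_mask.any():
        raise EmptyMaskError("every masked pixel failed to fit")
    return ParameterMaps(
        t1=t1,
        t2=t2,
        rho=rho,
        mask=out_mask,
        fit_quality={"t1_rms": q_t1, "t2_rms": q_t2, "rho_rms": q_rho},
    )
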