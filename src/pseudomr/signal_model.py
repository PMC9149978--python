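"""Spin-echo steady-state signal model and weighted-image synthesis.

The amplitude of a (90°–180°) spin-echo acquisition at echo time TE and
repetition time TR for a tissue with longitudinal relaxation time T1,
transverse relaxation time T2 and proton density rho is

    A(TE, TR) = rho * (1 - 2 e^{-(TR - TE/2)/T1} + e^{-TR/T1}) * e^{-TE/T2}

which for TE << TR reduces to the familiar saturation-recovery form

    A(TE, TR) ~= rho * (1 - e^{-TR/T1}) * e^{-TE/T2}.

All times are in milliseconds; rho carries arbitrary signal units (scanner
gain is an unknown constant scale, so no absolute calibration is attempted).
The full model's saturation factor can go negative when TR - TE/2 is small
relative to T1; magnitude-reconstructed MR images are non-negative, so by
default the signal is clamped at zero from below (``clamp_negative=False``
returns the signed value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, StructuralError

__all__ = [
    "SequenceParams",
    "TissueParams",
    "ParameterMaps",
    "spin_echo_signal",
    "spin_echo_signal_simplified",
    "synthesize_weighted_image",
    "saturation_factor",
]


@dataclass(frozen=True)
class SequenceParams:
    """Contrast parameters of one spin-echo acquisition.

    Attributes
    ----------
    te : float
        Echo time in milliseconds. Must satisfy 0 < te < tr.
    tr : float
        Repetition time in milliseconds.
    """

    te: float
    tr: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.te) and np.isfinite(self.tr)):
            raise DomainError("TE and TR must be finite")
        if self.te <= 0 or self.tr <= 0:
            raise DomainError(f"TE and TR must be positive (got TE={self.te}, TR={self.tr})")
        if self.te >= self.tr:
            raise DomainError(f"TE must be smaller than TR (got TE={self.te}, TR={self.tr})")


@dataclass(frozen=True)
class TissueParams:
    """Intrinsic contrast parameters of one tissue.

    t1, t2 in milliseconds (strictly positive); rho in arbitrary signal
    units (non-negative).
    """

    t1: float
    t2: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite (got {v})")
        if self.t1 <= 0 or self.t2 <= 0:
            raise DomainError(f"T1 and T2 must be positive (got T1={self.t1}, T2={self.t2})")
        if self.rho < 0:
            raise DomainError(f"rho must be non-negative (got {self.rho})")


@dataclass
class ParameterMaps:
    """Per-pixel T1/T2/rho grids over a masked region.

    All grids share one shape. Inside the mask the values are finite, with
    T1, T2 > 0 and rho >= 0; outside the mask they are set to NaN on
    construction (flagged invalid). ``fit_quality`` optionally carries
    per-pixel residual grids keyed by name.
    """

    t1: np.ndarray
    t2: np.ndarray
    rho: np.ndarray
    mask: np.ndarray
    fit_quality: dict[str, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = self.mask.shape
        for name in ("t1", "t2", "rho"):
            g = getattr(self, name)
            if g.shape != shape:
                raise StructuralError(
                    f"{name} grid shape {g.shape} does not match mask shape {shape}"
                )
        m = self.mask
        if m.any():
            for name, positive in (("t1", True), ("t2", True), ("rho", False)):
                vals = getattr(self, name)[m]
                if not np.all(np.isfinite(vals)):
                    raise DomainError(f"non-finite {name} values inside mask")
                if positive and np.any(vals <= 0):
                    raise DomainError(f"non-positive {name} values inside mask")
                if not positive and np.any(vals < 0):
                    raise DomainError(f"negative {name} values inside mask")
        # flag out-of-mask pixels invalid
        for name in ("t1", "t2", "rho"):
            g = getattr(self, name).copy()
            g[~m] = np.nan
            setattr(self, name, g)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def tissue_at(self, row: int, col: int) -> TissueParams:
        """Return the TissueParams of one in-mask pixel."""
        if not self.mask[row, col]:
            raise DomainError(f"pixel ({row}, {col}) is outside the mask")
        return TissueParams(self.t1[row, col], self.t2[row, col], self.rho[row, col])


def saturation_factor(tr, te, t1):
    """The TR/T1-dependent factor of the full spin-echo model.

    ``1 - 2 e^{-(TR - TE/2)/T1} + e^{-TR/T1}``; array-broadcasting.
    """
    tr = np.asarray(tr, dtype=float)
    te = np.asarray(te, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    return 1.0 - 2.0 * np.exp(-(tr - te / 2.0) / t1) + np.exp(-tr / t1)


def _signal_arrays(t1, t2, rho, te, tr, clamp_negative=True):
    s = rho * saturation_factor(tr, te, t1) * np.exp(-np.asarray(te, float) / np.asarray(t2, float))
    if clamp_negative:
        s = np.maximum(s, 0.0)
    return s


def spin_echo_signal(
    tissue: TissueParams, seq: SequenceParams, *, clamp_negative: bool = True
) -> float:
    """Spin-echo signal amplitude of one tissue under one acquisition.

    Parameters
    ----------
    tissue, seq
        Validated tissue and sequence parameters.
    clamp_negative
        If True (default) the returned amplitude is clamped at zero from
        below, matching magnitude reconstruction.
    """
    return float(
        _signal_arrays(tissue.t1, tissue.t2, tissue.rho, seq.te, seq.tr, clamp_negative)
    )


def spin_echo_signal_simplified(tissue: TissueParams, seq: SequenceParams) -> float:
    """Simplified (TE << TR) spin-echo amplitude: rho (1 - e^{-TR/T1}) e^{-TE/T2}."""
    return float(
        tissue.rho
        * (1.0 - np.exp(-seq.tr / tissue.t1))
        * np.exp(-seq.te / tissue.t2)
    )


def synthesize_weighted_image(
    maps: ParameterMaps, seq: SequenceParams, *, clamp_negative: bool = True
) -> np.ndarray:
    """Generate a weighted image by applying the signal model per pixel.

    Pixels outside the map mask are set to 0. The output shares the map
    shape. An all-false mask yields an all-zero image.
    """
    if not isinstance(maps, ParameterMaps):
        raise StructuralError("maps must be a ParameterMaps instance")
    out = np.zeros(maps.shape, dtype=float)
    m = maps.mask
    if m.any():
        out[m] = _signal_arrays(
            maps.t1[m], maps.t2[m], maps.rho[m], seq.te, seq.tr, clamp_negative
        )
    return out
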