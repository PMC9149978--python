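"""Digital tri-modality phantom: co-registered CT and spin-echo MR with truth.

Emulates a multi-tissue abdominal slice the way a tissue-mimicking physical
phantom would present to a CT and a 1.5 T MR scanner: each tissue has a
constant (T1, T2, rho) triple, a mean CT number and a within-tissue CT
texture standard deviation. The CT texture is spatially smoothed so that
small windows see a tissue-characteristic sigma — the premise that local
CT statistics identify tissue. CT acquisitions can be repeated and averaged
(noise sd falls as 1/sqrt(n)); MR series are simulated through the full
spin-echo model with Gaussian (default) or Rician noise.

All randomness flows from the explicit seed of each call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DomainError, StructuralError
from .signal_model import ParameterMaps, SequenceParams, synthesize_weighted_image
from .relaxometry import AcquisitionSeries

__all__ = [
    "TissueSpec",
    "PhantomSlice",
    "make_phantom",
    "simulate_ct",
    "simulate_mr_series",
    "abdominal_tissue_specs",
    "default_phantom",
    "t1_series_params",
    "t2_series_params",
    "VALIDATION_WEIGHTINGS",
]

# Acquisition protocol used throughout: variable-TR series at fixed TE for
# T1/rho, variable-TE series at fixed TR for T2, and the three validation
# weightings (T1-, T2- and rho-weighted).
T1_SERIES_TR_MS = (100.0, 200.0, 400.0, 800.0, 1250.0, 2000.0, 4000.0, 5000.0)
T1_SERIES_TE_MS = 20.0
T2_SERIES_TE_MS = (10.0, 15.0, 25.0, 40.0, 60.0, 90.0, 130.0, 180.0, 240.0)
T2_SERIES_TR_MS = 2000.0
VALIDATION_WEIGHTINGS = {
    "t1w": SequenceParams(te=10.0, tr=500.0),
    "t2w": SequenceParams(te=130.0, tr=2000.0),
    "pdw": SequenceParams(te=10.0, tr=4000.0),
}


def t1_series_params() -> list[SequenceParams]:
    """Variable-TR protocol (TE fixed) for T1/rho mapping."""
    return [SequenceParams(te=T1_SERIES_TE_MS, tr=tr) for tr in T1_SERIES_TR_MS]


def t2_series_params() -> list[SequenceParams]:
    """Variable-TE protocol (TR fixed) for T2 mapping."""
    return [SequenceParams(te=te, tr=T2_SERIES_TR_MS) for te in T2_SERIES_TE_MS]


@dataclass(frozen=True)
class TissueSpec:
    """One tissue-mimicking material and where it sits in the slice.

    geometry is one of
      ("ellipse", row_center, col_center, row_radius, col_radius)
      ("rect", row0, col0, height, width)
      ("mask", boolean array)
    in 0-based row-major pixel coordinates (pixel centers).
    """

    label: str
    geometry: tuple
    t1: float
    t2: float
    rho: float
    hu_mean: float
    hu_texture_sd: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise DomainError(f"{self.label}: T1 and T2 must be positive")
        if self.rho < 0 or self.hu_texture_sd < 0:
            raise DomainError(f"{self.label}: rho and hu_texture_sd must be non-negative")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        kind = self.geometry[0]
        if kind == "ellipse":
            _, r0, c0, rr, rc = self.geometry
            r, c = np.mgrid[0 : shape[0], 0 : shape[1]]
            return ((r - r0) / rr) ** 2 + ((c - c0) / rc) ** 2 <= 1.0
        if kind == "rect":
            _, r0, c0, h, w = self.geometry
            m = np.zeros(shape, dtype=bool)
            m[int(r0) : int(r0 + h), int(c0) : int(c0 + w)] = True
            return m
        if kind == "mask":
            m = np.asarray(self.geometry[1], dtype=bool)
            if m.shape != shape:
                raise StructuralError(f"{self.label}: mask geometry shape mismatch")
            return m
        raise DomainError(f"{self.label}: unknown geometry kind {kind!r}")


@dataclass
class PhantomSlice:
    """Ground truth of one simulated slice."""

    label_map: np.ndarray  # -1 = background, else index into specs
    truth_maps: ParameterMaps
    truth_ct: np.ndarray  # noiseless HU grid
    shape: tuple[int, int]
    seed: int
    specs: list[TissueSpec] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map >= 0

    def tissue_mask(self, label: str) -> np.ndarray:
        idx = [s.label for s in self.specs].index(label)
        return self.label_map == idx


BACKGROUND_HU = -1000.0  # air


def make_phantom(
    specs: list[TissueSpec],
    shape: tuple[int, int] = (128, 128),
    *,
    texture_correlation: float = 2.0,
    edge_blend: float = 0.8,
    seed: int = 0,
) -> PhantomSlice:
    """Build a phantom slice with known truth maps and noiseless CT.

    The CT texture is a seeded Gaussian random field smoothed with a
    Gaussian kernel of width ``texture_correlation`` pixels, then
    standardized per tissue so each region's sample sd equals its
    ``hu_texture_sd`` exactly. Tissue geometries must not overlap.

    ``edge_blend`` emulates partial volume at tissue-tissue interfaces: a
    pixel within ~``edge_blend`` pixels of a contact boundary carries a
    volume-weighted mix of the adjacent tissues' parameters and HU (no
    finite-resolution scanner presents an infinitely sharp interface).
    Pixels of a tissue not in contact with another tissue are unaffected,
    as is every interior pixel; 0 disables blending. Deterministic given
    the seed.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise DomainError("phantom shape must be at least 32 x 32")
    if edge_blend < 0:
        raise DomainError("edge_blend must be non-negative")
    label_map = np.full(shape, -1, dtype=int)
    for i, spec in enumerate(specs):
        m = spec.rasterize(shape)
        if not m.any():
            raise StructuralError(f"{spec.label}: geometry rasterizes to no pixels")
        if (label_map[m] != -1).any():
            raise StructuralError(f"{spec.label}: geometry overlaps an earlier tissue")
        label_map[m] = i
    mask = label_map >= 0

    # partial-volume composition weights per tissue
    n_t = len(specs)
    if edge_blend > 0:
        w = np.stack(
            [gaussian_filter((label_map == i).astype(float), edge_blend) for i in range(n_t)]
        )
        wsum = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(wsum > 0, w / wsum, 0.0)
    else:
        w = np.stack([(label_map == i).astype(float) for i in range(n_t)])

    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=texture_correlation)
    tex = np.zeros(shape)
    for i, spec in enumerate(specs):
        m = label_map == i
        if spec.hu_texture_sd > 0 and m.sum() >= 2:
            f = field_[m]
            sd = f.std(ddof=1)
            if sd > 0:
                tex[m] = (f - f.mean()) / sd * spec.hu_texture_sd

    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    rho = np.full(shape, np.nan)
    truth_ct = np.full(shape, BACKGROUND_HU)
    par = {
        "t1": np.array([s.t1 for s in specs]),
        "t2": np.array([s.t2 for s in specs]),
        "rho": np.array([s.rho for s in specs]),
        "hu": np.array([s.hu_mean for s in specs]),
    }
    blend = {k: np.einsum("kij,k->ij", w, v) for k, v in par.items()}
    t1[mask] = blend["t1"][mask]
    t2[mask] = blend["t2"][mask]
    rho[mask] = blend["rho"][mask]
    truth_ct[mask] = blend["hu"][mask] + tex[mask]

    truth_maps = ParameterMaps(t1=t1, t2=t2, rho=rho, mask=mask)
    return PhantomSlice(
        label_map=label_map,
        truth_maps=truth_maps,
        truth_ct=truth_ct,
        shape=shape,
        seed=seed,
        specs=list(specs),
    )


def simulate_ct(
    phantom: PhantomSlice, *, noise_sd: float = 10.0, n_repeats: int = 9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated CT acquisitions and their pixel-wise average.

    Each repeat is truth_ct plus independent zero-mean Gaussian noise of sd
    ``noise_sd`` HU; averaging ``n_repeats`` repeats leaves residual noise
    of sd noise_sd/sqrt(n_repeats). Returns (averaged image, repeat stack).
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if n_repeats < 1:
        raise DomainError("n_repeats must be >= 1")
    if noise_sd == 0:
        stack = np.repeat(phantom.truth_ct[None], n_repeats, axis=0)
        return phantom.truth_ct.copy(), stack
    rng = np.random.default_rng(seed)
    stack = phantom.truth_ct[None] + rng.normal(
        0.0, noise_sd, size=(n_repeats,) + phantom.shape
    )
    return stack.mean(axis=0), stack


def simulate_mr_series(
    phantom: PhantomSlice,
    seq_list: list[SequenceParams],
    *,
    noise_model: str = "gaussian",
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str | None = None,
) -> AcquisitionSeries:
    """Simulate a co-registered spin-echo series from the truth maps.

    Per image: the full spin-echo forward model of the truth maps plus
    seeded noise over the whole grid. ``gaussian`` adds zero-mean noise;
    ``rician`` takes the magnitude of signal + complex Gaussian noise (the
    magnitude-reconstruction statistics of real scanners; expected
    background magnitude is noise_sd*sqrt(pi/2)). ``kind`` is inferred from
    the sequence list when not given.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise DomainError(f"unknown noise model {noise_model!r}")
    if kind is None:
        tes = {p.te for p in seq_list}
        trs = {p.tr for p in seq_list}
        if len(tes) == 1 and len(trs) > 1:
            kind = "variable_tr"
        elif len(trs) == 1 and len(tes) > 1:
            kind = "variable_te"
        else:
            raise StructuralError("cannot infer series kind; pass kind= explicitly")
    rng = np.random.default_rng(seed)
    images = []
    for seq in seq_list:
        s = synthesize_weighted_image(phantom.truth_maps, seq)
        if noise_sd > 0:
            if noise_model == "gaussian":
                s = s + rng.normal(0.0, noise_sd, size=s.shape)
            else:
                s = np.hypot(
                    s + rng.normal(0.0, noise_sd, size=s.shape),
                    rng.normal(0.0, noise_sd, size=s.shape),
                )
        images.append(s)
    return AcquisitionSeries(images=np.stack(images), params=list(seq_list), kind=kind)


def abdominal_tissue_specs(variant: str = "A") -> list[TissueSpec]:
    """Three-tissue liver-region phantom at 1.5 T literature values.

    A large hepatic-parenchyma region containing a dense lesion and a cyst
    (the single-organ, multi-ROI setting of a liver partition). Variants
    "A" and "B" share the tissue set but differ in geometry, emulating two
    nearby slices of one phantom.
    """
    params = {
        "liver": dict(t1=586.0, t2=54.0, rho=720.0, hu_mean=55.0, hu_texture_sd=4.0),
        "lesion": dict(t1=1060.0, t2=79.0, rho=780.0, hu_mean=30.0, hu_texture_sd=6.0),
        "cyst": dict(t1=1400.0, t2=220.0, rho=950.0, hu_mean=8.0, hu_texture_sd=3.0),
    }
    if variant == "A":
        geoms = {
            "liver": ("ellipse", 62, 58, 44, 50),
            "lesion": ("ellipse", 76, 80, 12, 10),
            "cyst": ("ellipse", 48, 40, 9, 11),
        }
    elif variant == "B":
        geoms = {
            "liver": ("ellipse", 64, 66, 42, 46),
            "lesion": ("ellipse", 52, 78, 10, 12),
            "cyst": ("ellipse", 80, 52, 8, 8),
        }
    else:
        raise DomainError(f"unknown phantom variant {variant!r}")
    return [
        TissueSpec(label=name, geometry=geoms[name], **params[name])
        for name in ("liver", "lesion", "cyst")
    ]


def default_phantom(
    variant: str = "A",
    shape: tuple[int, int] = (128, 128),
    *,
    texture_correlation: float = 2.0,
    edge_blend: float = 0.8,
    seed: int = 0,
) -> PhantomSlice:
    """Build the default liver-region phantom slice.

    Insert geometries are carved out of the parenchyma ellipse so no pixel
    carries two labels; geometry parameters are scaled from the 128 x 128
    reference layout to the requested shape.
    """
    specs = abdominal_tissue_specs(variant)
    sr, sc = shape[0] / 128.0, shape[1] / 128.0

    def scaled(geom):
        k, r0, c0, a, b = geom
        return (k, r0 * sr, c0 * sc, a * sr, b * sc)

    inserts = [
        TissueSpec(
            label=s.label,
            geometry=scaled(s.geometry),
            t1=s.t1,
            t2=s.t2,
            rho=s.rho,
            hu_mean=s.hu_mean,
            hu_texture_sd=s.hu_texture_sd,
        )
        for s in specs[1:]
    ]
    liver = specs[0]
    liver_ellipse = TissueSpec(
        label="liver",
        geometry=scaled(liver.geometry),
        t1=liver.t1,
        t2=liver.t2,
        rho=liver.rho,
        hu_mean=liver.hu_mean,
        hu_texture_sd=liver.hu_texture_sd,
    )
    full = liver_ellipse.rasterize(tuple(int(s) for s in shape))
    for ins in inserts:
        full &= ~ins.rasterize(tuple(int(s) for s in shape))
    carved = TissueSpec(
        label="liver",
        geometry=("mask", full),
        t1=liver.t1,
        t2=liver.t2,
        rho=liver.rho,
        hu_mean=liver.hu_mean,
        hu_texture_sd=liver.hu_texture_sd,
    )
    return make_phantom(
        [carved] + inserts,
        shape,
        texture_correlation=texture_correlation,
        edge_blend=edge_blend,
        seed=seed,
    )
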