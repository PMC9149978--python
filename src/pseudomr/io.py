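"""Image readers/writers, series manifests, and parameter-map serialization.

Conventions: arrays are 2D float64 grids indexed (row, col), 0-based,
pixel-center; NIfTI volumes store the array with index (i, j) = (row, col)
and an identity affine, so write-then-read is the identity. CT DICOMs are
rescaled to HU using the RescaleSlope/RescaleIntercept tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import FormatError, StructuralError
from .relaxometry import AcquisitionSeries
from .signal_model import ParameterMaps, SequenceParams

__all__ = [
    "read_image",
    "write_text_grid",
    "write_nifti",
    "write_parameter_maps",
    "read_parameter_maps",
    "ManifestEntry",
    "SeriesManifest",
    "load_series",
]

_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.suffix.lower() in (".dcm", ".dicom", ".ima"):
        return "dicom"
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return "text"
    raise FormatError(f"cannot infer image format from {path.name!r}")


def read_image(path, fmt: str | None = None) -> tuple[np.ndarray, tuple[float, float], dict]:
    """Read a 2D grayscale image.

    Returns (array, (row_spacing, col_spacing) in mm, metadata dict).
    Supported: DICOM (HU rescale applied), NIfTI-1, delimited text.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)
    try:
        if fmt == "dicom":
            ds = pydicom.dcmread(path)
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
            spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", [1.0, 1.0]))
            meta = {"format": "dicom", "rescale_slope": slope, "rescale_intercept": intercept}
        elif fmt == "nifti":
            img = nib.load(path)
            arr = np.asarray(img.dataobj, dtype=float)
            arr = np.squeeze(arr)
            zooms = img.header.get_zooms()
            spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
            meta = {"format": "nifti"}
        elif fmt == "text":
            delim = "," if path.suffix.lower() == ".csv" else None
            arr = np.loadtxt(path, delimiter=delim, ndmin=2)
            spacing = (1.0, 1.0)
            meta = {"format": "text"}
        else:
            raise FormatError(f"unknown format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # parse failures from the underlying readers
        raise FormatError(f"could not read {path} as {fmt}: {exc}") from exc
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path} contains non-finite pixel values")
    return arr, spacing, meta


def write_text_grid(path, array) -> None:
    """Write a 2D grid as whitespace-delimited text (round-trip exact at %.17g)."""
    np.savetxt(path, np.asarray(array, dtype=float), fmt="%.17g")


def write_nifti(path, array, spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    """Write an array as NIfTI-1 with a diagonal affine from the spacing."""
    array = np.asarray(array)
    affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(array, affine), str(path))


def write_parameter_maps(path, maps: ParameterMaps) -> None:
    """Serialize ParameterMaps as a 4-channel float32 NIfTI [t1, t2, rho, mask]."""
    stack = np.stack(
        [maps.t1, maps.t2, maps.rho, maps.mask.astype(float)], axis=-1
    ).astype(np.float32)
    write_nifti(path, stack)


def read_parameter_maps(path) -> ParameterMaps:
    img = nib.load(str(path))
    stack = np.asarray(img.dataobj, dtype=np.float32)
    if stack.ndim != 3 or stack.shape[-1] != 4:
        raise FormatError(f"{path} is not a 4-channel parameter-map volume")
    mask = stack[..., 3] > 0.5
    return ParameterMaps(
        t1=stack[..., 0].astype(float),
        t2=stack[..., 1].astype(float),
        rho=stack[..., 2].astype(float),
        mask=mask,
    )


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    te: float
    tr: float
    role: str  # t1_series | t2_series | reference | ct


@dataclass
class SeriesManifest:
    """List of acquisition files with their TE/TR tags and roles."""

    entries: list[ManifestEntry] = field(default_factory=list)
    slice_id: str = ""

    _ROLES = ("t1_series", "t2_series", "reference", "ct")

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.role not in self._ROLES:
                raise StructuralError(f"unknown manifest role {e.role!r} for {e.path}")

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps({"slice_id": self.slice_id, "entries": [asdict(e) for e in self.entries]})
        )

    @classmethod
    def load(cls, path) -> "SeriesManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            entries=[ManifestEntry(**e) for e in d["entries"]],
            slice_id=d.get("slice_id", ""),
        )


def load_series(manifest: SeriesManifest, root, role: str) -> AcquisitionSeries:
    """Assemble an AcquisitionSeries from the manifest entries of one role.

    Paths are resolved relative to ``root``; role consistency (shared TE for
    t1_series, shared TR for t2_series, monotone varying parameter) is
    enforced by the AcquisitionSeries constructor.
    """
    root = Path(root)
    entries = [e for e in manifest.entries if e.role == role]
    if not entries:
        raise StructuralError(f"manifest has no entries with role {role!r}")
    images, params = [], []
    for e in entries:
        p = root / e.path
        if not p.exists():
            raise FormatError(f"manifest entry points to missing file: {p}")
        arr, _, _ = read_image(p)
        images.append(arr)
        params.append(SequenceParams(te=e.te, tr=e.tr))
    kind = "variable_tr" if role == "t1_series" else "variable_te"
    return AcquisitionSeries(images=np.stack(images), params=params, kind=kind)
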