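"""Volume containers, slice-stack / NIfTI I/O and mineral-density calibration.

Grey-value volumes come either as a directory of single-slice TIFF files
(one 2D image per file, ordered by natural filename sort) or as a NIfTI-1
volume.  TIFF stacks carry no voxel-size metadata, so the isotropic voxel
size in micrometres must be supplied by the caller; for NIfTI it is taken
from the header zooms unless explicitly overridden.

Density calibration is a linear map from stored grey values to equivalent
mineral density in mg hydroxyapatite (HA) per cm**3, anchored by scanning a
phantom of known density (conventionally 1200 mg HA/cm**3).  Only this
linear two-point/least-squares hook is provided; non-linear beam-hardening
corrections are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "GreyVolume",
    "LabelVolume",
    "DensityCalibration",
    "LABEL_BACKGROUND",
    "LABEL_CALLUS",
    "LABEL_CORTEX",
    "LABEL_OUTSIDE",
    "read_volume",
    "write_volume",
    "fit_calibration",
    "calibrate_density",
]

#: Label codes of the three-class segmentation.
LABEL_BACKGROUND = 0  # marrow / air
LABEL_CALLUS = 1
LABEL_CORTEX = 2
LABEL_OUTSIDE = 255  # outside the cylindrical VOI

_VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_CALLUS, LABEL_CORTEX, LABEL_OUTSIDE})


def _check_voxel_size(voxel_size_um: float) -> float:
    voxel_size_um = float(voxel_size_um)
    if not np.isfinite(voxel_size_um) or voxel_size_um <= 0:
        raise ValueError(f"voxel size must be positive and finite, got {voxel_size_um}")
    return voxel_size_um


@dataclass
class GreyVolume:
    """A 3D scalar voxel grid with isotropic voxel size.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, n_rows, n_cols)``.  Axis order is
        (z, y, x), 0-based.
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    value_kind
        ``"grey"`` for raw dimensionless scanner values, ``"density"`` once
        calibrated to mg HA/cm**3.
    """

    data: np.ndarray
    voxel_size_um: float
    value_kind: str = "grey"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)
        if self.value_kind not in ("grey", "density"):
            raise ValueError(f"value_kind must be 'grey' or 'density', got {self.value_kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size_um * 1e-3) ** 3

    def extent_um(self) -> tuple:
        """Physical span of the volume along (z, y, x) in micrometres."""
        return tuple(n * self.voxel_size_um for n in self.data.shape)


@dataclass
class LabelVolume:
    """Categorical companion of :class:`GreyVolume`.

    Codes: 0 background (marrow/air), 1 callus, 2 original cortical bone,
    255 outside the VOI.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)
        present = set(np.unique(self.data).tolist())
        if not present <= _VALID_LABELS:
            raise ValueError(f"invalid label codes present: {sorted(present - _VALID_LABELS)}")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def mask(self, label: int) -> np.ndarray:
        return self.data == label


@dataclass
class DensityCalibration:
    """Linear grey -> mg HA/cm**3 map: ``density = slope * grey + intercept``."""

    slope: float
    intercept: float
    phantom_density: float = 1200.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")

    def __call__(self, grey: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        return self.slope * grey + self.intercept


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _read_tiff_stack(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in {path}")
    slices = []
    shape = dtype = None
    for f in files:
        img = tifffile.imread(f)
        if img.ndim != 2:
            raise ValueError(f"{f.name}: expected a single 2D slice, got shape {img.shape}")
        if shape is None:
            shape, dtype = img.shape, img.dtype
        elif img.shape != shape:
            raise ValueError(
                f"inconsistent slice shapes: {f.name} is {img.shape}, expected {shape}"
            )
        elif img.dtype != dtype:
            raise ValueError(f"inconsistent slice dtypes: {f.name} is {img.dtype}, expected {dtype}")
        slices.append(img)
    return np.stack(slices, axis=0)


def read_volume(
    path,
    format: str = None,
    voxel_size_um: float = None,
) -> GreyVolume:
    """Read a grey-value volume from a TIFF slice stack or a NIfTI file.

    Parameters
    ----------
    path
        Directory of per-slice TIFFs, or a ``.nii``/``.nii.gz`` file.
    format
        ``"tiff_stack"`` or ``"nifti"``; inferred from ``path`` when omitted.
    voxel_size_um
        Required for TIFF stacks (they carry no metadata).  For NIfTI the
        header zoom wins unless this override is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "tiff_stack" if path.is_dir() else "nifti"
    if format == "tiff_stack":
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF stacks (no metadata)")
        data = _read_tiff_stack(path)
        return GreyVolume(data, voxel_size_um)
    if format == "nifti":
        img = nib.load(str(path))
        # stored (x, y, z); convert to our (z, y, x) convention
        data = np.asarray(img.dataobj).T
        if voxel_size_um is None:
            zooms = img.header.get_zooms()[:3]
            if max(zooms) - min(zooms) > 1e-6 * max(zooms):
                raise ValueError(f"anisotropic NIfTI zooms {zooms}; pass voxel_size_um explicitly")
            voxel_size_um = float(zooms[0]) * 1000.0  # header mm -> um
        return GreyVolume(data, voxel_size_um)
    raise ValueError(f"unknown format {format!r}")


def write_volume(vol, path, format: str = None) -> None:
    """Write a :class:`GreyVolume` or :class:`LabelVolume`.

    TIFF stacks are written as zero-padded ``slice_0000.tif`` files into the
    directory ``path`` (created if missing, parent must exist); NIfTI as a
    single file with the voxel size recorded in mm in the header.  Integer
    data round-trips losslessly through either format.
    """
    path = Path(path)
    if format is None:
        format = "nifti" if path.suffix in (".nii", ".gz") else "tiff_stack"
    data = vol.data
    if format == "tiff_stack":
        if not path.parent.exists():
            raise FileNotFoundError(f"parent directory {path.parent} does not exist")
        path.mkdir(exist_ok=True)
        width = max(4, len(str(len(data) - 1)))
        for i, sl in enumerate(data):
            tifffile.imwrite(path / f"slice_{i:0{width}d}.tif", sl)
    elif format == "nifti":
        if not path.parent.exists():
            raise FileNotFoundError(f"parent directory {path.parent} does not exist")
        vox_mm = vol.voxel_size_um * 1e-3
        img = nib.Nifti1Image(np.asarray(data).T, affine=np.diag([vox_mm] * 3 + [1.0]))
        img.header.set_zooms((vox_mm,) * 3)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def fit_calibration(
    pairs: Iterable[Sequence[float]], phantom_density: float = 1200.0
) -> DensityCalibration:
    """Least-squares line through (grey, density) pairs.

    With exactly two pairs the line interpolates both, so a measurement of
    the calibration phantom maps back to its nominal density exactly.
    """
    pairs = [(float(g), float(d)) for g, d in pairs]
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 calibration pairs, got {len(pairs)}")
    grey = np.array([g for g, _ in pairs])
    dens = np.array([d for _, d in pairs])
    if np.unique(grey).size < len(pairs):
        raise ValueError("duplicated grey values in calibration pairs")
    slope, intercept = np.polyfit(grey, dens, 1)
    return DensityCalibration(float(slope), float(intercept), phantom_density)


def calibrate_density(vol: GreyVolume, calib: DensityCalibration) -> GreyVolume:
    """Apply the affine grey -> density map; result carries ``value_kind='density'``."""
    if vol.value_kind != "grey":
        raise ValueError("volume is already density-calibrated")
    return GreyVolume(calib(vol.data.astype(float)), vol.voxel_size_um, value_kind="density")
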