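"""Seven-parameter 3D morphometric panel for a segmented compartment.

All quantities are computed directly on the voxel grid, without any model
assumption about the structure type (plate-like vs rod-like):

* BV — bone volume, voxel count times voxel volume, mm**3.
* BS — bone surface, area of the triangulated iso-surface, mm**2.
* Tb.Th. — mean local thickness: at each voxel, the diameter of the
  largest sphere that fits inside the structure and contains the voxel.
* SMI — structure model index, ``6 * BV * S' / S**2`` with ``S'`` the
  derivative of surface area under infinitesimal surface dilation
  (0 plates, 3 rods, 4 spheres; negative for concave structures).
* DA — degree of anisotropy: ratio of longest to shortest axis of the
  mean-intercept-length (MIL) fabric ellipsoid, >= 1.
* TMD — tissue mineral density: mean calibrated density over the
  compartment after peeling two voxel layers to suppress partial-volume
  voxels, mg HA/cm**3.
* BMC — bone mineral content, ``BV * TMD / 1000``, mg.

Surface meshing operates on the Gaussian-smoothed (sigma = 1 voxel) binary
field at iso-level 0.5; meshing the raw binary field would overestimate
curved surfaces by the staircase effect (~9% on digitized spheres, versus
<0.5% after smoothing).  Surfaces are left open where the structure meets
the volume boundary, so VOI cut faces do not count as bone surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, special
from skimage import measure

from .volume_io import LABEL_CALLUS, LABEL_CORTEX, GreyVolume, LabelVolume

__all__ = [
    "MorphometryResult",
    "ThicknessMap",
    "MILResult",
    "DegenerateStructureError",
    "bone_volume",
    "bone_surface",
    "local_thickness",
    "trabecular_thickness",
    "structure_model_index",
    "degree_of_anisotropy",
    "tissue_mineral_density",
    "bone_mineral_content",
    "analyse",
]


class DegenerateStructureError(ValueError):
    """Raised when a structure cannot support the requested measure."""


@dataclass
class MorphometryResult:
    """The seven-parameter panel for one specimen's compartment."""

    compartment: str
    bv_mm3: float
    tmd_mgHAcm3: float
    bmc_mg: float
    smi: float
    da: float
    bs_mm2: float
    tbth_mm: float

    def __post_init__(self) -> None:
        assert self.bv_mm3 >= 0 and self.bs_mm2 >= 0 and self.tbth_mm >= 0
        assert self.da >= 1.0

    def as_dict(self) -> dict:
        return {
            "compartment": self.compartment,
            "bv_mm3": self.bv_mm3,
            "tmd_mgHAcm3": self.tmd_mgHAcm3,
            "bmc_mg": self.bmc_mg,
            "smi": self.smi,
            "da": self.da,
            "bs_mm2": self.bs_mm2,
            "tbth_mm": self.tbth_mm,
        }


@dataclass
class ThicknessMap:
    """Local thickness in mm over the compartment, 0 elsewhere."""

    data: np.ndarray
    voxel_size_um: float


@dataclass
class MILResult:
    """Mean-intercept-length fabric fit.

    ``eigenvalues`` belong to the quadratic-form tensor ``H`` with
    ``u' H u = 1 / MIL(u)**2``; ellipsoid axis lengths are
    ``1 / sqrt(eigenvalue)``, so the largest eigenvalue marks the shortest
    MIL direction.  ``anisotropy_axis`` is the unit vector of the
    structure's unique (most separated) eigen-direction.
    """

    da: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    anisotropy_axis: np.ndarray
    mil: np.ndarray
    directions: np.ndarray

    def __float__(self) -> float:
        return self.da


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {m.shape}")
    return m.astype(bool)


def bone_volume(mask, voxel_size_um: float) -> float:
    """Voxel count times voxel volume, in mm**3."""
    m = _as_mask(mask)
    return float(m.sum()) * (voxel_size_um * 1e-3) ** 3


def _smoothed_mesh_area(mask: np.ndarray, level: float, spacing: float, sigma: float = 1.0) -> float:
    field = ndimage.gaussian_filter(mask.astype(float), sigma, mode="reflect")
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=(spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def bone_surface(mask, voxel_size_um: float) -> float:
    """Triangulated surface area of the binary structure, in mm**2."""
    m = _as_mask(mask)
    if not m.any():
        raise DegenerateStructureError("empty mask has no surface")
    return _smoothed_mesh_area(m, 0.5, voxel_size_um * 1e-3)


def local_thickness(mask, voxel_size_um: float, r_step: float = 0.1) -> ThicknessMap:
    """Largest-inscribed-sphere local thickness map.

    The Euclidean distance transform gives each voxel's inscribed-sphere
    radius; radii are visited in descending order (binned at ``r_step``
    voxels) and each sphere paints its diameter onto the voxels it covers,
    so every voxel ends up with the diameter of the largest sphere that
    contains it.  Diameters follow the half-voxel boundary convention
    ``2 * EDT - 1`` voxels: a single isolated voxel reads one voxel size.
    """
    m = _as_mask(mask)
    if not m.any():
        raise DegenerateStructureError("empty mask has no thickness")
    dt = ndimage.distance_transform_edt(m)
    r_step = max(r_step, float(dt.max()) / 50.0)  # bound the number of passes
    out = np.zeros(m.shape)
    radii = np.unique(np.round(dt[m] / r_step))[::-1] * r_step
    for r in radii:
        if r <= 0:
            continue
        seeds = dt >= r - r_step / 2
        dist_to_seed = ndimage.distance_transform_edt(~seeds)
        covered = (dist_to_seed <= r) & m & (out == 0)
        out[covered] = 2.0 * r
    out[m & (out == 0)] = 2.0 * dt[m & (out == 0)]  # safety: stray uncovered voxels
    thickness_vox = np.where(m, np.maximum(out - 1.0, 1.0), 0.0)
    return ThicknessMap(thickness_vox * voxel_size_um * 1e-3, voxel_size_um)


def trabecular_thickness(tmap: ThicknessMap) -> float:
    """Mean local thickness over compartment voxels, in mm."""
    vals = tmap.data[tmap.data > 0]
    if vals.size == 0:
        raise DegenerateStructureError("thickness map is empty")
    return float(vals.mean())


def structure_model_index(
    mask, voxel_size_um: float = 1.0, delta: float = 1.25, sigma: float = 1.2
) -> float:
    """SMI = 6 * BV * S' / S**2 (dimensionless, voxel-size independent).

    ``S'`` is estimated by a central difference: the smoothed binary field
    behaves like the Gaussian CDF of the signed boundary distance, so
    meshing it at levels ``Phi(-delta/sigma)`` and ``Phi(+delta/sigma)``
    yields the surface displaced outward/inward by ``delta`` voxels, and
    curvature-induced level shifts cancel in the difference.  Volume is the
    voxel count.  Negative values indicate concave surfaces.
    """
    m = _as_mask(mask)
    if not m.any():
        raise DegenerateStructureError("empty mask")
    bv = float(m.sum())

    def _phi(x):
        return 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))

    try:
        s0 = _smoothed_mesh_area(m, 0.5, 1.0, sigma)
        s_out = _smoothed_mesh_area(m, _phi(-delta / sigma), 1.0, sigma)
        s_in = _smoothed_mesh_area(m, _phi(delta / sigma), 1.0, sigma)
    except (ValueError, RuntimeError) as exc:
        raise DegenerateStructureError(f"no measurable surface: {exc}") from exc
    if s0 <= 0:
        raise DegenerateStructureError("zero surface area")
    s_prime = (s_out - s_in) / (2.0 * delta)
    return float(6.0 * bv * s_prime / s0**2)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the upper hemisphere, (z, y, x) components."""
    i = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = (i + 0.5) / n
    theta = 2 * np.pi * i / golden
    s = np.sqrt(1 - z * z)
    return np.stack([z, s * np.sin(theta), s * np.cos(theta)], axis=1)


def degree_of_anisotropy(
    mask,
    n_directions: int = 64,
    n_lines_per_direction: int = 1600,
    seed: int = 0,
    step: float = 0.5,
) -> MILResult:
    """Mean-intercept-length anisotropy of a binary structure.

    For each of ``n_directions`` quasi-uniform directions a raster of
    parallel test lines is traced through the volume; MIL(u) is the total
    in-structure path length divided by the number of background-to-
    structure crossings.  A second-order fabric tensor is fitted by least
    squares on ``1 / MIL**2`` and DA is the ratio of longest to shortest
    ellipsoid axis (>= 1).  Deterministic for a given seed (line offsets
    are jittered to avoid lattice aliasing).
    """
    m = _as_mask(mask)
    if not m.any():
        raise DegenerateStructureError("empty mask")
    if n_directions < 30:
        raise ValueError("need at least 30 directions for a stable fabric fit")
    rng = np.random.default_rng(seed)
    shape = np.array(m.shape)
    center = (shape - 1) / 2.0
    half_diag = float(np.linalg.norm(shape)) / 2.0
    spacing = max(1.0, 2.0 * half_diag / np.sqrt(n_lines_per_direction))
    dirs = _fibonacci_hemisphere(n_directions)
    mils = np.empty(n_directions)
    for k, u in enumerate(dirs):
        helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = np.cross(u, helper)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        offs = np.arange(-half_diag, half_diag, spacing)
        o1, o2 = np.meshgrid(offs, offs, indexing="ij")
        o1 = o1.ravel() + rng.uniform(-spacing / 2, spacing / 2, o1.size)
        o2 = o2.ravel() + rng.uniform(-spacing / 2, spacing / 2, o2.size)
        starts = center + o1[:, None] * v + o2[:, None] * w
        ts = np.arange(-half_diag, half_diag, step)
        pts = starts[:, None, :] + ts[None, :, None] * u
        idx = np.rint(pts).astype(np.int64)
        valid = ((idx >= 0) & (idx < shape)).all(axis=-1)
        hits = np.zeros(valid.shape, dtype=bool)
        flat = idx[valid]
        hits[valid] = m[flat[:, 0], flat[:, 1], flat[:, 2]]
        crossings = int((hits[:, 1:] & ~hits[:, :-1]).sum())
        if crossings == 0:
            raise DegenerateStructureError(
                f"no phase crossings along direction {u}; structure is degenerate"
            )
        mils[k] = hits.sum() * step / crossings
    # least-squares fit of the symmetric tensor H with u'Hu = 1/MIL^2
    design = np.stack(
        [
            dirs[:, 0] ** 2,
            dirs[:, 1] ** 2,
            dirs[:, 2] ** 2,
            2 * dirs[:, 0] * dirs[:, 1],
            2 * dirs[:, 0] * dirs[:, 2],
            2 * dirs[:, 1] * dirs[:, 2],
        ],
        axis=1,
    )
    h, *_ = np.linalg.lstsq(design, 1.0 / mils**2, rcond=None)
    H = np.array([[h[0], h[3], h[4]], [h[3], h[1], h[5]], [h[4], h[5], h[2]]])
    eigenvalues, eigenvectors = np.linalg.eigh(H)
    if np.any(eigenvalues <= 0):
        raise DegenerateStructureError("fabric tensor is not positive definite")
    axes = 1.0 / np.sqrt(eigenvalues)
    da = float(axes.max() / axes.min())
    unique = int(np.argmax(np.abs(eigenvalues - np.median(eigenvalues))))
    return MILResult(
        da=da,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        anisotropy_axis=eigenvectors[:, unique],
        mil=mils,
        directions=dirs,
    )


def tissue_mineral_density(vol: GreyVolume, mask, peel_voxels: int = 2) -> float:
    """Mean calibrated density over the compartment after peeling.

    The mask is eroded ``peel_voxels`` times with the 6-connected
    structuring element before averaging, discarding the partial-volume
    surface layers.
    """
    if vol.value_kind != "density":
        raise ValueError("TMD requires a density-calibrated volume")
    m = _as_mask(mask)
    if m.shape != vol.shape:
        raise ValueError("mask and volume shapes differ")
    if peel_voxels > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        m = ndimage.binary_erosion(m, structure=structure, iterations=peel_voxels)
    if not m.any():
        raise DegenerateStructureError(
            f"compartment vanished after peeling {peel_voxels} voxel layer(s)"
        )
    return float(vol.data[m].mean())


def bone_mineral_content(bv_mm3: float, tmd_mgHAcm3: float) -> float:
    """BMC = BV * TMD / 1000 (mm**3 -> cm**3), in mg."""
    if bv_mm3 < 0 or tmd_mgHAcm3 < 0:
        raise ValueError("BV and TMD must be non-negative")
    return bv_mm3 * tmd_mgHAcm3 / 1000.0


_COMPARTMENTS = ("callus", "cortex", "bone")


def compartment_mask(labels: LabelVolume, compartment: str = "callus") -> np.ndarray:
    if compartment == "callus":
        return labels.mask(LABEL_CALLUS)
    if compartment == "cortex":
        return labels.mask(LABEL_CORTEX)
    if compartment == "bone":
        return labels.mask(LABEL_CALLUS) | labels.mask(LABEL_CORTEX)
    raise ValueError(f"compartment must be one of {_COMPARTMENTS}, got {compartment!r}")


def analyse(
    vol: GreyVolume,
    labels: LabelVolume,
    calib=None,
    compartment: str = "callus",
    peel_voxels: int = 2,
    da_directions: int = 64,
    da_seed: int = 0,
    thickness_map_out: Optional[list] = None,
) -> MorphometryResult:
    """Assemble the full seven-parameter panel for one compartment.

    ``vol`` may be raw grey (then ``calib`` is required for TMD/BMC) or
    already density-calibrated.  Pass a list as ``thickness_map_out`` to
    also receive the local thickness map (appended).
    """
    from .volume_io import calibrate_density  # local import to avoid cycle noise

    if vol.shape != labels.shape:
        raise ValueError("volume and label shapes differ")
    mask = compartment_mask(labels, compartment)
    if not mask.any():
        raise DegenerateStructureError(f"compartment {compartment!r} contains no voxels")
    if vol.value_kind == "grey":
        if calib is None:
            raise ValueError("density calibration required for a raw grey volume")
        dens = calibrate_density(vol, calib)
    else:
        dens = vol
    bv = bone_volume(mask, vol.voxel_size_um)
    bs = bone_surface(mask, vol.voxel_size_um)
    tmap = local_thickness(mask, vol.voxel_size_um)
    tbth = trabecular_thickness(tmap)
    smi = structure_model_index(mask, vol.voxel_size_um)
    mil = degree_of_anisotropy(mask, n_directions=da_directions, seed=da_seed)
    tmd = tissue_mineral_density(dens, mask, peel_voxels=peel_voxels)
    bmc = bone_mineral_content(bv, tmd)
    if thickness_map_out is not None:
        thickness_map_out.append(tmap)
    return MorphometryResult(
        compartment=compartment,
        bv_mm3=bv,
        tmd_mgHAcm3=tmd,
        bmc_mg=bmc,
        smi=smi,
        da=mil.da,
        bs_mm2=bs,
        tbth_mm=tbth,
    )
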