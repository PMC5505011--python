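"""Synthetic test volumes: digitized primitives and a fractured-femur phantom.

The fracture phantom emulates a mid-diaphyseal comminuted fracture scanned
at 10 um: a hollow cortical cylinder along z interrupted by a transverse
fracture gap, displaced cortical wedge fragments inside the gap, a
periosteal callus collar and optional endosteal callus rendered as a
trabecular network, an optional intramedullary wire, and additive Gaussian
noise.  Grey plateaus (marrow < callus < cortex) straddle the default
segmentation thresholds, producing the characteristic trimodal histogram
of fractured specimens; the returned label volume is the noise-free
ground-truth region assignment.

Default geometry is a scaled rat mid-diaphysis fitting a 2.56 mm
field of view: cortical outer radius 0.62 mm, wall 0.18 mm, callus collar
0.50 mm, fracture gap 0.5 mm, three wedge fragments.  The trabecular
texture correlation length is set so the callus local thickness is near
0.1 mm, the magnitude reported for 21-day rat callus.

Primitives (sphere, rod, plate, plate stack, two spheres) are digitized on
integer-centred lattices; rods and plates extend through the volume
boundary so that open-surface meshing treats them as effectively infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume_io import (
    LABEL_BACKGROUND,
    LABEL_CALLUS,
    LABEL_CORTEX,
    GreyVolume,
    LabelVolume,
)

__all__ = ["PhantomSpec", "make_primitive", "make_fracture_phantom"]


@dataclass
class PhantomSpec:
    """Parameters of the comminuted-fracture phantom (all lengths in mm)."""

    shape_vox: Tuple[int, int, int] = (256, 256, 256)
    voxel_size_um: float = 10.0
    cortex_outer_radius_mm: float = 0.62
    cortex_inner_radius_mm: float = 0.44
    gap_halfwidth_mm: float = 0.25
    n_fragments: int = 3
    fragment_displacement_mm: float = 0.12
    callus_collar_thickness_mm: float = 0.50
    callus_fill_fraction: float = 0.5
    texture_corr_length_mm: float = 0.05
    include_endosteal_callus: bool = True
    include_wire: bool = False
    wire_radius_mm: float = 0.15
    grey_levels: Tuple[float, float, float, float] = (50.0, 250.0, 600.0, 900.0)
    noise_sd: float = 30.0
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.cortex_inner_radius_mm < self.cortex_outer_radius_mm:
            raise ValueError("inner cortical radius must lie below the outer radius")
        marrow, callus, cortex, _wire = self.grey_levels
        if not marrow < callus < cortex:
            raise ValueError("grey levels must increase marrow < callus < cortex")
        if not 0 < self.callus_fill_fraction <= 1:
            raise ValueError("callus_fill_fraction must be in (0, 1]")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")

    @property
    def voxel_mm(self) -> float:
        return self.voxel_size_um * 1e-3


def make_primitive(
    kind: str,
    dims,
    shape_vox: Tuple[int, int, int],
    voxel_size_um: float,
) -> np.ndarray:
    """Voxel-centre digitization of an analytic solid.

    ``dims`` (mm): ``sphere`` diameter; ``rod`` diameter (axis z, through
    the volume); ``plate`` thickness (normal z, through x/y); ``plate_stack``
    (thickness, period); ``two_spheres`` (diameter, centre separation,
    along z).  Interior primitives must fit with a two-voxel margin.
    """
    nz, ny, nx = shape_vox
    vox = voxel_size_um * 1e-3
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    z, y, x = np.ogrid[:nz, :ny, :nx]
    dims = np.atleast_1d(np.asarray(dims, dtype=float))

    if kind == "sphere":
        r = dims[0] / 2 / vox
        if r + 2 > min(cz, cy, cx):
            raise ValueError("sphere does not fit with a 2-voxel margin")
        return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r

    if kind == "rod":
        r = dims[0] / 2 / vox
        if r + 2 > min(cy, cx):
            raise ValueError("rod cross-section does not fit with a 2-voxel margin")
        return np.broadcast_to((y - cy) ** 2 + (x - cx) ** 2 <= r * r, (nz, ny, nx)).copy()

    if kind == "plate":
        t = dims[0] / vox
        if t / 2 + 2 > cz:
            raise ValueError("plate does not fit with a 2-voxel margin")
        half = (t - 1) / 2  # t voxels centred on cz
        return np.broadcast_to(np.abs(z - cz) <= half, (nz, ny, nx)).copy()

    if kind == "plate_stack":
        t, period = dims[0] / vox, dims[1] / vox
        if period <= t:
            raise ValueError("plate period must exceed plate thickness")
        phase = (z - cz) % period
        return np.broadcast_to(phase < t, (nz, ny, nx)).copy()

    if kind == "two_spheres":
        d, sep = dims[0], dims[1]
        r = d / 2 / vox
        off = sep / 2 / vox
        if off + r + 2 > cz or r + 2 > min(cy, cx):
            raise ValueError("two_spheres does not fit with a 2-voxel margin")
        c1, c2 = cz - off, cz + off
        return ((z - c1) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r) | (
            (z - c2) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r
        )

    raise ValueError(f"unknown primitive kind {kind!r}")


def _trabecular_field(shape, corr_len_vox: float, rng) -> np.ndarray:
    """Smoothed Gaussian random field; thresholding it yields strut networks."""
    f = rng.standard_normal(shape).astype(np.float32)
    return ndimage.gaussian_filter(f, corr_len_vox)


def make_fracture_phantom(spec: PhantomSpec):
    """Generate ``(GreyVolume, LabelVolume)`` for the comminuted-fracture model.

    Deterministic for a given ``spec.seed``.  The label volume is the
    noise-free region assignment; the wire, when present, is merged into
    the cortical-bone class (it thresholds like dense bone).
    """
    nz, ny, nx = spec.shape_vox
    vox = spec.voxel_mm
    rng = np.random.default_rng(spec.seed)
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2

    outer_r = spec.cortex_outer_radius_mm / vox
    inner_r = spec.cortex_inner_radius_mm / vox
    collar = spec.callus_collar_thickness_mm / vox
    gap_half = spec.gap_halfwidth_mm / vox
    if outer_r + collar + 2 > min(cy, cx):
        raise ValueError("cortex plus callus collar does not fit inside the grid")

    z, y, x = np.ogrid[:nz, :ny, :nx]
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    ring = (rad <= outer_r) & (rad >= inner_r)
    in_gap = np.abs(z - cz) <= gap_half
    cortex = ring & ~in_gap

    # wedge fragments of the cortical ring, rigidly displaced, inside the gap
    for _ in range(spec.n_fragments):
        th0 = rng.uniform(-np.pi, np.pi)
        width = rng.uniform(0.5, 1.0)
        length = rng.uniform(0.5, 0.9) * 2 * gap_half
        zc = cz + rng.uniform(-1, 1) * (gap_half - length / 2 - 1)
        disp = spec.fragment_displacement_mm / vox
        dy = disp * np.sin(th0 + width / 2)
        dx = disp * np.cos(th0 + width / 2)
        rad_s = np.sqrt((y - cy - dy) ** 2 + (x - cx - dx) ** 2)
        theta_s = np.arctan2(y - cy - dy, x - cx - dx) + 0 * z
        dtheta = (theta_s - th0) % (2 * np.pi)
        cortex |= (
            (rad_s <= outer_r)
            & (rad_s >= inner_r)
            & (dtheta <= width)
            & (np.abs(z - zc) <= length / 2)
        )

    wire = np.zeros((nz, ny, nx), dtype=bool)
    if spec.include_wire:
        wire = (rad <= spec.wire_radius_mm / vox) & ~cortex
        wire = np.broadcast_to(wire, (nz, ny, nx)) if wire.ndim < 3 else wire

    # candidate callus space: periosteal collar, fracture gap, optional canal
    callus_region = (rad > outer_r) & (rad <= outer_r + collar)
    callus_region = callus_region | ((rad <= outer_r) & in_gap)
    if spec.include_endosteal_callus:
        callus_region = callus_region | (rad < inner_r)
    callus_region = np.broadcast_to(callus_region, (nz, ny, nx)) & ~cortex & ~wire

    field = _trabecular_field((nz, ny, nx), spec.texture_corr_length_mm / vox, rng)
    threshold = np.quantile(field, 1.0 - spec.callus_fill_fraction)
    callus = callus_region & (field >= threshold)

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[callus] = LABEL_CALLUS
    labels[cortex | wire] = LABEL_CORTEX

    marrow_g, callus_g, cortex_g, wire_g = spec.grey_levels
    grey = np.full((nz, ny, nx), marrow_g, dtype=np.float32)
    grey[callus] = callus_g
    grey[cortex] = cortex_g
    grey[wire] = wire_g
    if spec.noise_sd > 0:
        grey += rng.normal(0.0, spec.noise_sd, grey.shape).astype(np.float32)

    return (
        GreyVolume(grey, spec.voxel_size_um),
        LabelVolume(labels, spec.voxel_size_um),
    )
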