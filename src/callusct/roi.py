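"""Cylindrical volume of interest from two end-slice circles.

The VOI is drawn once on the first and once on the last slice as a circle
wide enough to enclose the bone; circles for every intermediate slice are
obtained by linear interpolation of centre coordinates and radius.  The
contour does not need to hug the bone surface: every downstream statistic
is restricted to voxels inside the VOI, and the panel contains no
volume-dependent quantity that the enclosed air would dilute.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .volume_io import GreyVolume

__all__ = ["Circle", "CylinderRoi", "apply_roi"]


@dataclass(frozen=True)
class Circle:
    """Circle on one slice: centre (row, col) in voxel coordinates, radius in voxels."""

    center: tuple
    radius: float

    def __post_init__(self) -> None:
        if len(self.center) != 2:
            raise ValueError("center must be (row, col)")
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class CylinderRoi:
    """Linearly interpolated stack of circles spanning ``n_slices`` slices."""

    first: Circle
    last: Circle
    n_slices: int

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("a cylinder ROI needs at least 2 slices")

    def circle_at(self, z: int) -> Circle:
        """Circle on slice ``z``; exact at both endpoints, affine in between."""
        if not 0 <= z < self.n_slices:
            raise IndexError(f"slice {z} outside [0, {self.n_slices})")
        t = z / (self.n_slices - 1)
        r0, c0 = self.first.center
        r1, c1 = self.last.center
        return Circle(
            center=((1 - t) * r0 + t * r1, (1 - t) * c0 + t * c1),
            radius=(1 - t) * self.first.radius + t * self.last.radius,
        )

    def mask(self, shape) -> np.ndarray:
        """Boolean inside-mask for a volume of the given (z, y, x) shape.

        A voxel belongs to the VOI iff its centre lies within (<=) the
        slice's circle.
        """
        nz, ny, nx = shape
        if nz != self.n_slices:
            raise ValueError(f"ROI spans {self.n_slices} slices but volume has {nz}")
        rows = np.arange(ny)[:, None]
        cols = np.arange(nx)[None, :]
        t = np.arange(nz) / (nz - 1)
        r0, c0 = self.first.center
        r1, c1 = self.last.center
        centers_r = (1 - t) * r0 + t * r1
        centers_c = (1 - t) * c0 + t * c1
        radii = (1 - t) * self.first.radius + t * self.last.radius
        out = np.empty((nz, ny, nx), dtype=bool)
        for z in range(nz):
            out[z] = (rows - centers_r[z]) ** 2 + (cols - centers_c[z]) ** 2 <= radii[z] ** 2
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "CylinderRoi":
        d = json.loads(Path(path).read_text())
        return cls(
            first=Circle(tuple(d["first"]["center"]), d["first"]["radius"]),
            last=Circle(tuple(d["last"]["center"]), d["last"]["radius"]),
            n_slices=d["n_slices"],
        )


def apply_roi(vol: GreyVolume, roi: CylinderRoi):
    """Return the volume together with its boolean inside-mask.

    Grey values are not altered; callers restrict histograms, segmentation
    and morphometry to the mask.
    """
    inside = roi.mask(vol.shape)
    return vol, inside
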