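"""Fully automated three-class segmentation of fractured bone.

The classifier separates original cortical bone, mineralised callus and
marrow/air in one pass over the whole volume, with no per-structure
contouring.  Two independently filtered copies of the grey volume are
thresholded globally:

* cortical bone: truncated Gaussian, sigma 1.5 voxels, support 3,
  threshold 370 grey values;
* callus: sigma 0.8, support 1, threshold 150.

A voxel at or above the cortical threshold is cortical bone regardless of
the callus test (cortex precedence); otherwise at or above the callus
threshold it is callus; the remainder is background.  Voxels outside the
cylindrical VOI receive the sentinel code 255.

The grey histogram of in-VOI voxels is trimodal on fractured specimens —
marrow/air peak, callus plateau, cortical maximum — and drives an optional
valley-detection routine that proposes the two thresholds automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import CylinderRoi
from .volume_io import (
    LABEL_BACKGROUND,
    LABEL_CALLUS,
    LABEL_CORTEX,
    LABEL_OUTSIDE,
    GreyVolume,
    LabelVolume,
)

__all__ = [
    "FilterParams",
    "CALLUS_DEFAULTS",
    "CORTEX_DEFAULTS",
    "Histogram",
    "constrained_gaussian_filter",
    "segment_three_class",
    "grey_histogram",
    "suggest_thresholds",
]


@dataclass(frozen=True)
class FilterParams:
    """Gaussian pre-filter and global threshold for one tissue class.

    ``support`` is the kernel truncation radius in voxels (kernel width
    ``2 * support + 1``); the truncated kernel is renormalised to unit sum.
    """

    sigma: float
    support: int
    threshold: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.support < 0 or int(self.support) != self.support:
            raise ValueError(f"support must be a non-negative integer, got {self.support}")


CALLUS_DEFAULTS = FilterParams(sigma=0.8, support=1, threshold=150)
CORTEX_DEFAULTS = FilterParams(sigma=1.5, support=3, threshold=370)


@dataclass(frozen=True)
class Histogram:
    """Relative-frequency histogram over in-VOI voxels (frequencies sum to 1)."""

    bin_edges: np.ndarray
    frequencies: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"bin_center": self.bin_centers, "rel_freq": self.frequencies}
        ).to_csv(path, index=False)


def _kernel_1d(sigma: float, support: int) -> np.ndarray:
    i = np.arange(-support, support + 1, dtype=float)
    if sigma == 0:
        k = (i == 0).astype(float)
    else:
        k = np.exp(-(i * i) / (2.0 * sigma * sigma))
    return k / k.sum()


def constrained_gaussian_filter(vol, sigma: float, support: int):
    """Separable truncated-Gaussian smoothing with mirror boundaries.

    The 1D kernel is cut off at ``support`` voxels and renormalised, so
    support 0 (or sigma 0) is the identity and constants are preserved
    exactly.  Accepts a :class:`GreyVolume` or a bare array; returns the
    same kind.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if support < 0 or int(support) != support:
        raise ValueError(f"support must be a non-negative integer, got {support}")
    data = vol.data if isinstance(vol, GreyVolume) else np.asarray(vol)
    out = data.astype(float, copy=True)
    if support > 0 and sigma > 0:
        k = _kernel_1d(sigma, int(support))
        for ax in range(out.ndim):
            out = ndimage.correlate1d(out, k, axis=ax, mode="mirror")
    if isinstance(vol, GreyVolume):
        return GreyVolume(out, vol.voxel_size_um, vol.value_kind)
    return out


def segment_three_class(
    vol: GreyVolume,
    callus: FilterParams = CALLUS_DEFAULTS,
    cortex: FilterParams = CORTEX_DEFAULTS,
    roi: Optional[CylinderRoi] = None,
) -> LabelVolume:
    """Two-filter, dual-threshold classification into {background, callus, cortex}.

    Each tissue is detected on its own filtered copy of the volume with a
    ``>=`` threshold comparison; cortex takes precedence where both fire.
    With a ROI, voxels outside it are coded 255 and ignored.
    """
    if not callus.threshold < cortex.threshold:
        raise ValueError(
            f"callus threshold ({callus.threshold}) must lie below "
            f"cortex threshold ({cortex.threshold})"
        )
    f_cal = constrained_gaussian_filter(vol.data, callus.sigma, callus.support)
    f_cor = constrained_gaussian_filter(vol.data, cortex.sigma, cortex.support)
    labels = np.zeros(vol.shape, dtype=np.uint8)
    labels[f_cal >= callus.threshold] = LABEL_CALLUS
    labels[f_cor >= cortex.threshold] = LABEL_CORTEX
    if roi is not None:
        inside = roi.mask(vol.shape)
        labels[~inside] = LABEL_OUTSIDE
    return LabelVolume(labels, vol.voxel_size_um)


def grey_histogram(
    vol: GreyVolume,
    roi: Optional[CylinderRoi] = None,
    n_bins: int = 256,
) -> Histogram:
    """Relative-frequency histogram of raw in-VOI grey (or density) values."""
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    values = vol.data[roi.mask(vol.shape)] if roi is not None else vol.data.ravel()
    if values.size == 0:
        raise ValueError("empty ROI: no voxels to histogram")
    counts, edges = np.histogram(values, bins=n_bins)
    return Histogram(bin_edges=edges, frequencies=counts / counts.sum())


def suggest_thresholds(hist: Histogram, smoothing: int = 5):
    """Propose (t_low, t_high) from the valleys of a trimodal histogram.

    The frequency profile is smoothed by a moving average over ``smoothing``
    bins, its three tallest local maxima are located, and each threshold is
    the minimum-frequency bin centre between consecutive modes.  Returns
    ``None`` when fewer than three modes are detectable, in which case the
    caller falls back to the defaults (150, 370).
    """
    f = hist.frequencies.astype(float)
    if smoothing > 1:
        k = np.ones(int(smoothing)) / int(smoothing)
        f = np.convolve(f, k, mode="same")
    interior = (f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:])
    peaks = np.where(interior)[0] + 1
    if f[0] > f[1]:
        peaks = np.concatenate([[0], peaks])
    if f[-1] > f[-2]:
        peaks = np.concatenate([peaks, [len(f) - 1]])
    if len(peaks) < 3:
        return None
    top3 = np.sort(peaks[np.argsort(f[peaks])[-3:]])
    centers = hist.bin_centers
    thresholds = []
    for a, b in zip(top3[:-1], top3[1:]):
        valley = a + int(np.argmin(f[a : b + 1]))
        thresholds.append(float(centers[valley]))
    return tuple(thresholds)
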