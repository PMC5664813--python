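"""Grain segmentation from reconstructed µCT volumes.

Dried grain is markedly denser than the surrounding air, holder plastic
and chaff, so a scan's pooled grey-value histogram is bimodal: a large
low-density mode (background) and a high-density mode (plant material).
Segmentation proceeds as a fixed chain:

1. adaptive threshold at the histogram valley between the two modes,
2. binarization,
3. morphological cleanup (slice-wise disk erosion, 3D median filter,
   slice-wise disk dilation),
4. removal of the largest connected component (the holder tube),
5. minimum-object-size filtering,
6. masking the original grey volume so grain voxels keep their exact
   recorded grey values.

All component labelling uses 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import disk

from .errors import (
    EmptyMaskError,
    NoBimodalityError,
    ParameterError,
    StageError,
)
from .volume_io import Volume

__all__ = [
    "ThresholdResult",
    "BinaryMask",
    "SegmentationParams",
    "compute_threshold",
    "find_bimodal_valley",
    "binarize",
    "morphological_cleanup",
    "remove_largest_component",
    "filter_small_objects",
    "mask_original",
    "segment_spike",
    "CONNECTIVITY_STRUCTURE",
]

#: 26-connectivity structuring element used for all 3D labelling.
CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ThresholdResult:
    """Outcome of the adaptive bimodal threshold.

    ``grain_threshold`` is the grey value at the deepest valley between
    the two dominant smoothed histogram modes; voxels at or above it are
    candidate plant material.
    """

    grain_threshold: int
    histogram: np.ndarray
    mode_lo: int
    mode_hi: int

    def __post_init__(self):
        if not (self.mode_lo < self.grain_threshold < self.mode_hi):
            raise ParameterError(
                f"threshold {self.grain_threshold} not between modes "
                f"({self.mode_lo}, {self.mode_hi})"
            )


@dataclass
class BinaryMask:
    """A boolean voxel mask with the shape of its source volume."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.dtype != bool:
            raise ParameterError("mask must be a 3D boolean array")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    ``se_radius`` is the disk structuring-element radius (pixels),
    ``min_object_size`` the minimum kept component size (voxels) and
    ``median_radius`` the half-width of the cubic median window.
    ``histogram_smooth_bins`` is the moving-average width applied to the
    pooled 65536-bin histogram before valley detection.
    """

    se_radius: int = 5
    min_object_size: int = 1000
    median_radius: int = 2
    histogram_smooth_bins: int = 257

    def __post_init__(self):
        for name in ("se_radius", "min_object_size", "median_radius"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.histogram_smooth_bins < 1:
            raise ParameterError("histogram_smooth_bins must be >= 1")


def compute_threshold(
    volume: Volume, smooth_bins: int = 257
) -> ThresholdResult:
    """Find the grain threshold from the pooled grey-value histogram.

    Per-slice histograms are pooled into one scan-level 65536-bin
    histogram, smoothed with a moving average of ``smooth_bins`` bins,
    and the threshold is placed at the deepest valley between the two
    highest smoothed peaks (midpoint of the minimal plateau when the
    valley is flat). Raises :class:`NoBimodalityError` when fewer than
    two modes are present, which signals an unusable scan.
    """
    hist = np.bincount(volume.data.ravel(), minlength=65536).astype(np.float64)
    valley, mode_lo, mode_hi = find_bimodal_valley(hist, smooth_bins)
    return ThresholdResult(
        grain_threshold=valley,
        histogram=hist,
        mode_lo=mode_lo,
        mode_hi=mode_hi,
    )


def find_bimodal_valley(hist: np.ndarray, smooth_bins: int = 257):
    """Valley of a bimodal grey-value histogram.

    Smooths ``hist`` with a ``smooth_bins``-wide moving average, locates
    the two highest peaks (separated by at least the smoothing width)
    and returns ``(valley, mode_lo, mode_hi)`` where valley is the bin
    of the deepest minimum between them — midpoint of the minimal
    plateau when flat. Raises :class:`NoBimodalityError` when fewer than
    two modes exist.
    """
    hist = np.asarray(hist, dtype=np.float64)
    smoothed = ndimage.uniform_filter1d(hist, size=smooth_bins, mode="constant")
    if smoothed.max() <= 0:
        raise NoBimodalityError("empty histogram")
    # modes must be separated by at least the smoothing width and carry a
    # non-negligible prominence; this rejects noise wiggles on the flanks
    # of the dominant background mode
    peaks, _ = find_peaks(
        smoothed, distance=max(smooth_bins, 2), prominence=smoothed.max() * 0.01
    )
    if len(peaks) < 2:
        raise NoBimodalityError(
            f"found {len(peaks)} histogram mode(s); need 2 (constant or "
            "unimodal scan)"
        )
    # the dominant mode is the background; the plant-material mode is the
    # topmost significant mode. Intermediate low-density modes (rachis,
    # chaff) may exist, so the grain threshold is placed in the deepest
    # valley directly below the plant mode — between it and its nearest
    # significant neighbour.
    mode_lo = int(peaks[np.argmax(smoothed[peaks])])
    mode_hi = int(peaks[-1])
    if mode_lo >= mode_hi:  # dominant mode is topmost: plain two-mode case
        order = np.argsort(smoothed[peaks])[::-1]
        p1, p2 = peaks[order[0]], peaks[order[1]]
        mode_lo, mode_hi = int(min(p1, p2)), int(max(p1, p2))
    left = int(peaks[peaks < mode_hi][-1])
    between = smoothed[left + 1 : mode_hi]
    if between.size == 0:
        raise NoBimodalityError("modes are adjacent; no valley exists")
    vmin = between.min()
    if vmin >= min(smoothed[left], smoothed[mode_hi]):
        raise NoBimodalityError("no valley between histogram modes")
    flat = np.flatnonzero(between == vmin)
    valley = left + 1 + int(flat[(len(flat) - 1) // 2])
    return valley, mode_lo, mode_hi


def binarize(volume: Volume, t: int) -> BinaryMask:
    """Threshold a volume: true where grey value >= ``t``."""
    if not 0 < t < 65535:
        raise ParameterError(f"threshold must be in (0, 65535), got {t}")
    return BinaryMask(volume.data >= t)


def _disk_se(radius: int) -> np.ndarray:
    """Slice-wise disk: a 2D disk applied independently to each z-slice."""
    return disk(radius)[None, :, :].astype(bool)


def morphological_cleanup(
    mask: BinaryMask, params: SegmentationParams
) -> BinaryMask:
    """Erode with a disk SE, median-filter, dilate with the same SE.

    The disk is a 2D structuring element applied per z-slice (the scan
    is a stack of reconstructed slices); the median filter is a 3D cube
    of edge ``2 * median_radius + 1``, realized as a majority vote.
    Specks smaller than the structuring element do not survive.
    """
    se = _disk_se(params.se_radius)
    if se.shape[1] > mask.shape[1] or se.shape[2] > mask.shape[2]:
        raise ParameterError(
            f"structuring element {se.shape[1:]} exceeds mask extents "
            f"{mask.shape[1:]}"
        )
    eroded = ndimage.binary_erosion(mask.data, structure=se)
    # median of a binary image == majority vote; the window has an odd
    # voxel count so no ties can occur
    win = 2 * params.median_radius + 1
    frac = ndimage.uniform_filter(eroded.astype(np.float32), size=win)
    median = frac > 0.5
    dilated = ndimage.binary_dilation(median, structure=se)
    return BinaryMask(dilated)


def _label(mask_data: np.ndarray):
    return ndimage.label(mask_data, structure=CONNECTIVITY_STRUCTURE)


def remove_largest_component(mask: BinaryMask) -> BinaryMask:
    """Remove the largest 26-connected component (the holder tube).

    Ties on voxel count are broken by lowest minimum z slice, then by
    label order, so the choice is deterministic. An empty mask raises
    :class:`EmptyMaskError`; a single-component mask returns all-false
    (callers that cannot assume a holder should guard, as
    :func:`segment_spike` does).
    """
    labels, n = _label(mask.data)
    if n == 0:
        raise EmptyMaskError("cannot remove largest component of empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    max_size = sizes.max()
    candidates = np.flatnonzero(sizes == max_size) + 1
    if len(candidates) > 1:
        slices = ndimage.find_objects(labels)
        min_z = [slices[c - 1][0].start for c in candidates]
        candidates = candidates[np.lexsort((candidates, min_z))]
    target = candidates[0]
    return BinaryMask(mask.data & (labels != target))


def filter_small_objects(mask: BinaryMask, min_size: int) -> BinaryMask:
    """Drop 26-connected components with fewer than ``min_size`` voxels.

    The bound is inclusive: a component of exactly ``min_size`` voxels
    is kept.
    """
    if min_size < 1:
        raise ParameterError(f"min_size must be >= 1, got {min_size}")
    labels, n = _label(mask.data)
    if n == 0:
        return BinaryMask(mask.data.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return BinaryMask(keep[labels])


def mask_original(volume: Volume, mask: BinaryMask) -> Volume:
    """Apply a binary mask to the original grey volume.

    Inside the mask the output grey values are bit-identical to the
    input (no data loss); outside they are zero.
    """
    if volume.shape != mask.shape:
        raise ParameterError(
            f"shape mismatch: volume {volume.shape} vs mask {mask.shape}"
        )
    return Volume(np.where(mask.data, volume.data, 0).astype(np.uint16), volume.meta)


#: Largest-to-second-largest component ratio above which a holder tube is
#: assumed present and removed.
TUBE_DOMINANCE_RATIO = 4.0


def segment_spike(
    volume: Volume, params: SegmentationParams | None = None
) -> tuple[Volume, BinaryMask, ThresholdResult]:
    """Run the full segmentation chain on one scan.

    Returns the masked grey volume, the final binary mask and the
    threshold record. Tube removal is skipped when the largest connected
    component is less than four times the second largest (no dominant
    holder structure, e.g. cropped scans); stage failures are re-raised
    as :class:`StageError` with the stage name attached.
    """
    params = params or SegmentationParams()

    def run(stage, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    thr = run("threshold", compute_threshold, volume, params.histogram_smooth_bins)
    mask = run("binarize", binarize, volume, thr.grain_threshold)
    mask = run("cleanup", morphological_cleanup, mask, params)

    labels, n = _label(mask.data)
    if n >= 2:
        sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
        if sizes[0] >= TUBE_DOMINANCE_RATIO * sizes[1]:
            mask = run("tube_removal", remove_largest_component, mask)
    mask = run("size_filter", filter_small_objects, mask, params.min_object_size)
    masked = run("masking", mask_original, volume, mask)
    return masked, mask, thr
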