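"""Spike-level processing.

The rachis (the spike's central axis) is less dense than grain and is
invisible at the grain threshold; it is recovered by relaxing the
threshold by 20%, which defines the spike's vertical extent and hence
its height. Spikes too tall for the scanner holder are scanned in two
portions and rejoined in silico: per-portion z positions are optionally
inverted (``Z = max(Z) - Zi`` for portions acquired tip-down) and the
top portion is shifted globally by the bottom portion's slice count.

Grains are finally binned into bottom / middle / top regions of the
spike: with p the grain centroid's normalized position along the rachis
extent, the middle is p in [0.5 - h, 0.5 + h] (inclusive, default
h = 0.16), below is bottom, above is top.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NoMaterialError, ParameterError, PortionMismatchError
from .morphometry import GrainRecord, to_mm
from .segmentation import (
    CONNECTIVITY_STRUCTURE,
    SegmentationParams,
    ThresholdResult,
    binarize,
    morphological_cleanup,
    remove_largest_component,
    _label,
    TUBE_DOMINANCE_RATIO,
)
from .volume_io import ScanMeta, Volume

__all__ = [
    "RachisExtent",
    "SpikeRecord",
    "SpikeConfig",
    "Portion",
    "detect_rachis_extent",
    "spike_height",
    "rejoin_portions",
    "assign_regions",
    "summarize_spike",
]

logger = logging.getLogger(__name__)

REGIONS = ("bottom", "middle", "top")


@dataclass(frozen=True)
class RachisExtent:
    """Lowest and highest z slices containing (relaxed-threshold) material."""

    z_low: int
    z_high: int
    relaxed_threshold: int

    def __post_init__(self):
        if self.z_low > self.z_high:
            raise ParameterError("z_low must be <= z_high")


@dataclass
class SpikeRecord:
    """Per-spike aggregate traits."""

    spike_id: str
    height_mm: float
    n_grains: int
    total_grain_volume_mm3: float
    region_counts: dict
    region_mean_volume_mm3: dict
    portions_joined: int = 1


@dataclass(frozen=True)
class SpikeConfig:
    """Spike-level configuration.

    ``region_half_width`` is the half-width of the middle region as a
    fraction of spike height; ``rachis_relax_fraction`` the fractional
    threshold relaxation used to pick up rachis material; the invert
    flags state which scan portions were acquired tip-down and must be
    z-inverted before rejoining.
    """

    region_half_width: float = 0.16
    rachis_relax_fraction: float = 0.20
    invert_top: bool = True
    invert_bottom: bool = False

    def __post_init__(self):
        if not 0 < self.region_half_width < 0.5:
            raise ParameterError("region_half_width must be in (0, 0.5)")
        if not 0 < self.rachis_relax_fraction < 1:
            raise ParameterError("rachis_relax_fraction must be in (0, 1)")


@dataclass
class Portion:
    """One scanned portion of a spike, ready for rejoining."""

    records: list
    n_slices: int
    meta: ScanMeta
    invert: bool = False


def detect_rachis_extent(
    volume: Volume,
    thr: ThresholdResult,
    params: SegmentationParams | None = None,
    relax_fraction: float = 0.20,
) -> RachisExtent:
    """Locate the lowest and highest rachis slices.

    The grain threshold is relaxed by ``relax_fraction`` (default 20%)
    so the less dense rachis becomes visible; after the usual cleanup
    and holder-tube removal, the z range of remaining material defines
    the beginning and end of the spike.
    """
    params = params or SegmentationParams()
    relaxed = int(round((1.0 - relax_fraction) * thr.grain_threshold))
    if relaxed < 1:
        raise ParameterError("relaxed threshold fell below 1")
    mask = binarize(volume, relaxed)
    if not mask.data.any():
        raise NoMaterialError("no voxels above the relaxed threshold")
    mask = morphological_cleanup(mask, params)
    # The holder tube is identified at the full grain threshold, where
    # the rachis is invisible and the tube dominates every other
    # component; its voxels (slightly padded) are then subtracted from
    # the relaxed-threshold mask. Identifying the tube at the relaxed
    # threshold instead would risk confusing it with the rachis itself.
    full = morphological_cleanup(binarize(volume, thr.grain_threshold), params)
    labels, n = _label(full.data)
    if n >= 2:
        sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
        if sizes[0] >= TUBE_DOMINANCE_RATIO * sizes[1]:
            tube = full.data & ~remove_largest_component(full).data
            tube = ndimage.binary_dilation(tube, CONNECTIVITY_STRUCTURE)
            mask.data &= ~tube
    z_any = np.flatnonzero(mask.data.any(axis=(1, 2)))
    if z_any.size == 0:
        raise NoMaterialError("no material left after cleanup at relaxed threshold")
    return RachisExtent(
        z_low=int(z_any[0]), z_high=int(z_any[-1]), relaxed_threshold=relaxed
    )


def spike_height(extent: RachisExtent, meta: ScanMeta) -> float:
    """Spike height in mm: slice span times voxel pitch."""
    return to_mm(extent.z_high - extent.z_low + 1, meta.voxel_pitch_um)


def _transform_record(rec: GrainRecord, n_slices: int, invert: bool,
                      offset: int, pitch_um: float) -> GrainRecord:
    out = copy.deepcopy(rec)
    x, y, z = out.centroid_vox
    if invert:
        z = (n_slices - 1) - z
    z = z + offset
    out.centroid_vox = (x, y, z)
    out.z_mm = to_mm(z, pitch_um)
    return out


def rejoin_portions(*portions: Portion) -> list:
    """Rejoin grain records from split-spike portions into global z.

    Portions are given in bottom-to-top order (two in the common case;
    more are handled by sequential offsetting). Within each portion z is
    first re-oriented by ``Z = (n_slices - 1) - Zi`` when that portion's
    ``invert`` flag is set, then shifted by the total slice count of all
    portions below it. Only z changes — every other trait is preserved
    bit-exactly — and the joined grain count is the sum of the portion
    counts.
    """
    if len(portions) < 2:
        raise ParameterError("need at least two portions to rejoin")
    ids = {p.meta.sample_id for p in portions}
    if len(ids) != 1:
        raise PortionMismatchError(f"portions belong to different spikes: {ids}")
    pitches = {p.meta.voxel_pitch_um for p in portions}
    if len(pitches) != 1:
        raise PortionMismatchError(f"voxel pitch mismatch across portions: {pitches}")
    roles = [p.meta.portion for p in portions]
    if len(portions) == 2:
        if len(roles) != len(set(roles)):
            raise PortionMismatchError(f"duplicate portion roles: {roles}")
        if roles != ["bottom", "top"]:
            raise PortionMismatchError(
                f"expected portion roles [bottom, top], got {roles}"
            )
    # with more than two portions the stated order is authoritative and
    # the three-valued portion role cannot name them all uniquely
    pitch = portions[0].meta.voxel_pitch_um
    joined: list = []
    offset = 0
    for p in portions:
        for rec in p.records:
            joined.append(
                _transform_record(rec, p.n_slices, p.invert, offset, pitch)
            )
        offset += p.n_slices
    joined.sort(key=lambda r: r.centroid_vox[2])
    for i, rec in enumerate(joined, start=1):
        rec.grain_index = i
    return joined


def assign_regions(
    records: list, extent: RachisExtent, half_width: float = 0.16
) -> list:
    """Assign each grain to bottom / middle / top (in place; returns records).

    p = (z - z_low) / (z_high - z_low) is the grain centroid's
    normalized height along the rachis extent; the middle band is
    p in [0.5 - half_width, 0.5 + half_width] with inclusive bounds.
    Positions outside the extent are clamped with a warning.
    """
    lo, hi = 0.5 - half_width, 0.5 + half_width
    span = extent.z_high - extent.z_low
    for rec in records:
        z = rec.centroid_vox[2]
        if z < extent.z_low or z > extent.z_high:
            logger.warning(
                "grain %s at z=%.1f outside rachis extent [%d, %d]; clamping",
                rec.grain_index, z, extent.z_low, extent.z_high,
            )
            z = min(max(z, extent.z_low), extent.z_high)
        p = 0.5 if span == 0 else (z - extent.z_low) / span
        if p < lo:
            rec.region = "bottom"
        elif p > hi:
            rec.region = "top"
        else:
            rec.region = "middle"
    return records


def summarize_spike(
    records: list,
    extent: RachisExtent,
    meta: ScanMeta,
    portions_joined: int = 1,
) -> SpikeRecord:
    """Aggregate grain records into one per-spike summary.

    Total grain volume is the proxy trait correlated with manual spike
    weight; per-region counts and mean volumes mirror the along-spike
    trait profiles. Empty spikes yield zero counts.
    """
    counts = {r: 0 for r in REGIONS}
    volumes = {r: [] for r in REGIONS}
    total = 0.0
    for rec in records:
        if rec.region not in counts:
            raise ParameterError(
                f"grain {rec.grain_index} has unassigned region; run "
                "assign_regions first"
            )
        counts[rec.region] += 1
        volumes[rec.region].append(rec.volume_mm3)
        total += rec.volume_mm3
    mean_vol = {
        r: (float(np.mean(v)) if v else 0.0) for r, v in volumes.items()
    }
    return SpikeRecord(
        spike_id=meta.sample_id,
        height_mm=spike_height(extent, meta),
        n_grains=len(records),
        total_grain_volume_mm3=total,
        region_counts=counts,
        region_mean_volume_mm3=mean_vol,
        portions_joined=portions_joined,
    )
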