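"""Synthetic spike phantoms with known ground truth.

A phantom emulates what a benchtop µCT scanner records for a dried
cereal spike inside a cylindrical plastic holder: a bimodal grey-value
volume in which ellipsoidal grains sit in two opposed ranks along a
central low-density rachis cylinder. Grain grey values follow the
high-density mode, air the low-density mode, and the rachis is placed
between the two so that it is invisible at the grain threshold but
appears when the threshold is relaxed by 20%. Options add an enclosing
holder tube (the largest bright connected structure), bright specks
(mounting-material artefacts), grain–grain fusion bridges, and a split
of the spike into bottom/top scan portions.

The generator is deterministic given its seed, and every planted grain
is described analytically in the returned :class:`PhantomTruth`, so all
pipeline stages can be validated without real scan data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError, PlacementError
from .segmentation import BinaryMask, find_bimodal_valley
from .volume_io import ScanMeta, Volume

__all__ = [
    "PhantomSpec",
    "GrainTruth",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "render_grain_mask",
    "truth_to_json",
    "truth_to_frame",
]

#: Thomsen exponent for the approximate ellipsoid surface area.
_THOMSEN_P = 1.6075


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic spike scan.

    Defaults mirror routine scanning of a wheat spike: 68.8 µm/pixel
    voxels, a 512-slice stack, grains of roughly 6.4 x 3.2 x 2.8 mm with
    10% size variation, background and plant grey-value modes at
    5000 +/- 800 and 20000 +/- 1500, and a rachis grey level at 85% of
    the histogram valley so it only appears at a relaxed threshold.
    """

    n_spikelet_pairs: int = 10
    grains_per_spikelet: int = 1
    grain_semi_axes_mm: tuple = (3.2, 1.6, 1.4)
    semi_axis_cv: float = 0.10
    voxel_pitch_um: float = 68.8
    volume_shape: tuple = (512, 128, 128)
    grey_background: tuple = (5000.0, 800.0)
    grey_plant: tuple = (20000.0, 1500.0)
    grey_rachis_fraction: float = 0.85
    grey_rachis_sd: float = 250.0
    rachis: bool = True
    rachis_radius_mm: float = 1.1
    tube: bool = True
    tube_thickness_vox: int = 4
    n_noise_specks: int = 4
    fused_pair_fraction: float = 0.0
    bridge_radius_vox: int = 3
    split_at_slice: int | None = None
    flip_top_portion: bool = True
    max_tilt_deg: float = 30.0
    histogram_smooth_bins: int = 257
    sample_id: str = "phantom"
    seed: int = 0

    def __post_init__(self):
        if self.n_spikelet_pairs < 1 or self.grains_per_spikelet < 1:
            raise ParameterError("need at least one spikelet pair and grain")
        if not 0 <= self.fused_pair_fraction <= 1:
            raise ParameterError("fused_pair_fraction must be in [0, 1]")
        if not 0 < self.grey_rachis_fraction < 1:
            raise ParameterError("grey_rachis_fraction must be in (0, 1)")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 8:
            raise ParameterError("volume_shape must be 3 extents >= 8")

    @property
    def semi_axes_vox(self) -> np.ndarray:
        return (
            np.asarray(self.grain_semi_axes_mm) * 1000.0 / self.voxel_pitch_um
        )


@dataclass
class GrainTruth:
    """Analytic description of one planted grain (voxel coordinates)."""

    index: int
    center_zyx: tuple
    semi_axes_vox: tuple  # (a, b, c), a >= b >= c
    semi_axes_mm: tuple
    axes: list  # 3x3, rows are axis directions (major first), (z, y, x)
    volume_vox_analytic: float
    volume_mm3_analytic: float
    surface_area_mm2_analytic: float
    voxel_count: int = 0


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    sample_id: str
    shape: tuple
    voxel_pitch_um: float
    grains: list = field(default_factory=list)
    rachis_extent: tuple | None = None
    fusion_links: list = field(default_factory=list)
    bridge_radius_vox: int = 0
    split_at_slice: int | None = None
    flip_top_portion: bool = False
    predicted_threshold: int = 0
    rachis_grey_mean: float | None = None
    n_plant_voxels: int = 0
    seed: int = 0


def _thomsen_area(a: float, b: float, c: float) -> float:
    p = _THOMSEN_P
    return (
        4.0
        * np.pi
        * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    )


def _axes_from_angles(tilt: float, azimuth: float) -> np.ndarray:
    """Orthonormal axes (rows, (z,y,x) components); major axis tilted
    ``tilt`` radians away from the rachis (z) axis toward ``azimuth``."""
    u = np.array(
        [np.cos(tilt), np.sin(tilt) * np.sin(azimuth), np.sin(tilt) * np.cos(azimuth)]
    )
    helper = np.array([0.0, 1.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    v = helper - (helper @ u) * u
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.stack([u, v, w])


def _ellipsoid_voxels(center, semi_axes, axes, shape):
    """Integer voxel coordinates inside a rotated ellipsoid."""
    center = np.asarray(center, dtype=np.float64)
    semi_axes = np.asarray(semi_axes, dtype=np.float64)
    axes = np.asarray(axes, dtype=np.float64)
    # axis-aligned bounding half-extents of the rotated ellipsoid
    half = np.sqrt(((axes * semi_axes[:, None]) ** 2).sum(axis=0)) + 1.0
    lo = np.maximum(np.floor(center - half).astype(int), 0)
    hi = np.minimum(np.ceil(center + half).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return tuple(np.empty(0, dtype=np.int64) for _ in range(3))
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    rel = (pts - center) @ axes.T / semi_axes
    inside = (rel**2).sum(axis=1) <= 1.0
    return tuple(pts[inside, i].astype(np.int64) for i in range(3))


def _bridge_voxels(c1, c2, radius, shape):
    """Voxels within ``radius`` (Euclidean) of the segment c1-c2."""
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    lo = np.maximum(np.floor(np.minimum(c1, c2) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(c1, c2) + radius + 1).astype(int) + 1, shape)
    grids = np.meshgrid(
        *[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    d = c2 - c1
    seg_len2 = d @ d
    t = np.clip((pts - c1) @ d / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    closest = c1 + np.outer(t, d)
    inside = ((pts - closest) ** 2).sum(axis=1) <= radius**2
    return tuple(pts[inside, i].astype(np.int64) for i in range(3))


def _conflicts(occupied: np.ndarray, voxels) -> bool:
    """True when ``voxels`` come within chessboard distance 1 of
    ``occupied`` (which would 26-connect the two objects)."""
    zz, yy, xx = voxels
    if zz.size == 0:
        return True
    shape = occupied.shape
    lo = [max(int(v.min()) - 1, 0) for v in (zz, yy, xx)]
    hi = [min(int(v.max()) + 2, s) for v, s in zip((zz, yy, xx), shape)]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    local = np.zeros([h - l for l, h in zip(lo, hi)], dtype=bool)
    local[zz - lo[0], yy - lo[1], xx - lo[2]] = True
    grown = ndimage.binary_dilation(local, structure=np.ones((3, 3, 3), bool))
    return bool((grown & occupied[box]).any())


def generate_phantom(spec: PhantomSpec):
    """Generate one synthetic spike scan (or two portions) plus truth.

    Returns ``(Volume, PhantomTruth)``, or ``((bottom, top), truth)``
    when ``spec.split_at_slice`` is set. Deterministic given
    ``spec.seed``; raises :class:`PlacementError` if grains cannot be
    placed without touching after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.volume_shape)
    Z, Y, X = shape
    cy, cx = (Y - 1) / 2.0, (X - 1) / 2.0
    base_axes_vox = spec.semi_axes_vox
    a_vox = float(base_axes_vox[0])
    rachis_r = spec.rachis_radius_mm * 1000.0 / spec.voxel_pitch_um

    occupied = np.zeros(shape, dtype=bool)  # grains + tube + specks
    plant = np.zeros(shape, dtype=bool)

    # --- holder tube: a full-height cylinder shell near the lateral edge
    yy_g, xx_g = np.mgrid[0:Y, 0:X]
    r2 = (yy_g - cy) ** 2 + (xx_g - cx) ** 2
    if spec.tube:
        r_out = min(cy, cx) - 1.0
        r_in = r_out - spec.tube_thickness_vox
        shell = (r2 <= r_out**2) & (r2 >= r_in**2)
        tube_mask = np.broadcast_to(shell, shape).copy()
        plant |= tube_mask
        occupied |= tube_mask

    # --- grain placement: two opposed ranks along the rachis axis
    pad = max(4, int(np.ceil(a_vox)) + 2)
    z0, z1 = pad, Z - 1 - pad
    if z1 <= z0:
        raise ParameterError("volume too short for the requested grains")
    pair_z = np.linspace(z0, z1, spec.n_spikelet_pairs)
    grains: list[GrainTruth] = []
    factor = spec.voxel_pitch_um / 1000.0
    index = 0
    for pair_i, pz in enumerate(pair_z):
        for side in (+1, -1):
            for k in range(spec.grains_per_spikelet):
                # grain size is fixed before placement retries so that
                # crowding cannot bias accepted grains toward smaller sizes
                s = base_axes_vox * (
                    1.0
                    + np.clip(
                        rng.normal(0.0, spec.semi_axis_cv, 3), -0.25, 0.25
                    )
                )
                s = np.sort(s)[::-1]
                # consecutive spikelet pairs alternate in y, as real
                # spikelets do along the rachis
                stagger = (1 if pair_i % 2 == 0 else -1) * s[1] / 2.0
                placed = False
                for attempt in range(25):
                    tilt_deg = rng.uniform(5.0, spec.max_tilt_deg)
                    if attempt > 15:
                        tilt_deg *= 0.3  # relax toward upright if crowded
                    azimuth = 0.0 if side > 0 else np.pi
                    axes = _axes_from_angles(np.deg2rad(tilt_deg), azimuth)
                    y_off = stagger + (
                        k - (spec.grains_per_spikelet - 1) / 2.0
                    ) * (2.0 * s[1] + 3.0)
                    center = np.array(
                        [pz, cy + y_off, cx + side * (rachis_r + s[2] + 2.0)]
                    )
                    vox = _ellipsoid_voxels(center, s, axes, shape)
                    if vox[0].size == 0:
                        continue
                    if not _conflicts(occupied, vox):
                        placed = True
                        break
                if not placed:
                    raise PlacementError(
                        f"could not place grain {index} after bounded retries"
                    )
                plant[vox] = True
                occupied[vox] = True
                s_mm = tuple(float(v) * factor for v in s)
                grains.append(
                    GrainTruth(
                        index=index,
                        center_zyx=tuple(float(v) for v in center),
                        semi_axes_vox=tuple(float(v) for v in s),
                        semi_axes_mm=s_mm,
                        axes=axes.tolist(),
                        volume_vox_analytic=float(
                            4.0 / 3.0 * np.pi * s[0] * s[1] * s[2]
                        ),
                        volume_mm3_analytic=float(
                            4.0 / 3.0 * np.pi * np.prod(s_mm)
                        ),
                        surface_area_mm2_analytic=float(_thomsen_area(*s_mm)),
                        voxel_count=int(vox[0].size),
                    )
                )
                index += 1

    # --- fusion bridges between the two grains of selected spikelet pairs
    fusion_links = []
    n_fused = int(round(spec.fused_pair_fraction * len(grains) / 2.0))
    if n_fused > 0:
        grains_per_pair = 2 * spec.grains_per_spikelet
        pair_ids = rng.choice(spec.n_spikelet_pairs, size=n_fused, replace=False)
        for pid in sorted(int(p) for p in pair_ids):
            i = pid * grains_per_pair  # first grain of the pair (side +1)
            j = i + spec.grains_per_spikelet  # first grain on side -1
            bv = _bridge_voxels(
                grains[i].center_zyx,
                grains[j].center_zyx,
                spec.bridge_radius_vox,
                shape,
            )
            plant[bv] = True
            occupied[bv] = True
            fusion_links.append((i, j))

    # --- bright specks emulating mounting-material fragments
    speck_r = 2.0
    for _ in range(spec.n_noise_specks):
        for attempt in range(20):
            center = np.array(
                [
                    rng.uniform(4, Z - 5),
                    cy + rng.uniform(-0.5, 0.5) * (min(cy, cx)),
                    cx + rng.uniform(-0.5, 0.5) * (min(cy, cx)),
                ]
            )
            vox = _ellipsoid_voxels(center, [speck_r] * 3, np.eye(3), shape)
            if vox[0].size and not _conflicts(occupied, vox):
                plant[vox] = True
                occupied[vox] = True
                break

    # --- rachis: a cylinder spanning the grain z-extent (plus margin)
    rachis_mask = None
    rachis_extent = None
    if spec.rachis:
        grain_z = np.flatnonzero(plant.any(axis=(1, 2)))
        if spec.tube:
            core = plant & np.broadcast_to(r2 < (min(cy, cx) - 2 -
                                                 spec.tube_thickness_vox) ** 2,
                                           shape)
            grain_z = np.flatnonzero(core.any(axis=(1, 2)))
        z_lo = max(2, int(grain_z[0]) - 2) if grain_z.size else 2
        z_hi = min(Z - 3, int(grain_z[-1]) + 2) if grain_z.size else Z - 3
        rachis_mask = np.zeros(shape, dtype=bool)
        rachis_mask[z_lo : z_hi + 1] = r2 <= rachis_r**2
        rachis_mask &= ~plant  # grains overrule rachis where they touch
        rachis_extent = (z_lo, z_hi)

    # --- grey-value synthesis with a self-consistent rachis grey level.
    # The rachis mean is a fraction of the histogram valley, but the
    # rachis mode itself shifts where the valley lands, so the level is
    # found by fixed-point iteration on the realized histogram (the
    # noise draws are fixed; only the rachis mean moves).
    n_plant = int(plant.sum())
    n_rachis = int(rachis_mask.sum()) if rachis_mask is not None else 0
    bg_mean, bg_sd = spec.grey_background
    pl_mean, pl_sd = spec.grey_plant
    data = rng.normal(bg_mean, bg_sd, size=shape)
    data[plant] = rng.normal(pl_mean, pl_sd, n_plant)
    rachis_mean = None
    if n_rachis:
        rachis_noise = rng.normal(0.0, spec.grey_rachis_sd, n_rachis)
        base_hist = np.bincount(
            np.clip(data[~rachis_mask], 0, 65535).astype(np.int64).ravel(),
            minlength=65536,
        ).astype(np.float64)
        valley, _, _ = find_bimodal_valley(
            base_hist, spec.histogram_smooth_bins
        )
        for _ in range(6):
            rachis_mean = spec.grey_rachis_fraction * valley
            rachis_vals = np.clip(rachis_mean + rachis_noise, 0, 65535)
            hist = base_hist + np.bincount(
                rachis_vals.astype(np.int64), minlength=65536
            )
            new_valley, _, _ = find_bimodal_valley(
                hist, spec.histogram_smooth_bins
            )
            if new_valley == valley:
                break
            valley = new_valley
        rachis_mean = spec.grey_rachis_fraction * valley
        data[rachis_mask] = rachis_mean + rachis_noise
    else:
        hist = np.bincount(
            np.clip(data, 0, 65535).astype(np.int64).ravel(), minlength=65536
        ).astype(np.float64)
        valley, _, _ = find_bimodal_valley(hist, spec.histogram_smooth_bins)
    data = np.clip(data, 0, 65535).astype(np.uint16)

    truth = PhantomTruth(
        sample_id=spec.sample_id,
        shape=shape,
        voxel_pitch_um=spec.voxel_pitch_um,
        grains=grains,
        rachis_extent=rachis_extent,
        fusion_links=fusion_links,
        bridge_radius_vox=spec.bridge_radius_vox if fusion_links else 0,
        flip_top_portion=spec.flip_top_portion,
        predicted_threshold=int(valley),
        rachis_grey_mean=rachis_mean,
        n_plant_voxels=n_plant,
        seed=spec.seed,
    )

    meta = ScanMeta(
        sample_id=spec.sample_id, voxel_pitch_um=spec.voxel_pitch_um
    )
    if spec.split_at_slice is None:
        return Volume(data, meta), truth

    split = _safe_split_slice(spec.split_at_slice, grains, Z)
    truth.split_at_slice = split
    bottom = Volume(
        data[:split].copy(), replace(meta, portion="bottom")
    )
    top_data = data[split:]
    if spec.flip_top_portion:
        top_data = top_data[::-1]
    top = Volume(np.ascontiguousarray(top_data), replace(meta, portion="top"))
    return (bottom, top), truth


def _safe_split_slice(requested: int, grains, n_slices: int) -> int:
    """Nearest slice to ``requested`` whose cut plane severs no grain."""
    spans = []
    for g in grains:
        half = np.sqrt(
            sum(
                (g.axes[i][0] * g.semi_axes_vox[i]) ** 2 for i in range(3)
            )
        )
        spans.append((g.center_zyx[0] - half - 1, g.center_zyx[0] + half + 1))

    def safe(z):
        return all(z <= lo or z > hi for lo, hi in spans)

    for delta in range(n_slices):
        for z in (requested - delta, requested + delta):
            if 1 <= z <= n_slices - 1 and safe(z):
                return int(z)
    raise PlacementError("no grain-free split slice exists")


def render_grain_mask(truth: PhantomTruth) -> BinaryMask:
    """Re-digitize the planted grains (and fusion bridges) as a clean
    binary mask — the idealized segmentation output for this phantom."""
    mask = np.zeros(truth.shape, dtype=bool)
    for g in truth.grains:
        vox = _ellipsoid_voxels(
            g.center_zyx, g.semi_axes_vox, np.asarray(g.axes), truth.shape
        )
        mask[vox] = True
    for i, j in truth.fusion_links:
        bv = _bridge_voxels(
            truth.grains[i].center_zyx,
            truth.grains[j].center_zyx,
            truth.bridge_radius_vox,
            truth.shape,
        )
        mask[bv] = True
    return BinaryMask(mask)


def truth_to_frame(truth: PhantomTruth) -> pd.DataFrame:
    """Per-grain ground truth as a DataFrame (CSV-ready)."""
    rows = []
    for g in truth.grains:
        rows.append(
            {
                "sample_id": truth.sample_id,
                "grain": g.index,
                "center_z": g.center_zyx[0],
                "center_y": g.center_zyx[1],
                "center_x": g.center_zyx[2],
                "a_vox": g.semi_axes_vox[0],
                "b_vox": g.semi_axes_vox[1],
                "c_vox": g.semi_axes_vox[2],
                "volume_mm3_analytic": g.volume_mm3_analytic,
                "surface_area_mm2_analytic": g.surface_area_mm2_analytic,
                "voxel_count": g.voxel_count,
            }
        )
    return pd.DataFrame(rows)


def truth_to_json(truth: PhantomTruth, path) -> Path:
    """Serialize the full truth record to JSON."""
    path = Path(path)
    payload = {
        "sample_id": truth.sample_id,
        "shape": list(truth.shape),
        "voxel_pitch_um": truth.voxel_pitch_um,
        "rachis_extent": list(truth.rachis_extent)
        if truth.rachis_extent
        else None,
        "fusion_links": [list(l) for l in truth.fusion_links],
        "bridge_radius_vox": truth.bridge_radius_vox,
        "split_at_slice": truth.split_at_slice,
        "flip_top_portion": truth.flip_top_portion,
        "predicted_threshold": truth.predicted_threshold,
        "rachis_grey_mean": truth.rachis_grey_mean,
        "n_plant_voxels": truth.n_plant_voxels,
        "seed": truth.seed,
        "grains": [
            {
                "index": g.index,
                "center_zyx": list(g.center_zyx),
                "semi_axes_vox": list(g.semi_axes_vox),
                "semi_axes_mm": list(g.semi_axes_mm),
                "axes": g.axes,
                "volume_vox_analytic": g.volume_vox_analytic,
                "volume_mm3_analytic": g.volume_mm3_analytic,
                "surface_area_mm2_analytic": g.surface_area_mm2_analytic,
                "voxel_count": g.voxel_count,
            }
            for g in truth.grains
        ],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def generate_cohort(
    n_spikes: int,
    group_effects: dict,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
):
    """Generate a cohort of phantoms with planted group differences.

    ``group_effects`` maps group name to a dict with
    ``count_multiplier`` and ``volume_multiplier`` applied to the base
    spikelet-pair count and per-grain volume (semi-axes scale with the
    cube root). Returns ``(phantoms, planted)`` where phantoms is a list
    of dicts with keys ``group``, ``spec``, ``volume``, ``truth`` and
    planted is a per-spike DataFrame of the planted count and mean
    grain volume. Reproducible given ``seed``.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    phantoms = []
    rows = []
    for group, effects in group_effects.items():
        cmul = float(effects.get("count_multiplier", 1.0))
        vmul = float(effects.get("volume_multiplier", 1.0))
        axis_scale = vmul ** (1.0 / 3.0)
        n_pairs = max(1, int(round(base.n_spikelet_pairs * cmul)))
        semi_axes = tuple(
            float(s) * axis_scale for s in base.grain_semi_axes_mm
        )
        for i in range(n_spikes):
            spike_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base,
                n_spikelet_pairs=n_pairs,
                grain_semi_axes_mm=semi_axes,
                sample_id=f"{group}_s{i:02d}",
                seed=spike_seed,
            )
            vol, truth = generate_phantom(spec)
            phantoms.append(
                {"group": group, "spec": spec, "volume": vol, "truth": truth}
            )
            rows.append(
                {
                    "spike_id": spec.sample_id,
                    "group": group,
                    "planted_count": len(truth.grains),
                    "planted_mean_volume_mm3": float(
                        np.mean([g.volume_mm3_analytic for g in truth.grains])
                    ),
                }
            )
    return phantoms, pd.DataFrame(rows)
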