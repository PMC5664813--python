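"""Batch orchestration: discover scans, match metadata, run the pipeline.

One *spike* is either a single whole scan or a bottom/top pair of
portion scans. For every spike the stages run in a fixed order —
segment, separate fused grains, measure, rejoin portions (when split),
detect the rachis extent, assign regions — and a per-spike grain CSV
plus one cohort-level summary table are written. A failing spike is
quarantined and reported; it never aborts the batch.
"""

from __future__ import annotations

import glob as globlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import ParameterError, SpikeCTError
from .morphometry import measure_all
from .segmentation import SegmentationParams, segment_spike
from .separation import separate_grains
from .spike import (
    Portion,
    RachisExtent,
    SpikeConfig,
    assign_regions,
    detect_rachis_extent,
    rejoin_portions,
    summarize_spike,
)
from .volume_io import ScanMeta, read_isq, read_tiff_stack, write_grain_csv

__all__ = ["RunConfig", "MatchedSpike", "discover_and_match", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run."""

    input_glob: str
    metadata_path: str
    output_dir: str
    segmentation: SegmentationParams = SegmentationParams()
    spike: SpikeConfig = SpikeConfig()
    min_seed_separation: int = 5
    distance_metric: str = "chessboard"
    default_pitch_um: float | None = None
    aux_columns: bool = False
    log_level: str = "INFO"


@dataclass
class MatchedSpike:
    """One spike's scan file(s) and metadata after discovery."""

    sample_id: str
    paths: dict  # portion role -> file path
    meta: ScanMeta


def _portion_from_name(stem: str, sample_id: str) -> str:
    suffix = stem[len(sample_id):].lower()
    if "bottom" in suffix:
        return "bottom"
    if "top" in suffix:
        return "top"
    return "whole"


def discover_and_match(
    input_glob: str,
    metadata_table,
    default_pitch_um: float | None = None,
):
    """Pair scan files with metadata rows by sample-id filename stem.

    ``metadata_table`` is a CSV path or DataFrame with columns
    ``sample_id``, ``voxel_pitch_um`` and optional ``portion`` and
    treatment columns. Matching uses the longest sample_id that
    prefixes the file stem; portion roles come from a ``_bottom`` /
    ``_top`` stem suffix (or the metadata ``portion`` column), and the
    two portions of one spike are grouped into a single entry.

    Returns ``(matched, unmatched)``; files without a metadata row go to
    the unmatched report (with a default-pitch fallback entry when
    ``default_pitch_um`` is given). Ambiguous equal-length matches and
    duplicate sample_id+portion combinations raise.
    """
    if isinstance(metadata_table, (str, Path)):
        meta_df = pd.read_csv(metadata_table, dtype={"sample_id": str})
    else:
        meta_df = metadata_table.copy()
    if "sample_id" not in meta_df.columns:
        raise ParameterError("metadata table needs a sample_id column")
    files = sorted(globlib.glob(str(input_glob)))
    label_cols = [
        c
        for c in meta_df.columns
        if c not in ("sample_id", "voxel_pitch_um", "portion")
    ]
    spikes: dict[str, MatchedSpike] = {}
    unmatched = []
    for f in files:
        stem = Path(f).stem
        candidates = [
            row
            for _, row in meta_df.iterrows()
            if stem == row["sample_id"] or stem.startswith(str(row["sample_id"]))
        ]
        if not candidates:
            if default_pitch_um is not None:
                sid = stem
                meta = ScanMeta(sample_id=sid, voxel_pitch_um=default_pitch_um)
                spikes.setdefault(sid, MatchedSpike(sid, {}, meta)).paths[
                    "whole"
                ] = f
            unmatched.append(f)
            continue
        best_len = max(len(str(r["sample_id"])) for r in candidates)
        best = [r for r in candidates if len(str(r["sample_id"])) == best_len]
        if len(best) > 1:
            raise ParameterError(
                f"ambiguous metadata match for {f}: "
                f"{[str(r['sample_id']) for r in best]}"
            )
        row = best[0]
        sid = str(row["sample_id"])
        portion = str(row["portion"]) if "portion" in row and pd.notna(
            row.get("portion")
        ) else _portion_from_name(stem, sid)
        pitch = float(row.get("voxel_pitch_um", default_pitch_um or 0) or 0)
        if pitch <= 0:
            raise ParameterError(f"no voxel pitch for sample {sid}")
        labels = {c: str(row[c]) for c in label_cols if pd.notna(row[c])}
        entry = spikes.setdefault(
            sid,
            MatchedSpike(
                sid,
                {},
                ScanMeta(
                    sample_id=sid,
                    voxel_pitch_um=pitch,
                    treatment_labels=labels,
                ),
            ),
        )
        if portion in entry.paths:
            raise ParameterError(
                f"duplicate portion {portion!r} for sample {sid}"
            )
        entry.paths[portion] = f
    return list(spikes.values()), unmatched


def _read_scan(path: str, meta: ScanMeta):
    if str(path).lower().endswith(".isq"):
        vol = read_isq(path)
        return vol.with_meta(
            sample_id=meta.sample_id,
            treatment_labels=meta.treatment_labels,
            portion=meta.portion,
        )
    return read_tiff_stack(path, meta)


def _process_portion(volume, config: RunConfig):
    masked, mask, thr = segment_spike(volume, config.segmentation)
    labels = separate_grains(
        mask,
        min_seed_separation=config.min_seed_separation,
        distance_metric=config.distance_metric,
    )
    records = measure_all(labels, masked, volume.meta)
    extent = detect_rachis_extent(
        volume,
        thr,
        config.segmentation,
        relax_fraction=config.spike.rachis_relax_fraction,
    )
    return records, extent, volume.n_slices


def _process_spike(entry: MatchedSpike, config: RunConfig):
    roles = sorted(entry.paths)
    if "whole" in roles:
        vol = _read_scan(entry.paths["whole"], entry.meta)
        records, extent, _ = _process_portion(vol, config)
        portions_joined = 1
    else:
        if set(roles) != {"bottom", "top"}:
            raise ParameterError(
                f"sample {entry.sample_id}: need bottom+top portions, "
                f"got {roles}"
            )
        parts = []
        extents = []
        offset = 0
        for role in ("bottom", "top"):
            meta = replace(entry.meta, portion=role)
            vol = _read_scan(entry.paths[role], meta)
            recs, ext, n_slices = _process_portion(vol, config)
            invert = (
                config.spike.invert_top
                if role == "top"
                else config.spike.invert_bottom
            )
            parts.append(Portion(recs, n_slices, meta, invert=invert))
            lo, hi = ext.z_low, ext.z_high
            if invert:
                lo, hi = (n_slices - 1) - hi, (n_slices - 1) - lo
            extents.append((lo + offset, hi + offset, ext.relaxed_threshold))
            offset += n_slices
        records = rejoin_portions(*parts)
        extent = RachisExtent(
            z_low=min(e[0] for e in extents),
            z_high=max(e[1] for e in extents),
            relaxed_threshold=extents[0][2],
        )
        portions_joined = 2
    assign_regions(records, extent, half_width=config.spike.region_half_width)
    summary = summarize_spike(
        records, extent, entry.meta, portions_joined=portions_joined
    )
    return records, summary


def run_pipeline(config: RunConfig):
    """Run the full pipeline over every discovered spike.

    Writes one ``<sample_id>_grains.csv`` per spike and a cohort-level
    ``spike_summary.csv`` into the output directory, plus an
    ``unmatched.txt`` report when files lack metadata. Returns a dict
    with the output directory, per-spike summaries and quarantined
    failures. Identical inputs and configuration produce identical
    output bytes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matched, unmatched = discover_and_match(
        config.input_glob, config.metadata_path, config.default_pitch_um
    )
    if not matched:
        raise SpikeCTError(
            f"no scans matched {config.input_glob!r}; nothing to do"
        )
    if unmatched:
        (out / "unmatched.txt").write_text("\n".join(unmatched) + "\n")
        for f in unmatched:
            logger.warning("no metadata for %s", f)
    failures = {}
    summaries = []
    for entry in sorted(matched, key=lambda e: e.sample_id):
        try:
            logger.info(
                "spike %s: %d portion(s)", entry.sample_id, len(entry.paths)
            )
            records, summary = _process_spike(entry, config)
            write_grain_csv(
                records,
                summary,
                out / f"{entry.sample_id}_grains.csv",
                aux_columns=config.aux_columns,
            )
            summaries.append(summary)
        except Exception as exc:  # quarantine, keep the batch going
            logger.error("spike %s failed: %s", entry.sample_id, exc)
            failures[entry.sample_id] = str(exc)
    rows = []
    for s in summaries:
        row = {
            "spike_id": s.spike_id,
            "height_mm": s.height_mm,
            "n_grains": s.n_grains,
            "total_grain_volume_mm3": s.total_grain_volume_mm3,
            "portions_joined": s.portions_joined,
        }
        for region in ("bottom", "middle", "top"):
            row[f"n_{region}"] = s.region_counts[region]
            row[f"mean_volume_{region}_mm3"] = s.region_mean_volume_mm3[region]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "spike_summary.csv", index=False)
    if failures:
        pd.Series(failures, name="error").rename_axis("spike_id").to_csv(
            out / "failures.csv"
        )
    return {"output_dir": out, "summaries": summaries, "failures": failures}
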