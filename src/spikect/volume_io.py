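"""Volume input/output: multi-page TIFF stacks, minimal ISQ scans, trait CSVs.

A scan is held as a :class:`Volume` — a ``(z, y, x)`` array of unsigned
16-bit grey values plus a :class:`ScanMeta` carrying the voxel pitch and
sample identity. Slice 0 is the bottom of the scanned portion and all
indices are 0-based.

The ISQ reader implements the 512-byte Scanco header convention
(``CTDATA-HEADER_V1`` magic, little-endian 32-bit dimension fields,
physical extents in µm, data offset counted in 512-byte blocks, 16-bit
signed little-endian samples). Only the fields required to recover the
image grid are consumed; negative stored samples are clamped to zero on
load. A matching fixture writer is provided so the reader is testable
without proprietary scan files.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import tifffile

from .errors import ParameterError, VolumeFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .morphometry import GrainRecord
    from .spike import SpikeRecord

__all__ = [
    "ScanMeta",
    "Volume",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_isq",
    "write_isq_fixture",
    "write_grain_csv",
    "GRAIN_CSV_COLUMNS",
]

ISQ_MAGIC = b"CTDATA-HEADER_V1"
ISQ_HEADER_SIZE = 512

#: Column order of the per-spike grain table; stable across runs.
GRAIN_CSV_COLUMNS = (
    "spike_id",
    "grain_index",
    "centroid_x_vox",
    "centroid_y_vox",
    "centroid_z_vox",
    "z_mm",
    "length_mm",
    "width_mm",
    "depth_mm",
    "volume_vox",
    "volume_mm3",
    "surface_area_mm2",
    "sphericity",
    "region",
)

AUX_CSV_COLUMNS = ("axis_ratio_ba", "axis_ratio_ca")


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata attached to a volume.

    Parameters
    ----------
    sample_id : str
        Identifier shared by all portions of one spike.
    voxel_pitch_um : float
        Physical edge length of one (isotropic) voxel in µm/pixel.
    treatment_labels : dict
        Free-form experimental labels (e.g. temperature, watering group).
    portion : str
        One of ``whole``, ``bottom``, ``top``; ``whole`` for single scans.
    """

    sample_id: str
    voxel_pitch_um: float
    treatment_labels: dict = field(default_factory=dict)
    portion: str = "whole"

    def __post_init__(self):
        if not self.voxel_pitch_um > 0:
            raise ParameterError(
                f"voxel_pitch_um must be positive, got {self.voxel_pitch_um}"
            )
        if self.portion not in ("whole", "bottom", "top"):
            raise ParameterError(f"unknown portion role {self.portion!r}")


@dataclass
class Volume:
    """A reconstructed 3D scan: grey values indexed ``(z, y, x)``."""

    data: np.ndarray
    meta: ScanMeta

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ParameterError(f"all extents must be >= 1, got {self.data.shape}")
        if self.data.dtype != np.uint16:
            raise ParameterError(f"volume dtype must be uint16, got {self.data.dtype}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def with_meta(self, **kwargs) -> "Volume":
        return Volume(self.data, replace(self.meta, **kwargs))


def read_tiff_stack(path, meta: ScanMeta) -> Volume:
    """Read a multi-page 16-bit grayscale TIFF as a volume.

    One page per z-slice, page order taken as z order (slice 0 first).
    Pages must share a single 2D shape and unsigned 16-bit samples;
    missing files, inconsistent page shapes and unsupported sample
    formats are reported as distinct :class:`VolumeFormatError` messages.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        tif = tifffile.TiffFile(path)
    except Exception as exc:  # malformed container
        raise VolumeFormatError(f"not a readable TIFF: {path} ({exc})") from exc
    with tif:
        pages = tif.pages
        if len(pages) == 0:
            raise VolumeFormatError(f"TIFF has no pages: {path}")
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise VolumeFormatError(
                f"inconsistent page shapes {sorted(shapes)} in {path}"
            )
        dtypes = {p.dtype for p in pages}
        if dtypes != {np.dtype(np.uint16)}:
            raise VolumeFormatError(
                f"unsupported sample format {sorted(map(str, dtypes))} in {path}; "
                "expected uint16"
            )
        data = np.stack([p.asarray() for p in pages], axis=0)
    return Volume(data, meta)


def write_tiff_stack(volume: Volume, path) -> Path:
    """Write a volume as an uncompressed multi-page 16-bit TIFF.

    ``read_tiff_stack`` inverts this exactly (voxelwise identity).
    """
    path = Path(path)
    try:
        tifffile.imwrite(path, volume.data, photometric="minisblack")
    except OSError as exc:
        raise VolumeFormatError(f"cannot write {path}: {exc}") from exc
    return path


def _isq_header(dimx: int, dimy: int, dimz: int, pitch_um: float) -> bytes:
    hdr = bytearray(ISQ_HEADER_SIZE)
    hdr[0:16] = ISQ_MAGIC
    struct.pack_into("<i", hdr, 16, 3)  # data type: 16-bit short
    struct.pack_into("<3i", hdr, 44, dimx, dimy, dimz)
    # physical extents in µm; element size is dim_um / dim_p
    struct.pack_into(
        "<3i",
        hdr,
        56,
        int(round(dimx * pitch_um)),
        int(round(dimy * pitch_um)),
        int(round(dimz * pitch_um)),
    )
    # data offset in 512-byte blocks counted after the header block
    struct.pack_into("<i", hdr, 508, 0)
    return bytes(hdr)


def read_isq(path) -> Volume:
    """Read a minimal Scanco-style ISQ file.

    The header's x/y/z pixel dimensions define the grid; the voxel pitch
    is derived as physical x-extent (µm) over x pixels. Stored samples
    are 16-bit signed little-endian in z-major order; negative values
    are clamped to 0 so the result fits the unsigned grey-value model.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    raw = path.read_bytes()
    if len(raw) < ISQ_HEADER_SIZE or raw[:16] != ISQ_MAGIC:
        raise VolumeFormatError(f"bad ISQ magic in {path}")
    dimx, dimy, dimz = struct.unpack_from("<3i", raw, 44)
    physx, _, _ = struct.unpack_from("<3i", raw, 56)
    (offset_blocks,) = struct.unpack_from("<i", raw, 508)
    if min(dimx, dimy, dimz) < 1:
        raise VolumeFormatError(f"non-positive ISQ dimensions ({dimx},{dimy},{dimz})")
    start = (offset_blocks + 1) * ISQ_HEADER_SIZE
    n_samples = dimx * dimy * dimz
    end = start + 2 * n_samples
    if len(raw) < end:
        raise VolumeFormatError(
            f"ISQ payload truncated: need {end} bytes, file has {len(raw)}"
        )
    samples = np.frombuffer(raw[start:end], dtype="<i2").reshape(dimz, dimy, dimx)
    data = np.clip(samples, 0, None).astype(np.uint16)
    pitch_um = physx / dimx
    meta = ScanMeta(sample_id=path.stem, voxel_pitch_um=pitch_um)
    return Volume(data, meta)


def write_isq_fixture(volume: Volume, path) -> Path:
    """Write a volume in the minimal ISQ dialect read by :func:`read_isq`.

    Intended for fixtures and phantoms only — real scanner files carry
    many more header fields than this writer populates.
    """
    path = Path(path)
    z, y, x = volume.shape
    hdr = _isq_header(x, y, z, volume.meta.voxel_pitch_um)
    samples = np.minimum(volume.data, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(samples.tobytes())
    return path


def write_grain_csv(
    records: Sequence["GrainRecord"],
    spike: "SpikeRecord",
    path,
    aux_columns: bool = False,
) -> Path:
    """Write one per-spike grain table as CSV (one row per grain).

    All records must share the spike id of ``spike``; the header line is
    byte-stable across runs. Floats are written with 6 decimal places so
    a parse-back reproduces them to that precision.
    """
    path = Path(path)
    ids = {r.spike_id for r in records}
    if ids and ids != {spike.spike_id}:
        raise ParameterError(
            f"mixed spike ids {sorted(ids)} vs spike {spike.spike_id!r}"
        )
    columns = GRAIN_CSV_COLUMNS + (AUX_CSV_COLUMNS if aux_columns else ())
    lines = [",".join(columns)]
    for r in records:
        row = []
        for col in columns:
            if col == "centroid_x_vox":
                val = r.centroid_vox[0]
            elif col == "centroid_y_vox":
                val = r.centroid_vox[1]
            elif col == "centroid_z_vox":
                val = r.centroid_vox[2]
            else:
                val = getattr(r, col)
            if isinstance(val, float):
                row.append(f"{val:.6f}")
            else:
                row.append(str(val))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path
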