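"""Data model for serial-section stacks, case metadata and result tables.

Images travel as one multi-page TIFF per channel (page index = section
index), 16-bit on disk and floating point in memory.  Coordinates are
0-based ``(section, row, col)``; the section index increases along the
cutting axis.  Tabular results are plain CSV.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError

__all__ = [
    "CHANNEL_ROLES",
    "VoxelGeometry",
    "ChannelVolume",
    "SectionStack",
    "CaseMetadata",
    "MeasurementTable",
    "load_stack",
    "save_stack",
    "save_results",
    "load_results",
]

CHANNEL_ROLES = frozenset(
    {"synaptic_pre", "synaptic_post", "donor", "acceptor", "fret_raw", "other"}
)

NM3_PER_MM3 = 1e18  # 1 mm = 1e6 nm


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel geometry of a serial-section stack.

    Parameters
    ----------
    pixel_size_xy : float
        In-plane pixel size in nanometres.  This is acquisition dependent
        and must be supplied; there is no sensible universal constant.
    section_thickness : float
        Physical section thickness in nanometres (default 70).
    """

    pixel_size_xy: float
    section_thickness: float = 70.0

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy > 0 and self.section_thickness > 0):
            raise FormatError(
                "pixel_size_xy and section_thickness must be strictly positive"
            )

    @property
    def voxel_volume_nm3(self) -> float:
        return self.pixel_size_xy**2 * self.section_thickness

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_volume_nm3 / NM3_PER_MM3

    @property
    def sampling_nm(self) -> tuple[float, float, float]:
        """(section, row, col) physical step sizes in nm."""
        return (self.section_thickness, self.pixel_size_xy, self.pixel_size_xy)


@dataclass
class ChannelVolume:
    """A single channel of a serial-section stack.

    ``data`` is a (n_sections, H, W) array of finite, non-negative
    intensities; ``role`` tags the biological meaning of the channel.
    """

    data: np.ndarray
    role: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(
                f"channel data must be 3D (section, row, col), got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("channel intensities must be finite")
        if np.any(self.data < 0):
            raise FormatError("channel intensities must be non-negative")
        if self.role not in CHANNEL_ROLES:
            raise FormatError(f"unknown channel role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SectionStack:
    """Ordered multi-channel serial-section volume.

    All channels share one (n_sections, H, W) shape and one physical
    geometry.  ``alignment_state`` records whether sections have been
    registered; ``valid_mask`` (set during alignment) marks voxels that
    were mapped from inside the original frame.
    """

    channels: dict[str, ChannelVolume]
    geometry: VoxelGeometry
    alignment_state: str = "raw"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("stack must contain at least one channel")
        if self.alignment_state not in ("raw", "aligned"):
            raise FormatError(f"bad alignment_state {self.alignment_state!r}")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        first_name = next(iter(shapes))
        ref = shapes[first_name]
        for name, shape in shapes.items():
            if shape != ref:
                raise FormatError(
                    f"channel {name!r} has shape {shape}, expected {ref} "
                    f"(from channel {first_name!r})"
                )
        if ref[0] < 2:
            raise FormatError("stack needs at least 2 sections")
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != ref:
                raise FormatError("valid_mask shape does not match channels")

    @property
    def n_sections(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> ChannelVolume:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(f"no channel named {name!r}") from None

    def by_role(self, role: str) -> ChannelVolume:
        """Return the first channel with the given role."""
        for ch in self.channels.values():
            if ch.role == role:
                return ch
        raise FormatError(f"stack has no channel with role {role!r}")

    def full_valid_mask(self) -> np.ndarray:
        """Validity mask, defaulting to all-valid for raw stacks."""
        if self.valid_mask is not None:
            return self.valid_mask
        shape = (self.n_sections, *self.frame_shape)
        return np.ones(shape, dtype=bool)


@dataclass(frozen=True)
class CaseMetadata:
    case_id: str
    sample_id: str
    diagnosis: str  # "AD" | "control"
    sex: str  # "F" | "M"

    def __post_init__(self) -> None:
        for name in ("case_id", "sample_id", "diagnosis", "sex"):
            if not str(getattr(self, name)):
                raise FormatError(f"metadata field {name!r} must be non-empty")


# ---------------------------------------------------------------------------
# Measurement table
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["case_id", "sample_id", "diagnosis", "sex", "measurement", "value"]


@dataclass
class MeasurementTable:
    """Per-sample summary rows feeding the statistics layer.

    One numeric ``value`` per (case_id, sample_id, measurement); metadata
    columns must be complete.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TABLE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"measurement table missing columns: {missing}")
        self.frame = self.frame[TABLE_COLUMNS].reset_index(drop=True)
        meta = self.frame[["case_id", "sample_id", "diagnosis", "sex", "measurement"]]
        if len(self.frame) and meta.isna().any().any():
            raise FormatError("measurement table has missing metadata")
        key = self.frame[["case_id", "sample_id", "measurement"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate (case, sample, measurement) row: {dup}")

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "MeasurementTable":
        if not records:
            return cls()
        return cls(pd.DataFrame.from_records(list(records)))

    def add_row(self, meta: CaseMetadata, measurement: str, value: float) -> "MeasurementTable":
        row = {
            "case_id": meta.case_id,
            "sample_id": meta.sample_id,
            "diagnosis": meta.diagnosis,
            "sex": meta.sex,
            "measurement": measurement,
            "value": float(value),
        }
        if self.frame.empty:
            frame = pd.DataFrame([row])
        else:
            frame = pd.concat([self.frame, pd.DataFrame([row])], ignore_index=True)
        return MeasurementTable(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self.frame.equals(other.frame)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_stack(
    paths: Mapping[str, object],
    geometry: VoxelGeometry,
    roles: Mapping[str, str] | None = None,
) -> SectionStack:
    """Load a raw (unaligned) stack from per-channel TIFF files.

    Parameters
    ----------
    paths : mapping of channel name -> path or sequence of paths
        A single path is read as a multi-page TIFF (page = section); a
        sequence is read as one single-page TIFF per section, in order.
    geometry : VoxelGeometry
    roles : optional mapping of channel name -> role

    Section and channel order are preserved exactly as given.
    """
    roles = dict(roles or {})
    channels: dict[str, ChannelVolume] = {}
    ref_shape: tuple[int, int, int] | None = None
    ref_name = ""
    for name, src in paths.items():
        if isinstance(src, (str, Path)):
            data = tifffile.imread(str(src))
            if data.ndim == 2:
                data = data[None]
        else:
            pages = [tifffile.imread(str(p)) for p in src]
            data = np.stack(pages, axis=0)
        if data.ndim != 3:
            raise FormatError(f"channel {name!r}: expected 2D sections, got ndim={data.ndim}")
        if ref_shape is None:
            ref_shape, ref_name = data.shape, name
        elif data.shape != ref_shape:
            raise FormatError(
                f"channel {name!r} has shape {data.shape}; channel {ref_name!r} "
                f"has {ref_shape} (section counts / frame sizes must match)"
            )
        channels[name] = ChannelVolume(data.astype(np.float64), roles.get(name, "other"))
    return SectionStack(channels, geometry, alignment_state="raw")


def save_stack(stack: SectionStack, directory: str | Path) -> dict[str, Path]:
    """Write one 16-bit multi-page TIFF per channel; returns name -> path.

    Intensities are rounded and clipped to the uint16 range, matching the
    on-disk convention.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, ch in stack.channels.items():
        path = directory / f"{name}.tif"
        data = np.clip(np.round(ch.data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(str(path), data)
        written[name] = path
    return written


def save_results(table: MeasurementTable, path: str | Path) -> None:
    """Write a MeasurementTable as CSV (header always present).

    Numeric values are serialized with full repr precision, comfortably
    above 6 significant digits.
    """
    try:
        table.frame.to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def load_results(path: str | Path) -> MeasurementTable:
    frame = pd.read_csv(path, dtype={"case_id": str, "sample_id": str})
    if len(frame) == 0:
        frame = pd.DataFrame(columns=TABLE_COLUMNS)
    return MeasurementTable(frame)
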