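"""Local thresholding, 3D object linking, persistence filtering, densities.

A pixel is foreground when it exceeds its local mean by a configurable
offset; in-plane components (8-connectivity) are linked across
consecutive sections when they overlap by at least
``linking_min_overlap_px`` pixels; only objects persisting across two or
more consecutive sections survive the persistence filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import label as sk_label

from .core_io import ChannelVolume, SectionStack, VoxelGeometry
from .exceptions import ConfigError, FormatError

__all__ = [
    "SegmentationParams",
    "Object3D",
    "local_threshold",
    "link_objects",
    "persistence_filter",
    "density",
    "segment_channel",
]


@dataclass
class SegmentationParams:
    """Per-channel segmentation parameters, frozen study-wide.

    The threshold offset is chosen once per channel (on a calibration
    stack) and then reused unchanged for every stack in a study.
    """

    local_window: int = 31
    threshold_offset: float = 1.0
    min_area_px: int = 2
    linking_min_overlap_px: int = 1
    exclusion_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ConfigError("local_window must be odd and >= 3")
        if self.min_area_px < 1:
            raise ConfigError("min_area_px must be >= 1")
        if self.linking_min_overlap_px < 1:
            raise ConfigError("linking_min_overlap_px must be >= 1")


@dataclass(frozen=True)
class Object3D:
    """A segmented punctum linked across consecutive sections."""

    id: int
    channel_role: str
    voxels: frozenset  # of (section, row, col)
    centroid_nm: tuple[float, float, float]  # (x, y, z)
    volume_nm3: float
    span: int
    per_section_area: tuple[int, ...]
    sections: tuple[int, ...]

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def _make_object(
    obj_id: int,
    voxels: np.ndarray,
    geometry: VoxelGeometry,
    channel_role: str,
) -> Object3D:
    secs = voxels[:, 0]
    uniq, counts = np.unique(secs, return_counts=True)
    centroid = (
        float(voxels[:, 2].mean() * geometry.pixel_size_xy),  # x <- col
        float(voxels[:, 1].mean() * geometry.pixel_size_xy),  # y <- row
        float(secs.mean() * geometry.section_thickness),  # z <- section
    )
    return Object3D(
        id=obj_id,
        channel_role=channel_role,
        voxels=frozenset(map(tuple, voxels.tolist())),
        centroid_nm=centroid,
        volume_nm3=len(voxels) * geometry.voxel_volume_nm3,
        span=len(uniq),
        per_section_area=tuple(int(c) for c in counts),
        sections=tuple(int(s) for s in uniq),
    )


def local_threshold(channel: ChannelVolume, params: SegmentationParams) -> np.ndarray:
    """Binary foreground: intensity > local mean × (1 + threshold_offset).

    The local mean is computed per section over a square
    ``local_window`` neighbourhood (reflect boundary).  Pixels under the
    exclusion mask are forced to background.
    """
    data = channel.data
    h, w = data.shape[1:]
    if params.local_window > min(h, w):
        raise ConfigError(
            f"local_window={params.local_window} exceeds frame size {(h, w)}"
        )
    out = np.empty(data.shape, dtype=bool)
    for s in range(data.shape[0]):
        mean = ndi.uniform_filter(data[s], size=params.local_window, mode="reflect")
        np.maximum(mean, 0.0, out=mean)  # filter round-off can go slightly negative
        out[s] = data[s] > mean * (1.0 + params.threshold_offset)
    if params.exclusion_mask is not None:
        excl = np.asarray(params.exclusion_mask, dtype=bool)
        if excl.shape != data.shape:
            raise FormatError("exclusion_mask shape does not match channel")
        out &= ~excl
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def link_objects(
    mask: np.ndarray,
    geometry: VoxelGeometry,
    *,
    min_overlap_px: int = 1,
    min_area_px: int = 1,
    channel_role: str = "other",
) -> list[Object3D]:
    """Link in-plane components across consecutive sections into 3D objects.

    Components are found per section with 8-connectivity; components in
    consecutive sections sharing at least ``min_overlap_px`` pixels are
    merged, and the transitive closure defines one object.  Components
    smaller than ``min_area_px`` are discarded before linking.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise FormatError("mask must be 3D (section, row, col)")
    n_sections = mask.shape[0]

    labels = np.zeros(mask.shape, dtype=np.int32)
    n_per_section: list[int] = []
    for s in range(n_sections):
        lab = sk_label(mask[s], connectivity=2)
        if min_area_px > 1 and lab.max() > 0:
            counts = np.bincount(lab.ravel())
            small = np.flatnonzero(counts < min_area_px)
            if len(small):
                lab[np.isin(lab, small)] = 0
                lab = sk_label(lab > 0, connectivity=2)
        labels[s] = lab
        n_per_section.append(int(lab.max()))

    offsets = np.concatenate([[0], np.cumsum(n_per_section)])
    total = int(offsets[-1])
    if total == 0:
        return []
    uf = _UnionFind(total)

    for s in range(1, n_sections):
        prev, cur = labels[s - 1], labels[s]
        both = (prev > 0) & (cur > 0)
        if not both.any():
            continue
        pairs = prev[both].astype(np.int64) * (n_per_section[s] + 1) + cur[both]
        uniq, counts = np.unique(pairs, return_counts=True)
        for key, cnt in zip(uniq, counts):
            if cnt >= min_overlap_px:
                p = int(key // (n_per_section[s] + 1))
                c = int(key % (n_per_section[s] + 1))
                uf.union(offsets[s - 1] + p - 1, offsets[s] + c - 1)

    groups: dict[int, list[np.ndarray]] = {}
    for s in range(n_sections):
        if n_per_section[s] == 0:
            continue
        rr, cc = np.nonzero(labels[s])
        lab_vals = labels[s][rr, cc]
        for lab_id in range(1, n_per_section[s] + 1):
            sel = lab_vals == lab_id
            vox = np.column_stack(
                [np.full(sel.sum(), s, dtype=np.int64), rr[sel], cc[sel]]
            )
            root = uf.find(offsets[s] + lab_id - 1)
            groups.setdefault(root, []).append(vox)

    objects = []
    for i, (_, parts) in enumerate(sorted(groups.items())):
        voxels = np.vstack(parts)
        objects.append(_make_object(i, voxels, geometry, channel_role))
    return objects


def persistence_filter(objects: list[Object3D], min_span: int = 2) -> list[Object3D]:
    """Retain only objects spanning at least ``min_span`` consecutive sections."""
    return [o for o in objects if o.span >= min_span]


def density(
    objects: list[Object3D],
    stack: SectionStack,
    valid_mask: np.ndarray | None = None,
) -> float:
    """Objects per mm³ of valid neuropil volume."""
    if valid_mask is None:
        valid_mask = stack.full_valid_mask()
    n_valid = int(np.asarray(valid_mask, dtype=bool).sum())
    if n_valid == 0:
        raise ValueError("zero valid volume; density undefined")
    volume_mm3 = n_valid * stack.geometry.voxel_volume_mm3
    return len(objects) / volume_mm3


def segment_channel(
    stack: SectionStack,
    channel_name: str,
    params: SegmentationParams,
) -> list[Object3D]:
    """Threshold, link and persistence-filter one channel of a stack."""
    ch = stack.channel(channel_name)
    mask = local_threshold(ch, params)
    objects = link_objects(
        mask,
        stack.geometry,
        min_overlap_px=params.linking_min_overlap_px,
        min_area_px=params.min_area_px,
        channel_role=ch.role,
    )
    return persistence_filter(objects)


def objects_mask(objects: list[Object3D], shape: tuple[int, int, int]) -> np.ndarray:
    """Rasterize object voxel sets into a boolean volume."""
    out = np.zeros(shape, dtype=bool)
    for obj in objects:
        idx = np.array(sorted(obj.voxels), dtype=np.int64)
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return out
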