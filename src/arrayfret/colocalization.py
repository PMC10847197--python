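"""Object colocalization, plaque segmentation and distance profiling.

A synaptic object counts as colocalized when any partner object covers
at least 10% of the synaptic object's voxels (the denominator is always
the synaptic object).  The plaque is the largest contiguous
high-threshold component of the amyloid channel; object distances are
Euclidean (anisotropic physical units) from the object centroid to the
nearest plaque-edge voxel, binned in 10 µm steps with a [50 µm, ∞)
far-field reference bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core_io import ChannelVolume, VoxelGeometry
from .exceptions import FormatError, PlaqueAbsentError
from .segmentation import Object3D

__all__ = [
    "PlaqueModel",
    "DistanceProfile",
    "ColocResult",
    "overlap_fraction",
    "colocalize",
    "segment_plaque",
    "distance_to_plaque",
    "distance_profile",
    "DEFAULT_BIN_EDGES_UM",
]

DEFAULT_BIN_EDGES_UM = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, math.inf)


@dataclass
class PlaqueModel:
    """Contiguous plaque core plus its morphological boundary."""

    present: bool
    core_mask: np.ndarray | None = None
    edge_mask: np.ndarray | None = None

    def edge_coords(self) -> np.ndarray:
        if not self.present:
            raise PlaqueAbsentError("no plaque detected")
        return np.column_stack(np.nonzero(self.edge_mask))


@dataclass
class ColocResult:
    pairs: list  # (synapse_id, partner_id, fraction) with fraction >= min_fraction
    percent: float
    colocalized_ids: frozenset


@dataclass
class DistanceProfile:
    bin_edges_um: tuple
    counts: np.ndarray
    volumes_mm3: np.ndarray
    densities: np.ndarray  # NaN where bin volume is zero


def overlap_fraction(synapse: Object3D, partner: Object3D) -> float:
    """|synapse ∩ partner| / |synapse| over 3D voxel sets."""
    if not synapse.voxels:
        raise FormatError("synaptic object has an empty voxel set")
    return len(synapse.voxels & partner.voxels) / len(synapse.voxels)


def colocalize(
    synapses: list[Object3D],
    partners: list[Object3D],
    min_fraction: float = 0.10,
) -> ColocResult:
    """Pair synapses with partners by the minimum-overlap rule.

    Each synapse is counted at most once, as soon as any partner reaches
    ``min_fraction`` of its voxels.
    """
    if not synapses:
        raise FormatError("percent colocalized is undefined for an empty synapse list")
    voxel_to_partner: dict[tuple, list[int]] = {}
    for j, p in enumerate(partners):
        for v in p.voxels:
            voxel_to_partner.setdefault(v, []).append(j)

    pairs = []
    hit_ids = set()
    for syn in synapses:
        overlap_counts: dict[int, int] = {}
        for v in syn.voxels:
            for j in voxel_to_partner.get(v, ()):
                overlap_counts[j] = overlap_counts.get(j, 0) + 1
        for j, cnt in sorted(overlap_counts.items()):
            frac = cnt / len(syn.voxels)
            if frac >= min_fraction and (min_fraction > 0 or cnt > 0):
                pairs.append((syn.id, partners[j].id, frac))
                hit_ids.add(syn.id)
    percent = 100.0 * len(hit_ids) / len(synapses)
    return ColocResult(pairs=pairs, percent=percent, colocalized_ids=frozenset(hit_ids))


def segment_plaque(
    abeta_channel: ChannelVolume,
    geometry: VoxelGeometry,
    *,
    threshold_factor: float = 3.0,
    min_core_area_um2: float = 25.0,
) -> PlaqueModel:
    """Restrictive segmentation of the amyloid channel.

    Pixels above ``threshold_factor`` × the channel's global mean are
    candidates; only the largest contiguous 3D component is kept, and it
    must reach ``min_core_area_um2`` in at least one section — small
    halo puncta never qualify.
    """
    data = abeta_channel.data
    global_mean = float(data.mean())
    if global_mean <= 0:
        return PlaqueModel(present=False)
    candidate = data > threshold_factor * global_mean
    if not candidate.any():
        return PlaqueModel(present=False)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndi.label(candidate, structure=structure)
    if n == 0:
        return PlaqueModel(present=False)
    counts = np.bincount(labels.ravel())[1:]
    core = labels == (int(np.argmax(counts)) + 1)

    px_area_um2 = (geometry.pixel_size_xy / 1000.0) ** 2
    max_section_area = max(int(core[s].sum()) for s in range(core.shape[0]))
    if max_section_area * px_area_um2 < min_core_area_um2:
        return PlaqueModel(present=False)

    eroded = ndi.binary_erosion(
        core, structure=ndi.generate_binary_structure(3, 1), border_value=0
    )
    edge = core & ~eroded
    return PlaqueModel(present=True, core_mask=core, edge_mask=edge)


def _centroid_voxel(obj: Object3D, geometry: VoxelGeometry) -> tuple[int, int, int]:
    x, y, z = obj.centroid_nm
    return (
        int(round(z / geometry.section_thickness)),
        int(round(y / geometry.pixel_size_xy)),
        int(round(x / geometry.pixel_size_xy)),
    )


def distance_to_plaque(
    obj: Object3D, plaque: PlaqueModel, geometry: VoxelGeometry
) -> float:
    """Distance (µm) from object centroid to the nearest plaque-edge voxel.

    Centroids inside the plaque core are assigned distance 0.
    """
    if not plaque.present:
        raise PlaqueAbsentError("distance profile not applicable: no plaque")
    s, r, c = _centroid_voxel(obj, geometry)
    core = plaque.core_mask
    if (
        0 <= s < core.shape[0]
        and 0 <= r < core.shape[1]
        and 0 <= c < core.shape[2]
        and core[s, r, c]
    ):
        return 0.0
    edge = plaque.edge_coords().astype(np.float64)
    x, y, z = obj.centroid_nm
    dz = edge[:, 0] * geometry.section_thickness - z
    dy = edge[:, 1] * geometry.pixel_size_xy - y
    dx = edge[:, 2] * geometry.pixel_size_xy - x
    return float(np.sqrt(dz**2 + dy**2 + dx**2).min() / 1000.0)


def edge_distance_map_um(
    plaque: PlaqueModel, shape: tuple[int, int, int], geometry: VoxelGeometry
) -> np.ndarray:
    """Per-voxel distance (µm) to the plaque edge; 0 inside the core."""
    if not plaque.present:
        raise PlaqueAbsentError("distance profile not applicable: no plaque")
    dist_nm = ndi.distance_transform_edt(
        ~plaque.edge_mask, sampling=geometry.sampling_nm
    )
    dist_um = dist_nm / 1000.0
    dist_um[plaque.core_mask] = 0.0
    return dist_um


def distance_profile(
    objects: list[Object3D],
    plaque: PlaqueModel,
    valid_mask: np.ndarray,
    geometry: VoxelGeometry,
    bin_edges_um: tuple = DEFAULT_BIN_EDGES_UM,
) -> DistanceProfile:
    """Object density per 10 µm distance bin from the plaque edge.

    Bin volumes count valid voxels (excluding the plaque core) whose own
    edge distance falls in the bin; empty-volume bins report NaN density
    rather than zero.  Objects whose centroid lies inside the core get
    distance 0 and land in the first bin.
    """
    if not plaque.present:
        raise PlaqueAbsentError("distance profile not applicable: no plaque")
    valid_mask = np.asarray(valid_mask, dtype=bool)
    edges = np.asarray(bin_edges_um, dtype=float)
    n_bins = len(edges) - 1

    dist_map = edge_distance_map_um(plaque, valid_mask.shape, geometry)
    neuropil = valid_mask & ~plaque.core_mask
    counts = np.zeros(n_bins, dtype=int)
    volumes = np.zeros(n_bins, dtype=float)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        in_bin = neuropil & (dist_map >= lo) & (dist_map < hi)
        volumes[b] = in_bin.sum() * geometry.voxel_volume_mm3

    for obj in objects:
        d = distance_to_plaque(obj, plaque, geometry)
        b = int(np.searchsorted(edges, d, side="right") - 1)
        b = min(max(b, 0), n_bins - 1)
        counts[b] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        densities = np.where(volumes > 0, counts / volumes, np.nan)
    return DistanceProfile(
        bin_edges_um=tuple(edges), counts=counts, volumes_mm3=volumes, densities=densities
    )
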