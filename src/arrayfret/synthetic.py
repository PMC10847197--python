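"""Synthetic serial-section stacks with recoverable ground truth.

Puncta are rendered as Gaussian-profile cylinders (constant in-plane
footprint across their axial span) whose half-max contour defines the
truth voxel set.  A stack carries four channels — synaptic, donor,
acceptor and raw FRET — where the raw FRET channel is built as

    fret = E · donor_signal · [true coloc]  +  β·donor  +  γ·acceptor  +  noise

so every downstream stage (registration, segmentation, colocalization,
bleed-through calibration, FRET positivity) has an exact target.  Noise
is Poisson on the signal followed by additive Gaussian read noise.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .colocalization import PlaqueModel, distance_to_plaque, edge_distance_map_um
from .core_io import ChannelVolume, SectionStack, VoxelGeometry
from .exceptions import ConfigError
from .registration import AffineTransform2D
from .segmentation import Object3D, _make_object

__all__ = [
    "PlaqueConfig",
    "MisalignmentConfig",
    "NoiseConfig",
    "SimConfig",
    "SynapseAssociation",
    "GroundTruth",
    "generate_stack",
    "generate_calibration_stacks",
    "perturb_sections",
]

_HALF_MAX = np.sqrt(2.0 * np.log(2.0))  # sigma = radius / _HALF_MAX


@dataclass(frozen=True)
class PlaqueConfig:
    present: bool = False
    radius_um: float = 5.0
    gradient_slope: float = 1.0  # per-10µm-bin density multiplier
    halo_puncta: int = 8
    amplitude_factor: float = 4.0


@dataclass(frozen=True)
class MisalignmentConfig:
    max_translation_px: float = 0.0
    max_rotation_deg: float = 0.0
    max_shear: float = 0.0

    @property
    def magnitude_zero(self) -> bool:
        return (
            self.max_translation_px == 0
            and self.max_rotation_deg == 0
            and self.max_shear == 0
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Poisson shot noise on (signal + background) plus Gaussian read noise.

    The background pedestal makes the local-mean threshold meaningful,
    mirroring real detector offsets; ``off()`` disables everything so
    renders are exact.
    """

    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0  # 0 disables shot noise
    background: float = 20.0

    @property
    def enabled(self) -> bool:
        return self.gaussian_sd > 0 or self.poisson_scale > 0 or self.background > 0

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(gaussian_sd=0.0, poisson_scale=0.0, background=0.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic serial-section acquisition."""

    n_sections: int = 10
    frame_size: tuple[int, int] = (128, 128)
    geometry: VoxelGeometry = field(default_factory=lambda: VoxelGeometry(100.0, 70.0))
    n_synapses: int = 60
    synapse_radius_xy: tuple[float, float] = (150.0, 250.0)  # nm
    synapse_span_sections: tuple[int, int] = (2, 4)
    frac_donor_in_synapse: float = 0.7
    frac_acceptor_in_synapse: float = 0.6
    frac_coloc: float = 0.3
    fret_efficiency: float = 0.3
    beta_true: float = 0.2
    gamma_true: float = 0.1
    plaque: PlaqueConfig = field(default_factory=PlaqueConfig)
    misalignment: MisalignmentConfig = field(default_factory=MisalignmentConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    single_section_noise_objects: int = 0
    n_distractors: int = 8  # free-floating partner puncta per partner channel
    amplitude: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_donor_in_synapse": self.frac_donor_in_synapse,
            "frac_acceptor_in_synapse": self.frac_acceptor_in_synapse,
            "frac_coloc": self.frac_coloc,
            "fret_efficiency": self.fret_efficiency,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.frac_coloc > min(self.frac_donor_in_synapse, self.frac_acceptor_in_synapse):
            raise ConfigError(
                "frac_coloc cannot exceed the per-channel in-synapse fractions"
            )
        if self.synapse_span_sections[0] < 2:
            raise ConfigError("synapse span must be >= 2 sections")
        if self.synapse_span_sections[1] > self.n_sections:
            raise ConfigError("synapse span exceeds n_sections")
        if self.beta_true < 0 or self.gamma_true < 0:
            raise ConfigError("bleed-through coefficients must be non-negative")
        if self.n_sections < 2:
            raise ConfigError("need at least 2 sections")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SynapseAssociation:
    synapse_id: int
    donor_id: int | None
    acceptor_id: int | None

    @property
    def coloc(self) -> bool:
        return self.donor_id is not None and self.acceptor_id is not None


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    objects: list[Object3D]
    noise_objects: list[Object3D]
    associations: list[SynapseAssociation]
    true_fret_mask: np.ndarray
    section_transforms: list[AffineTransform2D] | None = None
    plaque_core_mask: np.ndarray | None = None
    plaque_edge_mask: np.ndarray | None = None
    true_bin_counts: np.ndarray | None = None
    true_bin_densities: np.ndarray | None = None

    def objects_by_role(self, role: str) -> list[Object3D]:
        return [o for o in self.objects if o.channel_role == role]

    @property
    def n_synapses(self) -> int:
        return len(self.objects_by_role("synaptic_post"))

    @property
    def n_coloc(self) -> int:
        return sum(1 for a in self.associations if a.coloc)

    def plaque_model(self) -> PlaqueModel:
        if self.plaque_core_mask is None:
            return PlaqueModel(present=False)
        return PlaqueModel(
            present=True,
            core_mask=self.plaque_core_mask,
            edge_mask=self.plaque_edge_mask,
        )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _render_punctum(
    volume: np.ndarray,
    s0: int,
    span: int,
    yc: float,
    xc: float,
    r_px: float,
    amplitude: float,
) -> np.ndarray:
    """Add a Gaussian-profile cylinder; return its half-max voxel array."""
    h, w = volume.shape[1:]
    sigma = r_px / _HALF_MAX
    lo_r = max(int(np.floor(yc - 3 * r_px)), 0)
    hi_r = min(int(np.ceil(yc + 3 * r_px)) + 1, h)
    lo_c = max(int(np.floor(xc - 3 * r_px)), 0)
    hi_c = min(int(np.ceil(xc + 3 * r_px)) + 1, w)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d2 = (rr - yc) ** 2 + (cc - xc) ** 2
    profile = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    for s in range(s0, s0 + span):
        volume[s, lo_r:hi_r, lo_c:hi_c] += profile
    in_r, in_c = np.nonzero(d2 <= r_px**2)
    sec = np.repeat(np.arange(s0, s0 + span), len(in_r))
    rows = np.tile(rr[in_r, in_c], span)
    cols = np.tile(cc[in_r, in_c], span)
    return np.column_stack([sec, rows, cols]).astype(np.int64)


class _Packer:
    """Rejection-sampling placement keeping puncta apart and inside the frame."""

    def __init__(self, frame: tuple[int, int], margin: float, min_gap_px: float = 8.0):
        self.frame = frame
        self.margin = margin
        self.min_gap = min_gap_px
        self.placed: list[tuple[float, float, float]] = []  # (y, x, r)

    def fits(self, y: float, x: float, r: float) -> bool:
        h, w = self.frame
        if not (self.margin + r <= y <= h - 1 - self.margin - r):
            return False
        if not (self.margin + r <= x <= w - 1 - self.margin - r):
            return False
        for py, px_, pr in self.placed:
            if (y - py) ** 2 + (x - px_) ** 2 < (r + pr + self.min_gap) ** 2:
                return False
        return True

    def add(self, y: float, x: float, r: float) -> None:
        self.placed.append((y, x, r))


def _apply_noise(data: np.ndarray, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    out = data + noise.background
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=data.shape)
    return np.clip(out, 0.0, None)


def _plaque_geometry(cfg: SimConfig) -> tuple[float, float, float]:
    """(yc, xc, radius_px) of the plaque disk."""
    h, w = cfg.frame_size
    r_px = cfg.plaque.radius_um * 1000.0 / cfg.geometry.pixel_size_xy
    return (h / 2.0, r_px + 4.0, r_px)


def _placement_weight(
    cfg: SimConfig, y: float, x: float, plaque_yx_r: tuple[float, float, float] | None
) -> float:
    """Relative acceptance probability under the per-bin density gradient."""
    slope = cfg.plaque.gradient_slope
    if plaque_yx_r is None or slope == 1.0:
        return 1.0
    yc, xc, r_px = plaque_yx_r
    dist_um = max(0.0, (np.hypot(y - yc, x - xc) - r_px)) * cfg.geometry.pixel_size_xy / 1000.0
    b = min(int(dist_um // 10.0), 5)
    weights = [slope**k for k in range(6)]
    return (slope**b) / max(weights)


def _sample_center(
    cfg: SimConfig,
    rng: np.random.Generator,
    packer: _Packer,
    r_px: float,
    plaque_yx_r,
    max_tries: int = 4000,
) -> tuple[float, float]:
    h, w = cfg.frame_size
    for _ in range(max_tries):
        y = rng.uniform(0, h - 1)
        x = rng.uniform(0, w - 1)
        if not packer.fits(y, x, r_px):
            continue
        if rng.uniform() < _placement_weight(cfg, y, x, plaque_yx_r):
            return y, x
    raise ConfigError(
        f"infeasible packing: could not place object of radius {r_px:.1f} px "
        f"after {max_tries} tries (frame {cfg.frame_size}, "
        f"{len(packer.placed)} objects already placed)"
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_stack(cfg: SimConfig) -> tuple[SectionStack, GroundTruth]:
    """Render one synthetic acquisition and its ground truth.

    The returned stack is perfectly aligned; apply
    :func:`perturb_sections` to exercise registration.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_size
    shape = (cfg.n_sections, h, w)
    px_nm = cfg.geometry.pixel_size_xy

    r_lo, r_hi = cfg.synapse_radius_xy
    max_r_px = r_hi / px_nm
    margin = max_r_px + cfg.misalignment.max_translation_px + 2.0
    if margin * 2 >= min(h, w) - 2:
        raise ConfigError("frame too small for object radius + misalignment margin")

    synaptic = np.zeros(shape)
    donor = np.zeros(shape)
    acceptor = np.zeros(shape)
    true_fret_mask = np.zeros(shape, dtype=bool)

    plaque_core = plaque_edge = None
    plaque_yx_r = None
    if cfg.plaque.present:
        plaque_yx_r = _plaque_geometry(cfg)
        yc, xc, r_px = plaque_yx_r
        rr, cc = np.mgrid[0:h, 0:w]
        disk = (rr - yc) ** 2 + (cc - xc) ** 2 <= r_px**2
        donor += cfg.amplitude * cfg.plaque.amplitude_factor * disk[None, :, :]
        plaque_core = np.broadcast_to(disk, shape).copy()
        inner = (rr - yc) ** 2 + (cc - xc) ** 2 <= (r_px - 1.0) ** 2
        plaque_edge = plaque_core & ~np.broadcast_to(inner, shape)

    packer = _Packer((h, w), margin)
    if plaque_yx_r is not None:
        packer.add(plaque_yx_r[0], plaque_yx_r[1], plaque_yx_r[2])

    # rough feasibility bound before slow rejection sampling
    usable = (h - 2 * margin) * (w - 2 * margin)
    footprint = np.pi * (max_r_px + 3.0) ** 2
    n_total = cfg.n_synapses + 2 * cfg.n_distractors + cfg.single_section_noise_objects
    if n_total * footprint > 0.65 * usable:
        raise ConfigError(
            f"infeasible packing: {n_total} objects need ~{n_total * footprint:.0f} px², "
            f"frame offers {usable:.0f} px²"
        )

    objects: list[Object3D] = []
    noise_objects: list[Object3D] = []
    associations: list[SynapseAssociation] = []
    next_id = 0

    def new_object(vox: np.ndarray, role: str) -> Object3D:
        nonlocal next_id
        obj = _make_object(next_id, vox, cfg.geometry, role)
        next_id += 1
        return obj

    span_lo, span_hi = cfg.synapse_span_sections
    for _ in range(cfg.n_synapses):
        r_px = rng.uniform(r_lo, r_hi) / px_nm
        y, x = _sample_center(cfg, rng, packer, r_px, plaque_yx_r)
        packer.add(y, x, r_px)
        span = int(rng.integers(span_lo, span_hi + 1))
        s0 = int(rng.integers(0, cfg.n_sections - span + 1))
        amp = cfg.amplitude * rng.uniform(0.8, 1.2)
        vox = _render_punctum(synaptic, s0, span, y, x, r_px, amp)
        syn_obj = new_object(vox, "synaptic_post")
        objects.append(syn_obj)

        # label category: coloc / donor-only / acceptor-only / neither
        u = rng.uniform()
        p_c = cfg.frac_coloc
        p_d = cfg.frac_donor_in_synapse - p_c
        p_a = cfg.frac_acceptor_in_synapse - p_c
        has_d = has_a = False
        if u < p_c:
            has_d = has_a = True
        elif u < p_c + p_d:
            has_d = True
        elif u < p_c + p_d + p_a:
            has_a = True

        donor_id = acceptor_id = None
        if has_d:
            dvox = _render_punctum(
                donor, s0, span, y, x, r_px, cfg.amplitude * rng.uniform(0.8, 1.2)
            )
            dobj = new_object(dvox, "donor")
            objects.append(dobj)
            donor_id = dobj.id
        if has_a:
            avox = _render_punctum(
                acceptor, s0, span, y, x, r_px, cfg.amplitude * rng.uniform(0.8, 1.2)
            )
            aobj = new_object(avox, "acceptor")
            objects.append(aobj)
            acceptor_id = aobj.id
        if has_d and has_a:
            true_fret_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        associations.append(SynapseAssociation(syn_obj.id, donor_id, acceptor_id))

    for channel, role in ((donor, "donor"), (acceptor, "acceptor")):
        for _ in range(cfg.n_distractors):
            r_px = rng.uniform(r_lo, r_hi) / px_nm
            y, x = _sample_center(cfg, rng, packer, r_px, plaque_yx_r)
            packer.add(y, x, r_px)
            span = int(rng.integers(span_lo, span_hi + 1))
            s0 = int(rng.integers(0, cfg.n_sections - span + 1))
            vox = _render_punctum(
                channel, s0, span, y, x, r_px, cfg.amplitude * rng.uniform(0.8, 1.2)
            )
            objects.append(new_object(vox, role))

    for _ in range(cfg.single_section_noise_objects):
        r_px = rng.uniform(r_lo, r_hi) / px_nm
        y, x = _sample_center(cfg, rng, packer, r_px, plaque_yx_r)
        packer.add(y, x, r_px)
        s0 = int(rng.integers(0, cfg.n_sections))
        vox = _render_punctum(
            synaptic, s0, 1, y, x, r_px, cfg.amplitude * rng.uniform(0.8, 1.2)
        )
        noise_objects.append(new_object(vox, "synaptic_post"))

    if cfg.plaque.present:
        yc, xc, r_px = plaque_yx_r
        halo_amp = cfg.amplitude * cfg.plaque.amplitude_factor
        for _ in range(cfg.plaque.halo_puncta):
            for _try in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                rad = r_px + rng.uniform(8.0, 25.0)
                y, x = yc + rad * np.sin(ang), xc + rad * np.cos(ang)
                if packer.fits(y, x, 1.5):
                    break
            else:
                continue
            packer.add(y, x, 1.5)
            s0 = int(rng.integers(0, cfg.n_sections))
            vox = _render_punctum(donor, s0, 1, y, x, 1.5, halo_amp)
            noise_objects.append(new_object(vox, "donor"))

    fret = (
        cfg.fret_efficiency * donor * true_fret_mask
        + cfg.beta_true * donor
        + cfg.gamma_true * acceptor
    )

    channels = {
        "synaptic": ChannelVolume(_apply_noise(synaptic, cfg.noise, rng), "synaptic_post"),
        "donor": ChannelVolume(_apply_noise(donor, cfg.noise, rng), "donor"),
        "acceptor": ChannelVolume(_apply_noise(acceptor, cfg.noise, rng), "acceptor"),
        "fret": ChannelVolume(_apply_noise(fret, cfg.noise, rng), "fret_raw"),
    }
    stack = SectionStack(channels, cfg.geometry, alignment_state="aligned")

    truth = GroundTruth(
        objects=objects,
        noise_objects=noise_objects,
        associations=associations,
        true_fret_mask=true_fret_mask,
        plaque_core_mask=plaque_core,
        plaque_edge_mask=plaque_edge,
    )
    if cfg.plaque.present:
        _fill_truth_profile(truth, cfg, shape)
    return stack, truth


def _fill_truth_profile(truth: GroundTruth, cfg: SimConfig, shape) -> None:
    plaque = truth.plaque_model()
    edges = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf])
    counts = np.zeros(6, dtype=int)
    for obj in truth.objects_by_role("synaptic_post"):
        d = distance_to_plaque(obj, plaque, cfg.geometry)
        b = min(int(np.searchsorted(edges, d, side="right") - 1), 5)
        counts[max(b, 0)] += 1
    dist_map = edge_distance_map_um(plaque, shape, cfg.geometry)
    neuropil = ~truth.plaque_core_mask
    volumes = np.zeros(6)
    for b in range(6):
        sel = neuropil & (dist_map >= edges[b]) & (dist_map < edges[b + 1])
        volumes[b] = sel.sum() * cfg.geometry.voxel_volume_mm3
    with np.errstate(divide="ignore", invalid="ignore"):
        truth.true_bin_densities = np.where(volumes > 0, counts / volumes, np.nan)
    truth.true_bin_counts = counts


def generate_calibration_stacks(cfg: SimConfig) -> tuple[SectionStack, SectionStack]:
    """Donor-only and acceptor-only control stacks for β/γ estimation.

    The donor-only stack has zero acceptor signal and
    ``fret = β·donor + noise``; the acceptor-only stack is symmetric
    with γ.
    """
    cfg.validate()
    seq = np.random.SeedSequence(cfg.seed)
    child_d, child_a = seq.spawn(2)
    stacks = []
    for which, child in (("donor", child_d), ("acceptor", child_a)):
        rng = np.random.default_rng(child)
        h, w = cfg.frame_size
        shape = (cfg.n_sections, h, w)
        signal = np.zeros(shape)
        r_lo, r_hi = cfg.synapse_radius_xy
        px_nm = cfg.geometry.pixel_size_xy
        margin = r_hi / px_nm + 2.0
        packer = _Packer((h, w), margin)
        span_lo, span_hi = cfg.synapse_span_sections
        n_blobs = max(cfg.n_synapses, 30)
        for _ in range(n_blobs):
            r_px = rng.uniform(r_lo, r_hi) / px_nm
            y, x = _sample_center(cfg, rng, packer, r_px, None)
            packer.add(y, x, r_px)
            span = int(rng.integers(span_lo, span_hi + 1))
            s0 = int(rng.integers(0, cfg.n_sections - span + 1))
            _render_punctum(
                signal, s0, span, y, x, r_px, cfg.amplitude * rng.uniform(0.8, 1.2)
            )
        coeff = cfg.beta_true if which == "donor" else cfg.gamma_true
        fret = coeff * signal
        zero = np.zeros(shape)
        donor_data = signal if which == "donor" else zero
        acceptor_data = signal if which == "acceptor" else zero
        channels = {
            "donor": ChannelVolume(
                _apply_noise(donor_data, cfg.noise, rng) if which == "donor" else zero.copy(),
                "donor",
            ),
            "acceptor": ChannelVolume(
                _apply_noise(acceptor_data, cfg.noise, rng)
                if which == "acceptor"
                else zero.copy(),
                "acceptor",
            ),
            "fret": ChannelVolume(_apply_noise(fret, cfg.noise, rng), "fret_raw"),
        }
        stacks.append(SectionStack(channels, cfg.geometry, alignment_state="aligned"))
    return stacks[0], stacks[1]


def perturb_sections(
    stack: SectionStack,
    cfg: SimConfig,
    seed: int | None = None,
) -> tuple[SectionStack, list[AffineTransform2D]]:
    """Apply a recorded random affine to every channel of each section.

    Returns the perturbed stack (alignment_state reset to raw) and the
    per-section forward transforms actually applied.
    """
    mis = cfg.misalignment
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    h, w = stack.frame_shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    transforms: list[AffineTransform2D] = []
    for _ in range(stack.n_sections):
        if mis.magnitude_zero:
            transforms.append(AffineTransform2D.identity())
            continue
        t = AffineTransform2D.from_params(
            rotation_deg=rng.uniform(-mis.max_rotation_deg, mis.max_rotation_deg),
            shear=rng.uniform(-mis.max_shear, mis.max_shear),
            translation=(
                rng.uniform(-mis.max_translation_px, mis.max_translation_px),
                rng.uniform(-mis.max_translation_px, mis.max_translation_px),
            ),
            center=center,
        )
        transforms.append(t)

    channels = {}
    for name, ch in stack.channels.items():
        out = np.empty_like(ch.data)
        for i, t in enumerate(transforms):
            out[i] = np.clip(t.warp(ch.data[i]), 0.0, None)
        channels[name] = ChannelVolume(out, ch.role)
    perturbed = SectionStack(channels, stack.geometry, alignment_state="raw")
    return perturbed, transforms
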