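"""Rigid-then-affine alignment of consecutive serial sections.

Pairwise transforms are estimated on a single reference channel
(normalized cross-correlation seeds a rigid fit, which in turn seeds a
mean-squared-error affine refinement), composed against a fixed middle
reference section, and applied identically to every channel.  Pixels
mapped from outside the original frame are filled with zero and flagged
in a validity mask so later density computations can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .core_io import ChannelVolume, SectionStack
from .exceptions import DegenerateImageError, FormatError, RegistrationError

__all__ = ["AffineTransform2D", "AlignmentResult", "estimate_pairwise", "align_stack"]


class AffineTransform2D:
    """2D affine map ``(row, col) -> (row', col')`` stored as a 2x3 matrix.

    The linear part must be invertible; the identity is represented
    exactly by ``np.eye(2)`` and a zero offset.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (2, 3):
            raise FormatError(f"affine matrix must be 2x3, got {matrix.shape}")
        if abs(np.linalg.det(matrix[:, :2])) < 1e-12:
            raise FormatError("affine linear part is singular")
        self.matrix = matrix

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        shear: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Rotation (about ``center``) + shear + translation, in (row, col)."""
        theta = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        sh = np.array([[1.0, shear], [0.0, 1.0]])
        linear = rot @ sh
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float)
        offset = c + t - linear @ c
        return cls(np.hstack([linear, offset[:, None]]))

    # -- accessors ----------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:, 2]

    # -- algebra ------------------------------------------------------
    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        linear = self.linear @ other.linear
        offset = self.linear @ other.offset + self.offset
        return AffineTransform2D(np.hstack([linear, offset[:, None]]))

    def invert(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(np.hstack([inv, (-inv @ self.offset)[:, None]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (row, col) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset

    def is_close_to_identity(self, atol: float = 1e-8) -> bool:
        return np.allclose(self.matrix, AffineTransform2D.identity().matrix, atol=atol)

    # -- resampling ---------------------------------------------------
    def warp(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Resample ``image`` so that ``out(p) = image(T⁻¹ p)``."""
        if self.is_close_to_identity():
            return image.astype(np.float64, copy=True)
        inv = self.invert()
        return ndi.affine_transform(
            np.asarray(image, dtype=np.float64),
            inv.linear,
            offset=inv.offset,
            order=order,
            mode="constant",
            cval=cval,
        )

    def warp_with_mask(self, image: np.ndarray, order: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Warp and return (warped, valid) where valid marks in-frame source pixels."""
        warped = self.warp(image, order=order)
        if self.is_close_to_identity():
            return warped, np.ones(image.shape, dtype=bool)
        ones = np.ones(image.shape, dtype=np.float64)
        support = self.warp(ones, order=order)
        return warped, support > 0.999

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"AffineTransform2D({self.matrix.tolist()})"


@dataclass
class AlignmentResult:
    stack: SectionStack
    transforms: list[AffineTransform2D]
    valid_mask: np.ndarray


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    a = a[mask]
    b = b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _masked_mse(fixed: np.ndarray, warped: np.ndarray, valid: np.ndarray) -> float:
    if valid.sum() < 0.25 * valid.size:
        return np.inf
    diff = fixed[valid] - warped[valid]
    return float(np.mean(diff**2))


def estimate_pairwise(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str = "affine",
    *,
    min_similarity: float = 0.1,
) -> AffineTransform2D:
    """Estimate the transform mapping ``moving`` coordinates into ``fixed``.

    A translation seed from phase correlation is refined by a rigid
    (rotation + translation) MSE fit, which for ``model="affine"`` seeds
    a full 6-parameter refinement.  If the final similarity falls below
    ``min_similarity`` a warning is issued and identity returned.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise FormatError(f"image shapes differ: {fixed.shape} vs {moving.shape}")
    if model not in ("rigid", "affine"):
        raise FormatError(f"unknown model {model!r}")
    if fixed.std() == 0 or moving.std() == 0:
        raise DegenerateImageError("constant image cannot be registered")

    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=20)

    def rigid_cost(x: np.ndarray) -> float:
        t = AffineTransform2D.from_params(
            rotation_deg=x[0], translation=(x[1], x[2]), center=center
        )
        warped, valid = t.warp_with_mask(moving)
        return _masked_mse(fixed, warped, valid)

    res = minimize(
        rigid_cost,
        x0=np.array([0.0, shift[0], shift[1]]),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200},
    )
    transform = AffineTransform2D.from_params(
        rotation_deg=res.x[0], translation=(res.x[1], res.x[2]), center=center
    )

    if model == "affine":
        c = np.asarray(center)
        lin0 = transform.linear
        t0 = transform.apply(c[None])[0] - c

        def affine_cost(x: np.ndarray) -> float:
            linear = lin0 + x[:4].reshape(2, 2)
            offset = c + t0 + x[4:] - linear @ c
            t = AffineTransform2D(np.hstack([linear, offset[:, None]]))
            warped, valid = t.warp_with_mask(moving)
            return _masked_mse(fixed, warped, valid)

        res2 = minimize(
            affine_cost,
            x0=np.zeros(6),
            method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 400},
        )
        if res2.fun <= res.fun:
            linear = lin0 + res2.x[:4].reshape(2, 2)
            offset = c + t0 + res2.x[4:] - linear @ c
            transform = AffineTransform2D(np.hstack([linear, offset[:, None]]))

    warped, valid = transform.warp_with_mask(moving)
    if _ncc(fixed, warped, valid) < min_similarity:
        warnings.warn(
            "pairwise similarity below floor; returning identity transform",
            stacklevel=2,
        )
        return AffineTransform2D.identity()
    return transform


def align_stack(
    stack: SectionStack,
    reference_channel: str | None = None,
    model: str = "affine",
) -> AlignmentResult:
    """Align all sections of ``stack`` to the middle section.

    Transforms are estimated pairwise (section i vs its neighbour toward
    the middle) on ``reference_channel`` and composed; each section's
    composed transform is applied to every channel.
    """
    if reference_channel is None:
        for name, ch in stack.channels.items():
            if ch.role == "synaptic_post":
                reference_channel = name
                break
        else:
            reference_channel = next(iter(stack.channels))
    ref = stack.channel(reference_channel).data
    n = stack.n_sections
    mid = n // 2

    transforms: list[AffineTransform2D | None] = [None] * n
    transforms[mid] = AffineTransform2D.identity()
    for i in range(mid + 1, n):
        try:
            pair = estimate_pairwise(ref[i - 1], ref[i], model=model)
        except DegenerateImageError as exc:
            raise RegistrationError(f"section {i}: {exc}") from exc
        transforms[i] = transforms[i - 1].compose(pair)
    for i in range(mid - 1, -1, -1):
        try:
            pair = estimate_pairwise(ref[i + 1], ref[i], model=model)
        except DegenerateImageError as exc:
            raise RegistrationError(f"section {i}: {exc}") from exc
        transforms[i] = transforms[i + 1].compose(pair)

    valid = np.zeros((n, *stack.frame_shape), dtype=bool)
    channels: dict[str, ChannelVolume] = {}
    for name, ch in stack.channels.items():
        out = np.empty_like(ch.data)
        for i in range(n):
            warped, v = transforms[i].warp_with_mask(ch.data[i])
            out[i] = np.clip(warped, 0.0, None)
            if name == reference_channel:
                valid[i] = v
        channels[name] = ChannelVolume(out, ch.role)

    aligned = SectionStack(
        channels, stack.geometry, alignment_state="aligned", valid_mask=valid
    )
    return AlignmentResult(aligned, list(transforms), valid)


def mean_corner_displacement(
    a: AffineTransform2D, b: AffineTransform2D, frame_shape: tuple[int, int]
) -> float:
    """Mean displacement (px) between two transforms over the frame corners."""
    h, w = frame_shape
    corners = np.array(
        [[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], dtype=float
    )
    return float(np.linalg.norm(a.apply(corners) - b.apply(corners), axis=1).mean())


def save_transforms(transforms: list[AffineTransform2D], path) -> None:
    """Write one flattened 2x3 matrix per line (sidecar text format)."""
    rows = np.array([t.matrix.ravel() for t in transforms])
    np.savetxt(path, rows, fmt="%.10g")


def load_transforms(path) -> list[AffineTransform2D]:
    rows = np.atleast_2d(np.loadtxt(path))
    return [AffineTransform2D(r.reshape(2, 3)) for r in rows]
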