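"""Sensitized-emission FRET: bleed-through calibration and pixel correction.

β (donor-emission crosstalk into the acceptor window) and γ (direct
acceptor excitation by the donor line) are estimated per imaging session
from single-fluorophore control stacks as robust slopes through the
origin.  The raw FRET image is corrected pixelwise as

    Fc = I_DA − β·I_DD − γ·I_AA

with negative values retained (not clipped) so the positivity test keeps
its meaning, and FRET-positive pixels are counted only inside the
triple overlap of donor, acceptor and synaptic object masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .core_io import SectionStack
from .exceptions import CalibrationError, FormatError, SessionMismatchError

__all__ = [
    "FretCalibration",
    "FretImages",
    "estimate_beta",
    "estimate_gamma",
    "estimate_calibration",
    "correct_fret",
    "fret_positive_fraction",
]

MIN_CALIBRATION_PIXELS = 50


@dataclass(frozen=True)
class FretCalibration:
    beta: float
    gamma: float
    diagnostics: dict = field(default_factory=dict)
    session_id: str | None = None

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise CalibrationError("bleed-through coefficients must be non-negative")


@dataclass
class FretImages:
    """The three volumes entering sensitized-emission correction."""

    I_DD: np.ndarray  # donor excitation / donor emission
    I_AA: np.ndarray  # acceptor excitation / acceptor emission
    I_DA: np.ndarray  # donor excitation / acceptor emission (raw FRET)
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.I_DD = np.asarray(self.I_DD, dtype=np.float64)
        self.I_AA = np.asarray(self.I_AA, dtype=np.float64)
        self.I_DA = np.asarray(self.I_DA, dtype=np.float64)
        if not (self.I_DD.shape == self.I_AA.shape == self.I_DA.shape):
            raise FormatError("FRET image volumes must share one shape")

    @classmethod
    def from_stack(
        cls,
        stack: SectionStack,
        session_id: str | None = None,
        subtract_background: bool = True,
    ) -> "FretImages":
        """Extract the three volumes by channel role.

        By default each channel's median (a robust background estimate —
        puncta are sparse) is subtracted so the corrected image is free
        of detector-offset bias; negative values are retained.
        """

        def grab(role: str) -> np.ndarray:
            data = stack.by_role(role).data
            if subtract_background:
                return data - np.median(data)
            return data.copy()

        return cls(
            I_DD=grab("donor"),
            I_AA=grab("acceptor"),
            I_DA=grab("fret_raw"),
            session_id=session_id,
        )


def _robust_origin_slope(
    reference: np.ndarray, signal: np.ndarray, floor: float | None
) -> tuple[float, dict]:
    """Median ratio signal/reference over reference pixels above a floor.

    Each channel's median (background pedestal) is subtracted first, so
    the slope is estimated through the origin of the signal proper.
    Both volumes are lightly smoothed in-plane beforehand: the ratio of
    two identically mixed linear images is slope-invariant, while noise
    on the reference — which otherwise causes a selection/dilution bias
    at the floor — is strongly suppressed.
    """
    reference = np.asarray(reference, dtype=np.float64)
    signal = np.asarray(signal, dtype=np.float64)
    if reference.max() <= 0:
        raise CalibrationError("reference channel is empty (all zero)")
    reference = reference - np.median(reference)
    signal = signal - np.median(signal)
    if reference.ndim == 3:
        reference = ndi.uniform_filter(reference, size=[1, 3, 3])
        signal = ndi.uniform_filter(signal, size=[1, 3, 3])
    reference = reference.ravel()
    signal = signal.ravel()
    if floor is None:
        # Otsu split of the reference channel separates puncta from background.
        floor = float(threshold_otsu(reference))
    sel = reference > floor
    n = int(sel.sum())
    if n < MIN_CALIBRATION_PIXELS:
        raise CalibrationError(
            f"only {n} pixels above floor {floor:.3g}; "
            f"need >= {MIN_CALIBRATION_PIXELS} for calibration"
        )
    ratios = signal[sel] / reference[sel]
    slope = float(np.median(ratios))
    diag = {
        "n_pixels": n,
        "floor": float(floor),
        "ratio_mad": float(np.median(np.abs(ratios - slope))),
    }
    return max(slope, 0.0), diag


def estimate_beta(donor_only: SectionStack, *, floor: float | None = None) -> float:
    """Donor-emission crosstalk coefficient from a donor-only control stack."""
    beta, _ = _robust_origin_slope(
        donor_only.by_role("donor").data, donor_only.by_role("fret_raw").data, floor
    )
    return beta


def estimate_gamma(acceptor_only: SectionStack, *, floor: float | None = None) -> float:
    """Direct-acceptor-excitation coefficient from an acceptor-only stack."""
    gamma, _ = _robust_origin_slope(
        acceptor_only.by_role("acceptor").data,
        acceptor_only.by_role("fret_raw").data,
        floor,
    )
    return gamma


def estimate_calibration(
    donor_only: SectionStack,
    acceptor_only: SectionStack,
    *,
    session_id: str | None = None,
    floor: float | None = None,
) -> FretCalibration:
    beta, diag_b = _robust_origin_slope(
        donor_only.by_role("donor").data, donor_only.by_role("fret_raw").data, floor
    )
    gamma, diag_g = _robust_origin_slope(
        acceptor_only.by_role("acceptor").data,
        acceptor_only.by_role("fret_raw").data,
        floor,
    )
    return FretCalibration(
        beta=beta,
        gamma=gamma,
        diagnostics={"beta": diag_b, "gamma": diag_g},
        session_id=session_id,
    )


def correct_fret(
    images: FretImages,
    calib: FretCalibration,
    *,
    allow_cross_session: bool = False,
) -> np.ndarray:
    """Per-pixel bleed-through correction; negative values are retained.

    Calibrations are session-scoped: applying one to images tagged with
    a different ``session_id`` raises unless explicitly overridden.
    """
    if (
        not allow_cross_session
        and images.session_id is not None
        and calib.session_id is not None
        and images.session_id != calib.session_id
    ):
        raise SessionMismatchError(
            f"calibration from session {calib.session_id!r} applied to "
            f"images from session {images.session_id!r}"
        )
    return images.I_DA - calib.beta * images.I_DD - calib.gamma * images.I_AA


def fret_positive_fraction(
    Fc: np.ndarray,
    donor_mask: np.ndarray,
    acceptor_mask: np.ndarray,
    synapse_mask: np.ndarray,
    *,
    threshold: float = 0.0,
) -> float:
    """Percent of triple-overlap pixels with corrected FRET above threshold.

    ``threshold=0`` is the literal any-signal rule; a positive value
    implements Fc > k·σ screening.  Returns NaN (missing) when no pixel
    is eligible.
    """
    Fc = np.asarray(Fc)
    masks = []
    for m in (donor_mask, acceptor_mask, synapse_mask):
        m = np.asarray(m, dtype=bool)
        if m.shape != Fc.shape:
            raise FormatError("mask shape does not match corrected volume")
        masks.append(m)
    eligible = masks[0] & masks[1] & masks[2]
    n = int(eligible.sum())
    if n == 0:
        return math.nan
    return 100.0 * float((Fc[eligible] > threshold).sum()) / n
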