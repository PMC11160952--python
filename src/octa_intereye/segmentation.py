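"""Global-threshold vessel binarization of en-face angiograms.

The reading-center rule is a single global threshold per image,

    threshold = mean + std_coeff * sd,

where ``mean`` and ``sd`` are the mean and (population) standard deviation of
all pixel values.  A pixel is vessel iff its value is *strictly* greater than
the threshold.  ``std_coeff = 0.5`` segments all perfused vessels;
``std_coeff = 1.3`` keeps only the bright large arcade vessels, whose mask is
used to exclude the macrocirculation from capillary metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

STD_COEFF_ALL_VESSELS = 0.5
STD_COEFF_BIG_VESSELS = 1.3

Plexus = Literal["SCP", "DCP"]
Side = Literal["right", "left"]


@dataclass(frozen=True)
class EnFaceImage:
    """One eye/plexus grayscale en-face angiogram with physical pixel pitch.

    ``pixels`` holds 8-bit intensities (stored as an array, any numeric dtype
    in [0, 255]); ``pixel_pitch`` is the lateral sampling in mm per pixel
    (0.012 mm for a 500-px 6-mm scan).
    """

    pixels: np.ndarray
    pixel_pitch: float
    eye_side: Side = "right"
    plexus: Plexus = "SCP"
    patient_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("en-face image must be a non-empty 2D array")
        if px.shape[0] != px.shape[1]:
            raise ValueError(f"en-face image must be square, got {px.shape}")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class BinarizationParams:
    """Threshold coefficient for ``threshold = mean + std_coeff * sd``."""

    std_coeff: float = STD_COEFF_ALL_VESSELS

    def __post_init__(self) -> None:
        if not self.std_coeff > 0:
            raise ValueError("std_coeff must be positive")


@dataclass(frozen=True)
class BinaryVesselMap:
    """Thresholded vessel mask plus the coefficient that produced it."""

    mask: np.ndarray
    std_coeff_used: float
    source: Literal["all_vessels", "big_vessels"] = "all_vessels"
    threshold: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)

    @property
    def vessel_count(self) -> int:
        return int(self.mask.sum())


def binarize(image: EnFaceImage, params: BinarizationParams | None = None) -> BinaryVesselMap:
    """Threshold an en-face image at ``mean + std_coeff * sd``.

    ``sd`` is the population standard deviation (``ddof=0``) over every pixel
    of the image, with no windowing or preprocessing.  Vessel classification
    uses a strict inequality, so a constant image yields an empty mask.
    """
    if params is None:
        params = BinarizationParams()
    px = image.pixels.astype(np.float64)
    threshold = px.mean() + params.std_coeff * px.std(ddof=0)
    mask = px > threshold
    return BinaryVesselMap(mask=mask, std_coeff_used=params.std_coeff,
                           source="all_vessels", threshold=float(threshold))


def big_vessel_mask(image: EnFaceImage, dilation_radius: int = 0) -> BinaryVesselMap:
    """High-threshold (std_coeff = 1.3) mask of the large arcade vessels.

    The raw threshold mask is optionally dilated by a disc of
    ``dilation_radius`` pixels so the exclusion region covers the full vessel
    caliber and its immediate shadow.
    """
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    raw = binarize(image, BinarizationParams(std_coeff=STD_COEFF_BIG_VESSELS))
    mask = raw.mask
    if dilation_radius > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=disk(dilation_radius))
    return BinaryVesselMap(mask=mask, std_coeff_used=STD_COEFF_BIG_VESSELS,
                           source="big_vessels", threshold=raw.threshold)


def analysis_mask(
    all_vessels: BinaryVesselMap,
    big: Optional[BinaryVesselMap],
    plexus: Plexus = "SCP",
    exclude_projection: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Capillary mask and excluded-area mask for vessel-density measurement.

    SCP: the big-vessel mask is removed from both the vessel mask and the
    measured area, so density reflects the microcirculation only.  DCP: large
    superficial vessels cast projection artifacts onto the deep plexus; when
    ``exclude_projection`` is set the *SCP* big-vessel mask (passed as
    ``big``) is used as the exclusion region, otherwise nothing is excluded.

    Returns ``(capillary_mask, excluded_area_mask)``; the two are disjoint by
    construction.
    """
    av = all_vessels.mask
    if plexus == "SCP":
        exclude = big.mask if big is not None else np.zeros_like(av)
    elif plexus == "DCP":
        exclude = big.mask if (exclude_projection and big is not None) else np.zeros_like(av)
    else:
        raise ValueError(f"unknown plexus {plexus!r}")
    if exclude.shape != av.shape:
        raise ValueError(f"mask shape mismatch: {av.shape} vs {exclude.shape}")
    capillary = av & ~exclude
    return capillary, exclude
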