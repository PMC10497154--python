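"""Skeleton extraction: raw micrograph -> single-pixel network backbone.

The pipeline follows five image-processing stages:

1. top-hat background subtraction with a spherical (grayscale ball)
   structuring element, removing uneven illumination while preserving
   narrow bright features;
2. multi-scale Hessian vesselness enhancement of tubular structures;
3. binarisation at a fixed percentile of the in-ROI intensity
   distribution;
4. removal of small connected components;
5. topology-preserving thinning to a one-pixel-wide skeleton.

Frame normalisation (rotating the cell's long axis onto the horizontal)
runs as a dual path: the skeleton is computed both rotate-last (path A)
and rotate-first (path B) and the two results are OR-combined and
re-thinned, so that neither interpolation route loses pixels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, transform

from .config import ExtractionParams

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "RoiMask",
    "Skeleton",
    "tophat_subtract",
    "enhance_tubular",
    "percentile_threshold",
    "remove_small_components",
    "skeletonise",
    "roi_orientation",
    "extract_skeleton",
]

# 8-connectivity everywhere: required for diagonal continuity of 1-px lines.
CONNECTIVITY = 2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A single-channel fluorescence image (2D) or z-stack (3D).

    ``data`` is ``(y, x)`` or ``(z, y, x)``; ``pixel_size_nm`` is the lateral
    calibration, ``z_spacing_nm`` the inter-plane spacing (None for 2D).
    """

    data: np.ndarray
    pixel_size_nm: float = 95.0
    z_spacing_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("image data must be 2D (y,x) or 3D (z,y,x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("image intensities must be non-negative")
        if self.data.ndim == 3 and self.data.shape[0] < 2:
            raise ValueError("a z-stack needs at least 2 planes")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 3

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    def projection(self) -> np.ndarray:
        """Maximum-intensity projection over z (identity for 2D input)."""
        return self.data.max(axis=0) if self.is_stack else self.data


@dataclass
class RoiMask:
    """Boolean region-of-interest mask matching the image's (y, x) shape."""

    mask: np.ndarray
    provenance: str = "file"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask must contain at least one pixel")
        n_comp = measure.label(self.mask, connectivity=CONNECTIVITY).max()
        if n_comp > 1:
            warnings.warn(
                f"ROI mask has {n_comp} connected regions; expected one",
                stacklevel=2,
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Skeleton:
    """One-pixel-thick binary network backbone in the rotated frame.

    ``binary_rotated`` retains the thresholded (pre-thinning) binary in the
    same frame; filament width is measured on it.
    """

    grid: np.ndarray
    rotation_rad: float = 0.0
    mask_rotated: Optional[np.ndarray] = None
    binary_rotated: Optional[np.ndarray] = None
    source: Optional[ImageStack] = None
    params: Optional[ExtractionParams] = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def _ball_structure(radius: int, flat: bool = False) -> np.ndarray:
    """Height map of a grayscale ball (hemisphere) structuring element.

    ``flat`` returns a zero-height disc instead (rolling-ball-style flat
    opening)."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    r2 = radius**2 - yy**2 - xx**2
    inside = r2 >= 0
    height = np.where(inside, np.sqrt(np.clip(r2, 0, None)), -np.inf)
    if flat:
        height = np.where(inside, 0.0, -np.inf)
    return height


def tophat_subtract(
    image: np.ndarray, radius_px: int, flat: bool = False
) -> np.ndarray:
    """Subtract the grayscale opening with a spherical structuring element.

    Removes smooth background and uneven illumination while keeping
    features narrower than the structuring element.  The radius should be
    well above the widest filament (2–3x its width).
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    size = 2 * radius_px + 1
    if image.shape[0] < size or image.shape[1] < size:
        raise ValueError(
            f"image {image.shape} smaller than the {size}x{size} structuring element"
        )
    height = _ball_structure(radius_px, flat=flat)
    footprint = np.isfinite(height)
    structure = np.where(footprint, height, 0.0)
    opened = ndi.grey_opening(image, footprint=footprint, structure=structure)
    return np.clip(image - opened, 0.0, None)


def enhance_tubular(image: np.ndarray, scales_px) -> np.ndarray:
    """Boost bright ridge-like structures with a multi-scale vesselness filter.

    ``scales_px`` are filament *thicknesses* in pixels; the Hessian is
    evaluated with Gaussian derivatives of sigma = thickness / 6, so the
    +/-3 sigma support of each smoothing kernel spans the probed
    thickness, and the response is the maximum over scales.
    """
    image = np.asarray(image, dtype=float)
    scales = np.asarray(list(scales_px), dtype=float)
    if scales.size == 0:
        raise ValueError("at least one scale required")
    if np.ptp(image) == 0:
        return np.zeros_like(image)
    sigmas = scales / 6.0
    response = filters.frangi(image, sigmas=sigmas, black_ridges=False)
    response = np.clip(response, 0.0, None)
    # noise floor: far-field eigenvalue dust (~1e-9 of the peak) would
    # otherwise survive a percentile threshold of a sparse image; any real
    # bit depth quantises it away
    response[response < 1e-6 * response.max()] = 0.0
    return response


def percentile_threshold(
    image: np.ndarray, mask: np.ndarray, percentile: float
) -> np.ndarray:
    """Binarise at a percentile of the in-ROI intensity distribution.

    Pixels strictly above the percentile value (computed over ROI pixels
    only) are kept; everything outside the ROI is false.  A constant in-ROI
    image yields an all-false result with a warning.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = image[mask]
    if values.max() == values.min():
        warnings.warn("degenerate intensity distribution; empty binary", stacklevel=2)
        return np.zeros_like(mask)
    thresh = np.percentile(values, percentile)
    return (image > thresh) & mask


def remove_small_components(binary: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected components with fewer than ``min_px`` pixels."""
    binary = np.asarray(binary, dtype=bool)
    if min_px <= 1:
        return binary.copy()
    # keep components with >= min_px pixels ("fewer than min_px" removed)
    return morphology.remove_small_objects(
        binary, max_size=min_px - 1, connectivity=CONNECTIVITY
    )


def skeletonise(binary: np.ndarray) -> np.ndarray:
    """Thin a binary image to a single-pixel-wide, topology-preserving skeleton.

    Pixels are iteratively removed from object perimeters until further
    removal would change the number of components or holes (the Euler
    number)."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return binary.copy()
    return morphology.skeletonize(binary)


def roi_orientation(mask: np.ndarray) -> float:
    """Angle (radians) of the ROI's second-moment major axis to the horizontal.

    Computed from the central second moments of the mask (equivalent to the
    orientation of a fitted ellipse), returned in (-pi/2, pi/2] with the
    mathematical sign convention (y up).  A degenerate, isotropic mask
    (equal principal moments) returns 0 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = -(rows - rows.mean())  # flip to y-up
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    if np.isclose(mu20, mu02, rtol=1e-6, atol=1e-9) and np.isclose(
        mu11, 0.0, atol=1e-9 * max(mu20, 1.0)
    ):
        warnings.warn("isotropic ROI: orientation undefined, using 0", stacklevel=2)
        return 0.0
    angle = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return float(angle)


# ---------------------------------------------------------------------------
# Full extraction workflow
# ---------------------------------------------------------------------------


def _rotate_intensity(image: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate an intensity image (bilinear, expanded canvas)."""
    return transform.rotate(
        image, np.degrees(angle_rad), resize=True, order=1, preserve_range=True
    )


def _rotate_binary(binary: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate a binary image (nearest-neighbour, expanded canvas)."""
    out = transform.rotate(
        binary.astype(float),
        np.degrees(angle_rad),
        resize=True,
        order=0,
        preserve_range=True,
    )
    return out > 0.5


def _single_path(
    filtered: np.ndarray, mask: np.ndarray, params: ExtractionParams
) -> tuple[np.ndarray, np.ndarray]:
    """enhance -> threshold -> clean -> thin; returns (skeleton, cleaned binary)."""
    enhanced = enhance_tubular(filtered, params.vesselness_scales_px)
    binary = percentile_threshold(enhanced, mask, params.threshold_percentile)
    binary = remove_small_components(binary, params.min_object_px)
    return skeletonise(binary), binary


def extract_skeleton(
    image: ImageStack | np.ndarray,
    mask: RoiMask | np.ndarray,
    params: Optional[ExtractionParams] = None,
) -> Skeleton:
    """Run the full extraction workflow on an image (or stack) and ROI.

    For a z-stack the 2D pipeline operates on the maximum-intensity
    projection; the stack itself is only consulted later for z estimation.
    When rotation is enabled and the ROI is anisotropic, the dual-path
    workflow runs: path A thins first and rotates the skeleton
    (nearest-neighbour), path B rotates the filtered intensity image
    (bilinear) and thins in the rotated frame; the OR of both is re-thinned.
    """
    if params is None:
        params = ExtractionParams()
    if not isinstance(image, ImageStack):
        image = ImageStack(np.asarray(image))
    if not isinstance(mask, RoiMask):
        mask = RoiMask(np.asarray(mask))
    if mask.mask.shape != image.plane_shape:
        raise ValueError(
            f"ROI shape {mask.mask.shape} does not match image plane "
            f"{image.plane_shape}"
        )

    plane = image.projection()
    filtered = tophat_subtract(plane, params.tophat_radius_px, flat=params.tophat_flat)

    angle = roi_orientation(mask.mask) if params.rotate else 0.0
    logger.debug("extraction: rotation angle %.4f rad", angle)

    if angle == 0.0:
        skel, binary = _single_path(filtered, mask.mask, params)
        mask_rot = mask.mask.copy()
    else:
        # Path A: skeletonise in the native frame, rotate the skeleton.
        skel_a, binary_a = _single_path(filtered, mask.mask, params)
        skel_a = _rotate_binary(skel_a, angle)
        # Path B: rotate the filtered intensity image, then skeletonise.
        rot_filtered = _rotate_intensity(filtered, angle)
        mask_rot = _rotate_binary(mask.mask, angle)
        skel_b, binary_b = _single_path(rot_filtered, mask_rot, params)
        combined = (skel_a | skel_b) & mask_rot
        skel = skeletonise(combined)
        binary = (_rotate_binary(binary_a, angle) | binary_b) & mask_rot

    skel = skel & mask_rot
    if not skel.any():
        warnings.warn("extraction produced an empty skeleton", stacklevel=2)
    return Skeleton(
        grid=skel,
        rotation_rad=angle,
        mask_rotated=mask_rot,
        binary_rotated=binary,
        source=image,
        params=params,
    )
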