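"""Parameter containers and configuration loading.

All tunables of the pipeline live in three small dataclasses:

* :class:`ExtractionParams` — background subtraction, tubular enhancement,
  thresholding and cleanup of the raw image.
* :class:`CurvatureParams` — the physical sampling length used for discrete
  Menger curvature.
* :class:`SceneParams` — the synthetic ground-truth image generator.

Each can be built from a plain dict (and hence from a YAML/JSON config file
via :func:`load_config`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ExtractionParams",
    "CurvatureParams",
    "SceneParams",
    "RunConfig",
    "load_config",
]


@dataclass
class ExtractionParams:
    """Parameters of the skeleton-extraction stage.

    Attributes
    ----------
    tophat_radius_px:
        Radius of the spherical (non-flat) structuring element used for
        top-hat background subtraction.  Should be 2–3 times the width of
        the thickest filament.
    threshold_percentile:
        Percentile of the in-ROI intensity distribution of the
        tubular-enhanced image used as the binarisation threshold.
    min_object_px:
        Connected components (8-connectivity) smaller than this are removed
        before skeletonisation.
    vesselness_scales_px:
        Filament thicknesses, in pixels, probed by the multi-scale
        vesselness filter.
    rotate:
        Whether to normalise the frame so the ROI's major axis is
        horizontal (dual-path rotation workflow).
    tophat_flat:
        Use a flat disc instead of the grayscale ball (rolling-ball style)
        structuring element.
    """

    tophat_radius_px: int = 15
    threshold_percentile: float = 90.0
    min_object_px: int = 20
    vesselness_scales_px: tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0, 14.0)
    rotate: bool = True
    tophat_flat: bool = False

    def __post_init__(self) -> None:
        if self.tophat_radius_px < 1:
            raise ValueError("tophat_radius_px must be >= 1")
        if not 0.0 < self.threshold_percentile < 100.0:
            raise ValueError("threshold_percentile must lie strictly in (0, 100)")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be non-negative")
        scales = tuple(float(s) for s in self.vesselness_scales_px)
        if len(scales) == 0:
            raise ValueError("at least one vesselness scale is required")
        if any(s <= 0 for s in scales):
            raise ValueError("vesselness scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("vesselness scales must be strictly increasing")
        self.vesselness_scales_px = scales


@dataclass
class CurvatureParams:
    """Physical sampling for discrete Menger curvature.

    ``lambda_nm`` is the arc-length separation between the three points of
    each curvature triple; 475 nm equals five pixels at the default 95 nm
    pixel size — large enough to be robust to single-pixel noise, small
    enough to remain a local estimate.
    """

    lambda_nm: float = 475.0
    pixel_size_nm: float = 95.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.lambda_nm < 2 * self.pixel_size_nm:
            raise ValueError("lambda_nm must be at least 2 pixels")

    @property
    def lambda_px(self) -> int:
        """Sampling distance in whole pixel steps along the traced path."""
        return max(1, round(self.lambda_nm / self.pixel_size_nm))


@dataclass
class SceneParams:
    """Synthetic microscopy scene description.

    The generator renders smooth random filaments on a grid supersampled by
    ``supersample`` (default 19, i.e. 5 nm effective pixels at 95 nm/px),
    blurs with a Gaussian PSF, block-averages back to the acquisition grid
    and adds PSF-blurred salt-and-pepper noise.

    ``thickness_nm`` is the rendered filament diameter: 5 nm emulates
    F-actin, 15 nm intermediate filaments, 25 nm microtubules.  ``psf_sigma_nm``
    defaults to the Gaussian approximation of the Airy disc for a 1.35 NA
    lens imaging GFP emission (~509 nm): 0.21 * 509 / 1.35 ~ 79.2 nm.
    """

    shape: tuple[int, int] = (200, 200)
    pixel_size_nm: float = 95.0
    supersample: int = 19
    n_filaments: int = 10
    thickness_nm: float = 5.0
    brightness: float = 1.0
    noise_max: float = 0.0
    noise_density: float = 0.05
    psf_sigma_nm: float = 0.21 * 509.0 / 1.35
    min_separation_frac: float = 0.25
    midpoint_offset_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if self.thickness_nm < self.fine_pixel_nm:
            raise ValueError("thickness_nm must be at least one fine pixel")
        if not 0.0 <= self.noise_density <= 1.0:
            raise ValueError("noise_density must lie in [0, 1]")
        if self.noise_max < 0:
            raise ValueError("noise_max must be non-negative")

    @property
    def fine_pixel_nm(self) -> float:
        """Effective pixel size of the supersampled rendering grid."""
        return self.pixel_size_nm / self.supersample

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.shape[0] * self.supersample, self.shape[1] * self.supersample)


@dataclass
class RunConfig:
    """Top-level configuration for a pipeline run."""

    pixel_size_nm: float = 95.0
    z_spacing_nm: float = 550.0
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    curvature: CurvatureParams = field(default_factory=CurvatureParams)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.z_spacing_nm <= 0:
            raise ValueError("calibration values must be positive")


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file.

    Nested sections ``extraction`` and ``curvature`` override the
    corresponding dataclass fields; unknown keys raise.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = data or {}
    extraction = _build(ExtractionParams, data.pop("extraction", {}) or {})
    curv_raw = dict(data.pop("curvature", {}) or {})
    curv_raw.setdefault("pixel_size_nm", data.get("pixel_size_nm", 95.0))
    curvature = _build(CurvatureParams, curv_raw)
    cfg = _build(RunConfig, data)
    cfg.extraction = extraction
    cfg.curvature = curvature
    return cfg
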