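"""File input/output: TIFF images, ROI masks, result tables and sidecars.

Images are single-channel TIFFs, either one page (2D) or multi-page
(z-stack, page order = z order).  ROI masks come as binary TIFF/PNG of
the same lateral shape, or as a JSON polygon sidecar (a list of 0-based
``[row, col]`` vertices) rasterised with even-odd fill.  Every written
output gets a JSON sidecar recording the package version, a hash of the
configuration, and the seed where randomness was involved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from skimage import draw, io as skio

from . import __version__
from .config import RunConfig
from .extraction import ImageStack, RoiMask, Skeleton
from .labelling import LabelledNetwork
from .measures import MEASURE_CODES, MeasureSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "read_roi",
    "polygon_mask",
    "write_skeleton",
    "write_labels",
    "write_measures",
    "write_scene",
    "config_hash",
]


def read_image(
    path: str | Path,
    pixel_size_nm: float = 95.0,
    z_spacing_nm: Optional[float] = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Multi-sample (RGB) data is rejected: the pipeline expects one
    fluorescence channel.  Calibration comes from the arguments (a config
    overrides any TIFF tags).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise ValueError(
            f"{path} looks like RGB(A) data; a single-channel image is required"
        )
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: expected 2D or 3D data, got shape {data.shape}")
    return ImageStack(
        data=np.asarray(data, dtype=float),
        pixel_size_nm=pixel_size_nm,
        z_spacing_nm=z_spacing_nm if data.ndim == 3 else None,
    )


def polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a polygon ([row, col] vertex list, 0-based) to a mask."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("polygon needs at least 3 [row, col] vertices")
    return draw.polygon2mask(shape, vertices)


def read_roi(path: str | Path, image_shape: tuple[int, int]) -> RoiMask:
    """Read an ROI as a binary image file or a JSON polygon sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        vertices = data["polygon"] if isinstance(data, dict) else data
        mask = polygon_mask(vertices, image_shape)
        provenance = "polygon"
    else:
        raw = skio.imread(path)
        if raw.ndim == 3:
            raw = raw[..., 0]
        mask = np.asarray(raw) > 0
        provenance = "file"
    if mask.shape != tuple(image_shape):
        raise ValueError(
            f"ROI shape {mask.shape} does not match image shape {tuple(image_shape)}"
        )
    return RoiMask(mask=mask, provenance=provenance)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _sidecar(path: Path, payload: dict) -> None:
    meta = {"version": __version__, **payload}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def write_skeleton(path: str | Path, skeleton: Skeleton, config=None) -> None:
    """Write the skeleton as an 8-bit binary TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, (skeleton.grid.astype(np.uint8)) * 255)
    _sidecar(
        path,
        {
            "rotation_rad": skeleton.rotation_rad,
            "params": dataclasses.asdict(skeleton.params) if skeleton.params else None,
            "config_hash": config_hash(config) if config is not None else None,
        },
    )


def write_labels(path: str | Path, network: LabelledNetwork, config=None) -> None:
    """Write the 16-bit label image plus branch points / paths as JSON."""
    path = Path(path)
    tifffile.imwrite(path, network.labels.astype(np.uint16))
    payload = {
        "n_filaments": network.n_filaments,
        "branch_points": [
            {
                "coord": list(bp.coord),
                "filaments": sorted(bp.filaments),
                "main": bp.main,
            }
            for bp in network.branch_points
        ],
        "paths": {
            str(fid): np.asarray(p).tolist() for fid, p in network.paths.items()
        },
        "config_hash": config_hash(config) if config is not None else None,
    }
    _sidecar(path, payload)


def write_measures(
    out_dir: str | Path, measures: MeasureSet, stem: str = "measures", config=None
) -> dict[str, Path]:
    """Write per-cell and per-filament CSVs and the 17-measure JSON.

    The JSON carries exactly the seventeen measure codes; the per-cell CSV
    holds the scalar measures, the per-filament CSV one row per filament
    (list-valued measures).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = measures.to_dict()
    assert tuple(d) == MEASURE_CODES

    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(d, indent=2))

    cell_cols = {
        k: [d[k]]
        for k in ("cellSize", "orientation", "skelDensity", "branchRatio",
                  "cellBPDensity", "avgLen")
    }
    cell_cols["nStructures"] = [len(d["Structures"])]
    cell_path = out_dir / f"{stem}_cell.csv"
    pd.DataFrame(cell_cols).to_csv(cell_path, index=False)

    fil_rows = []
    for m in measures.filaments:
        fil_rows.append(
            {
                "filament": m.filament_id,
                "filWidth": m.width_nm,
                "filLenXY": m.length_2d_nm,
                "filLenXYZ": m.length_3d_nm,
                "filamentAng.angXY": m.angle_2d,
                "filamentAng.angZ": m.angle_z,
                "curvatureSigned": m.curvature_signed,
                "curvature": m.curvature_unsigned,
                "deviation": m.deviation_nm,
            }
        )
    fil_path = out_dir / f"{stem}_filaments.csv"
    pd.DataFrame(fil_rows).to_csv(fil_path, index=False)
    _sidecar(json_path, {"config_hash": config_hash(config) if config is not None else None})
    return {"json": json_path, "cell": cell_path, "filaments": fil_path}


def write_scene(out_dir: str | Path, scene, stem: str) -> dict[str, Path]:
    """Write a synthetic scene: image TIFF, truth TIFF, JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.tif"
    truth_path = out_dir / f"{stem}_truth.tif"
    tifffile.imwrite(img_path, scene.image.astype(np.float32))
    tifffile.imwrite(truth_path, scene.truth.astype(np.uint8) * 255)
    manifest = {
        "seed": scene.seed,
        "snr": scene.snr,
        "params": dataclasses.asdict(scene.params),
        "arclengths_nm": scene.arclengths_nm,
        "version": __version__,
    }
    man_path = out_dir / f"{stem}.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return {"image": img_path, "truth": truth_path, "manifest": man_path}
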