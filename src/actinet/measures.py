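"""Quantitative network measures.

Seventeen per-cell / per-filament quantities characterise an extracted,
labelled actin network, grouped as: whole-cell properties (ROI size, cell
orientation), overall network properties (skeleton density, structure
sizes, branch ratio, branch-point density), individual filament
properties (width, 2D/3D length, 2D/z angles, average length), curvature
properties (signed and unsigned Menger curvature over a physical scale
lambda, deviation from the endpoint chord) and branching properties
(2D/3D branch angles).

Lengths are reported in nm, angles in radians, curvatures in 1/nm.
z positions are estimated from the brightest plane of the stack at each
skeleton pixel; the 3D length is the 2D length divided by cos(theta_z).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import measure as skmeasure, transform

from .config import CurvatureParams
from .extraction import CONNECTIVITY, ImageStack, RoiMask, Skeleton, roi_orientation
from .labelling import DIRECTION_WINDOW, BranchPoint, LabelledNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURE_CODES",
    "FilamentMeasures",
    "MeasureSet",
    "roi_size",
    "skeleton_density",
    "structure_sizes",
    "branch_ratio",
    "branch_point_density",
    "filament_length_2d",
    "estimate_z",
    "filament_angle_2d",
    "filament_angle_3d",
    "filament_length_3d",
    "menger_curvature",
    "filament_curvature",
    "filament_deviation",
    "filament_width",
    "branch_angle_2d",
    "branch_angle_3d",
    "compute_all",
]

#: Output codes of the seventeen measures, in reporting order.
MEASURE_CODES = (
    "cellSize",
    "orientation",
    "skelDensity",
    "Structures",
    "branchRatio",
    "cellBPDensity",
    "filWidth",
    "filLenXY",
    "filLenXYZ",
    "filamentAng.angXY",
    "filamentAng.angZ",
    "avgLen",
    "curvatureSigned",
    "curvature",
    "deviation",
    "branchAng.angXY",
    "branchAng.angZ",
)

# theta_z is capped here before dividing the 2D length by cos(theta_z):
# the coarse brightest-plane z estimate makes near-vertical angles
# numerically explosive.
THETA_Z_CAP = math.radians(85.0)

# filament-width rays stop after this many pixels so a wide neighbouring
# structure cannot masquerade as local width.
WIDTH_RAY_CAP_PX = 30.0


@dataclass
class FilamentMeasures:
    """Per-filament measurements (lengths nm, angles rad, curvature 1/nm)."""

    filament_id: int
    width_px: float
    width_nm: float
    length_2d_nm: float
    length_3d_nm: float
    angle_2d: float
    angle_z: float
    curvature_signed: Optional[float]
    curvature_unsigned: Optional[float]
    deviation_nm: float
    mean_intensity: Optional[float] = None
    theta_z_capped: bool = False


@dataclass
class MeasureSet:
    """The full set of seventeen network measures for one image."""

    cell_size_px: int
    orientation_rad: float
    skeleton_density: float
    structure_sizes: list[int]
    branch_ratio: float
    branch_point_density: float
    filaments: list[FilamentMeasures]
    branch_angles_2d: list[float]
    branch_angles_3d: list[float]
    avg_length_nm: float
    skeleton_density_per_volume: Optional[float] = None
    branch_point_density_per_volume: Optional[float] = None

    def to_dict(self) -> dict:
        """The seventeen measures keyed by their output codes."""
        f = self.filaments
        return {
            "cellSize": self.cell_size_px,
            "orientation": self.orientation_rad,
            "skelDensity": self.skeleton_density,
            "Structures": list(self.structure_sizes),
            "branchRatio": self.branch_ratio,
            "cellBPDensity": self.branch_point_density,
            "filWidth": [m.width_nm for m in f],
            "filLenXY": [m.length_2d_nm for m in f],
            "filLenXYZ": [m.length_3d_nm for m in f],
            "filamentAng.angXY": [m.angle_2d for m in f],
            "filamentAng.angZ": [m.angle_z for m in f],
            "avgLen": self.avg_length_nm,
            "curvatureSigned": [
                m.curvature_signed for m in f if m.curvature_signed is not None
            ],
            "curvature": [
                m.curvature_unsigned for m in f if m.curvature_unsigned is not None
            ],
            "deviation": [m.deviation_nm for m in f],
            "branchAng.angXY": list(self.branch_angles_2d),
            "branchAng.angZ": list(self.branch_angles_3d),
        }


# ---------------------------------------------------------------------------
# Whole-cell and overall network properties
# ---------------------------------------------------------------------------


def roi_size(mask: RoiMask | np.ndarray) -> int:
    """Number of pixels in the region of interest."""
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, bool)
    return int(m.sum())


def skeleton_density(
    skeleton: Skeleton | np.ndarray,
    mask: RoiMask | np.ndarray,
    n_planes: Optional[int] = None,
    z_spacing_nm: Optional[float] = None,
) -> float:
    """Skeleton pixels divided by ROI pixels (optionally per volume).

    With ``n_planes`` and ``z_spacing_nm`` given, returns the per-volume
    variant: skeleton pixels / (ROI pixels * imaged depth in nm).
    """
    grid = skeleton.grid if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    n_roi = roi_size(mask)
    if n_roi == 0:
        raise ValueError("empty ROI")
    density = float(grid.sum()) / n_roi
    if n_planes is not None and z_spacing_nm is not None:
        return density / (n_planes * z_spacing_nm)
    return density


def structure_sizes(skeleton: Skeleton | np.ndarray) -> list[int]:
    """Pixel counts of the skeleton's 8-connected components."""
    grid = skeleton.grid if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    labels = skmeasure.label(grid, connectivity=CONNECTIVITY)
    if labels.max() == 0:
        return []
    return np.bincount(labels.ravel())[1:].tolist()


def branch_ratio(network: LabelledNetwork) -> float:
    """Branch points per labelled filament (0 for an unbranched network)."""
    if network.n_filaments == 0:
        return 0.0
    return network.n_branch_points / network.n_filaments


def branch_point_density(
    network: LabelledNetwork,
    mask: RoiMask | np.ndarray,
    n_planes: Optional[int] = None,
    z_spacing_nm: Optional[float] = None,
    per_branched_length: bool = False,
    pixel_size_nm: float = 95.0,
) -> float:
    """Branch points divided by ROI size (or by volume when 3D info given).

    ``per_branched_length`` switches to the alternative normalisation by
    the summed length (nm) of filaments that carry at least one branch
    point, instead of the ROI area.
    """
    n_bp = network.n_branch_points
    if per_branched_length:
        branched = {f for bp in network.branch_points for f in bp.filaments}
        total = sum(
            filament_length_2d(network.paths[f], pixel_size_nm)
            for f in branched
            if f in network.paths
        )
        return n_bp / total if total > 0 else 0.0
    n_roi = roi_size(mask)
    if n_roi == 0:
        raise ValueError("empty ROI")
    if n_planes is not None and z_spacing_nm is not None:
        return n_bp / (n_roi * n_planes * z_spacing_nm)
    return n_bp / n_roi


# ---------------------------------------------------------------------------
# Individual filament properties
# ---------------------------------------------------------------------------


def _diagonal_steps(path: np.ndarray) -> int:
    steps = np.abs(np.diff(path, axis=0))
    return int(np.sum((steps[:, 0] > 0) & (steps[:, 1] > 0)))


def filament_length_2d(path: np.ndarray, pixel_size_nm: float) -> float:
    """In-plane filament length in nm.

    Counts path pixels and adds (sqrt(2) - 1) for every diagonal step, so
    a diagonal connection costs sqrt(2) pixels in total.
    """
    path = np.asarray(path)
    n = len(path)
    d = _diagonal_steps(path)
    return (n + (math.sqrt(2.0) - 1.0) * d) * pixel_size_nm


def estimate_z(
    path: np.ndarray, stack: ImageStack, rotation_rad: float = 0.0
) -> np.ndarray:
    """Per-pixel z position (nm) from the brightest plane of the stack.

    The path lives in the rotated frame; each plane of the stack is mapped
    into that frame before the arg-max over z.  Ties take the lowest plane
    index.  For 2D input an all-zero array is returned.
    """
    path = np.asarray(path)
    if not stack.is_stack:
        return np.zeros(len(path))
    if rotation_rad != 0.0:
        planes = np.stack(
            [
                transform.rotate(
                    p, math.degrees(rotation_rad), resize=True, order=1,
                    preserve_range=True,
                )
                for p in stack.data
            ]
        )
    else:
        planes = stack.data
    dz = stack.z_spacing_nm if stack.z_spacing_nm is not None else 1.0
    rows = np.clip(path[:, 0], 0, planes.shape[1] - 1)
    cols = np.clip(path[:, 1], 0, planes.shape[2] - 1)
    profiles = planes[:, rows, cols]  # (z, n)
    return np.argmax(profiles, axis=0).astype(float) * dz


def filament_angle_2d(path: np.ndarray) -> float:
    """Endpoint-to-endpoint angle to the horizontal axis, in (-pi/2, pi/2].

    Row axis points down in image coordinates; the sign follows the
    mathematical convention after flipping to y-up.  Vertical filaments
    get +pi/2.
    """
    path = np.asarray(path)
    dr = float(path[-1, 0] - path[0, 0])
    dc = float(path[-1, 1] - path[0, 1])
    dx, dy = dc, -dr
    if dx == 0 and dy == 0:
        return 0.0
    angle = math.atan2(dy, dx)
    if angle <= -math.pi / 2:
        angle += math.pi
    elif angle > math.pi / 2:
        angle -= math.pi
    if angle == -math.pi / 2:
        angle = math.pi / 2
    return angle


def filament_angle_3d(
    path: np.ndarray, z_nm: np.ndarray, pixel_size_nm: float
) -> tuple[float, bool]:
    """Angle of the filament to the imaging plane from endpoint displacement.

    Returns ``(theta_z, capped)``; theta_z is capped at 85 degrees when the
    in-plane endpoint separation is too small to support the z rise.
    """
    path = np.asarray(path)
    z_nm = np.asarray(z_nm, dtype=float)
    dz = abs(z_nm[-1] - z_nm[0])
    d2d = float(np.hypot(*(path[-1] - path[0]).astype(float))) * pixel_size_nm
    if d2d == 0:
        return (THETA_Z_CAP, True) if dz > 0 else (0.0, False)
    theta = math.atan2(dz, d2d)
    if theta > THETA_Z_CAP:
        return THETA_Z_CAP, True
    return theta, False


def filament_length_3d(length_2d_nm: float, theta_z: float) -> float:
    """3D length estimate: the 2D length divided by cos(theta_z)."""
    return length_2d_nm / math.cos(min(theta_z, THETA_Z_CAP))


# ---------------------------------------------------------------------------
# Curvature properties
# ---------------------------------------------------------------------------


def menger_curvature(p1, p2, p3) -> float:
    """Signed Menger curvature of three points: 1 / circumradius.

    kappa = 4 * signed_area / (|p1p2| |p2p3| |p1p3|); the sign encodes the
    turn orientation, collinear points give 0.  Point units set the output
    units (points in nm -> curvature in 1/nm).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if a == 0 or b == 0 or c == 0:
        return 0.0
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return float(2.0 * cross / (a * b * c))


def filament_curvature(
    path: np.ndarray, params: CurvatureParams
) -> tuple[Optional[float], Optional[float]]:
    """(signed, unsigned) mean Menger curvature of a filament, in 1/nm.

    For every interior pixel the two flanking points are taken as close to
    lambda away *along the path* as possible (the endpoint itself when the
    pixel is nearer than lambda to it).  The signed value is the absolute
    mean of the signed curvatures — bends in opposite directions cancel —
    while the unsigned value is the mean magnitude.  Paths shorter than 3
    pixels have no defined curvature (returns (None, None)).
    """
    path = np.asarray(path, dtype=float)
    n = len(path)
    if n < 3:
        return None, None
    step = params.lambda_px
    pts = path * params.pixel_size_nm
    kappas = np.empty(n - 2)
    for i in range(1, n - 1):
        j = max(0, i - step)
        k = min(n - 1, i + step)
        kappas[i - 1] = menger_curvature(pts[j], pts[i], pts[k])
    return float(abs(kappas.mean())), float(np.abs(kappas).mean())


def filament_deviation(path: np.ndarray, pixel_size_nm: float) -> float:
    """Mean perpendicular distance (nm) of path pixels to the endpoint chord."""
    path = np.asarray(path, dtype=float)
    if len(path) < 3:
        return 0.0
    p0, p1 = path[0], path[-1]
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        # closed loop: fall back to distance from the start point
        d = np.linalg.norm(path - p0, axis=1)
    else:
        rel = path - p0
        d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    return float(d.mean()) * pixel_size_nm


# ---------------------------------------------------------------------------
# Filament width
# ---------------------------------------------------------------------------


def _ray_run_length(binary: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    """Contiguous true run through origin along +/-direction, in pixels."""
    h, w = binary.shape
    length = 1.0  # the origin pixel itself
    for sign in (1.0, -1.0):
        t = 1.0
        while t <= WIDTH_RAY_CAP_PX:
            r = origin[0] + sign * direction[0] * t
            c = origin[1] + sign * direction[1] * t
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w) or not binary[ri, ci]:
                break
            t += 1.0
        length += t - 1.0
    return length


def filament_width(path: np.ndarray, binary: np.ndarray) -> float:
    """Mean filament width in pixels.

    At every path pixel the local tangent is estimated from neighbouring
    path points and the run of true pixels in the pre-thinning binary is
    measured perpendicular to it; the widths are averaged along the path.
    """
    path = np.asarray(path, dtype=float)
    binary = np.asarray(binary, bool)
    n = len(path)
    if n == 1:
        return 1.0
    widths = np.empty(n)
    for i in range(n):
        a = path[max(0, i - 2)]
        b = path[min(n - 1, i + 2)]
        tangent = b - a
        norm = np.linalg.norm(tangent)
        if norm == 0:
            widths[i] = 1.0
            continue
        perp = np.array([-tangent[1], tangent[0]]) / norm
        widths[i] = _ray_run_length(binary, path[i], perp)
    return float(widths.mean())


# ---------------------------------------------------------------------------
# Branching properties
# ---------------------------------------------------------------------------


def _outgoing_direction(
    path: np.ndarray, junction: tuple[int, int], window: int = DIRECTION_WINDOW
) -> Optional[np.ndarray]:
    """Unit vector leaving the junction along the filament (2D, row/col)."""
    path = np.asarray(path)
    d_start = np.max(np.abs(path[0] - junction))
    d_end = np.max(np.abs(path[-1] - junction))
    j = np.array(junction, dtype=float)
    # walk from whichever end touches the junction
    if d_start <= d_end:
        target = path[min(window, len(path) - 1)].astype(float)
    else:
        target = path[max(0, len(path) - 1 - window)].astype(float)
    v = target - j
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def _vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    cosang = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return math.acos(cosang)


def branch_angle_2d(bp: BranchPoint, network: LabelledNetwork) -> list[float]:
    """Deviation angles a motor on the main filament would turn through to
    take each branch at this junction; in [0, pi].

    The main filament's two arms leave the junction in (roughly) opposite
    directions; for each branch the deviation is the angle between the
    branch's outgoing direction and the *nearer* main outgoing direction —
    the continuation a motor arriving along the other arm would follow.
    Junctions without a resolved main filament or without branches yield
    no angles.
    """
    dirs = _junction_directions(bp, network)
    if dirs is None:
        return []
    main_dirs, branch_dirs = dirs
    return [
        min(_vector_angle(b, m) for m in main_dirs) for b in branch_dirs
    ]


def branch_angle_3d(
    bp: BranchPoint,
    network: LabelledNetwork,
    z_by_filament: dict[int, np.ndarray],
    pixel_size_nm: float,
) -> list[float]:
    """3D deviation branch angles using per-pixel z estimates.

    The angle is evaluated in the plane spanned by the two filament
    centre-lines: the junction and the window points of the main and
    branch arms are lifted to 3D (z from the brightest-plane estimate),
    pairwise distances are formed and the interior angle at the junction
    follows from the law of cosines; the reported value is its deviation
    from a straight continuation (pi - interior), minimised over the two
    main arms.  A flat network reproduces the 2D angles.
    """
    pts = _junction_points_3d(bp, network, z_by_filament, pixel_size_nm)
    if pts is None:
        return []
    j3, main_pts, branch_pts = pts
    out = []
    for b in branch_pts:
        devs = []
        for m in main_pts:
            da = np.linalg.norm(b - j3)
            db = np.linalg.norm(m - j3)
            dc = np.linalg.norm(b - m)
            if da == 0 or db == 0:
                continue
            cosang = (da**2 + db**2 - dc**2) / (2 * da * db)
            interior = math.acos(float(np.clip(cosang, -1, 1)))
            devs.append(interior)
        if devs:
            out.append(min(devs))
    return out


def _junction_directions(bp: BranchPoint, network: LabelledNetwork):
    if bp.main is None or bp.main not in network.paths:
        return None
    branch_ids = [f for f in bp.filaments if f != bp.main and f in network.paths]
    if not branch_ids:
        return None
    main_path = network.paths[bp.main]
    main_dirs = _main_arm_directions(main_path, bp.coord)
    if not main_dirs:
        return None
    branch_dirs = []
    for f in branch_ids:
        d = _outgoing_direction(network.paths[f], bp.coord)
        if d is not None:
            branch_dirs.append(d)
    if not branch_dirs:
        return None
    return main_dirs, branch_dirs


def _main_arm_directions(
    main_path: np.ndarray, junction: tuple[int, int], window: int = DIRECTION_WINDOW
) -> list[np.ndarray]:
    """Outgoing directions of the two arms of the through-filament."""
    path = np.asarray(main_path)
    j = np.array(junction)
    idx = int(np.argmin(np.max(np.abs(path - j), axis=1)))
    dirs = []
    for target_idx in (min(idx + window, len(path) - 1), max(idx - window, 0)):
        if target_idx == idx:
            continue
        v = path[target_idx].astype(float) - j.astype(float)
        n = np.linalg.norm(v)
        if n > 0:
            dirs.append(v / n)
    return dirs


def _junction_points_3d(bp, network, z_by_filament, pixel_size_nm, window=DIRECTION_WINDOW):
    if bp.main is None or bp.main not in network.paths:
        return None
    branch_ids = [f for f in bp.filaments if f != bp.main and f in network.paths]
    if not branch_ids:
        return None
    main_path = np.asarray(network.paths[bp.main])
    j = np.array(bp.coord)
    idx = int(np.argmin(np.max(np.abs(main_path - j), axis=1)))
    z_main = z_by_filament.get(bp.main)
    if z_main is None:
        return None
    j3 = np.array([*(j * pixel_size_nm), z_main[idx]])
    main_pts = []
    for t in (min(idx + window, len(main_path) - 1), max(idx - window, 0)):
        if t == idx:
            continue
        main_pts.append(np.array([*(main_path[t] * pixel_size_nm), z_main[t]]))
    branch_pts = []
    for f in branch_ids:
        p = np.asarray(network.paths[f])
        zf = z_by_filament.get(f)
        if zf is None:
            continue
        d_start = np.max(np.abs(p[0] - j))
        d_end = np.max(np.abs(p[-1] - j))
        t = min(window, len(p) - 1) if d_start <= d_end else max(0, len(p) - 1 - window)
        if np.all(p[t] == j):
            warnings.warn("zero-length branch at junction; omitted", stacklevel=2)
            continue
        branch_pts.append(np.array([*(p[t] * pixel_size_nm), zf[t]]))
    if not main_pts or not branch_pts:
        return None
    return j3, main_pts, branch_pts


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def compute_all(
    network: LabelledNetwork,
    mask: RoiMask | np.ndarray,
    stack: Optional[ImageStack] = None,
    curvature_params: Optional[CurvatureParams] = None,
    z_spacing_nm: Optional[float] = None,
) -> MeasureSet:
    """Compute the full set of seventeen measures for one network.

    ``stack`` supplies z information (and intensities); without it all z
    angles are 0 and 3D quantities coincide with their 2D counterparts.
    """
    if curvature_params is None:
        curvature_params = CurvatureParams()
    px = curvature_params.pixel_size_nm
    skel = network.skeleton
    if skel is None:
        raise ValueError("network has no skeleton attached")
    mask_obj = mask if isinstance(mask, RoiMask) else RoiMask(np.asarray(mask, bool))

    is_3d = stack is not None and stack.is_stack
    if is_3d and z_spacing_nm is None:
        z_spacing_nm = stack.z_spacing_nm

    binary = skel.binary_rotated if skel.binary_rotated is not None else skel.grid

    z_by_filament: dict[int, np.ndarray] = {}
    filaments: list[FilamentMeasures] = []
    for fid, path in network.paths.items():
        z = (
            estimate_z(path, stack, skel.rotation_rad)
            if is_3d
            else np.zeros(len(path))
        )
        z_by_filament[fid] = z
        len2d = filament_length_2d(path, px)
        theta_z, capped = filament_angle_3d(path, z, px)
        signed, unsigned = filament_curvature(path, curvature_params)
        w_px = filament_width(path, binary)
        intensity = None
        if stack is not None:
            proj = stack.projection()
            rr = np.clip(path[:, 0], 0, proj.shape[0] - 1)
            cc = np.clip(path[:, 1], 0, proj.shape[1] - 1)
            if skel.rotation_rad == 0.0:
                intensity = float(proj[rr, cc].mean())
        filaments.append(
            FilamentMeasures(
                filament_id=fid,
                width_px=w_px,
                width_nm=w_px * px,
                length_2d_nm=len2d,
                length_3d_nm=filament_length_3d(len2d, theta_z),
                angle_2d=filament_angle_2d(path),
                angle_z=theta_z,
                curvature_signed=signed,
                curvature_unsigned=unsigned,
                deviation_nm=filament_deviation(path, px),
                mean_intensity=intensity,
                theta_z_capped=capped,
            )
        )

    angles_2d: list[float] = []
    angles_3d: list[float] = []
    for bp in network.branch_points:
        angles_2d.extend(branch_angle_2d(bp, network))
        angles_3d.extend(
            branch_angle_3d(bp, network, z_by_filament, px)
            if is_3d
            else branch_angle_2d(bp, network)
        )

    n_planes = stack.data.shape[0] if is_3d else None
    lengths_3d = [m.length_3d_nm for m in filaments]
    return MeasureSet(
        cell_size_px=roi_size(mask_obj),
        orientation_rad=skel.rotation_rad,
        skeleton_density=skeleton_density(skel, mask_obj),
        structure_sizes=structure_sizes(skel),
        branch_ratio=branch_ratio(network),
        branch_point_density=branch_point_density(network, mask_obj),
        filaments=filaments,
        branch_angles_2d=angles_2d,
        branch_angles_3d=angles_3d,
        avg_length_nm=float(np.mean(lengths_3d)) if lengths_3d else 0.0,
        skeleton_density_per_volume=(
            skeleton_density(skel, mask_obj, n_planes, z_spacing_nm) if is_3d else None
        ),
        branch_point_density_per_volume=(
            branch_point_density(network, mask_obj, n_planes, z_spacing_nm)
            if is_3d
            else None
        ),
    )
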