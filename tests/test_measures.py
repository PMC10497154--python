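"""Oracle and property tests for the seventeen network measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actinet import (
    CurvatureParams,
    ImageStack,
    MEASURE_CODES,
    compute_all,
    extract_skeleton,
    generate_scene,
    label_filaments,
    menger_curvature,
    SceneParams,
)
from actinet.measures import (
    branch_angle_2d,
    branch_angle_3d,
    branch_point_density,
    branch_ratio,
    estimate_z,
    filament_angle_2d,
    filament_angle_3d,
    filament_curvature,
    filament_deviation,
    filament_length_2d,
    filament_length_3d,
    filament_width,
    roi_size,
    skeleton_density,
    structure_sizes,
)
from tests.conftest import draw_line

PX = 95.0


# ---------------------------------------------------------------------------
# whole-cell / overall network scalars
# ---------------------------------------------------------------------------


def test_roi_size_counts_true_pixels():
    mask = np.zeros((10, 10), bool)
    mask[:5, :] = True
    assert roi_size(np.ones((10, 10), bool)) == 100
    assert roi_size(mask) == 50


def test_skeleton_density_ratio_and_scaling():
    skel = np.zeros((40, 25), bool)
    skel[5, :25] = True
    skel[9, :25] = True
    mask = np.ones((40, 25), bool)
    assert skeleton_density(skel, mask) == pytest.approx(50 / 1000)
    assert skeleton_density(np.zeros_like(skel), mask) == 0.0
    # doubling the ROI with the same skeleton halves the density
    big = np.zeros((80, 25), bool)
    big[5, :25] = True
    big[9, :25] = True
    assert skeleton_density(big, np.ones((80, 25), bool)) == pytest.approx(25 / 1000)
    # invariance under rotating both grids by 90 degrees
    assert skeleton_density(np.rot90(skel), np.rot90(mask)) == pytest.approx(0.05)


def test_structure_sizes_components():
    grid = np.zeros((30, 40), bool)
    grid[5, 0:10] = True
    grid[20, 0:20] = True
    assert sorted(structure_sizes(grid)) == [10, 20]
    assert structure_sizes(np.zeros((5, 5), bool)) == []
    assert structure_sizes(grid[:10]) == [10]


def test_branch_ratio_t_network(t_skeleton):
    net = label_filaments(t_skeleton)
    assert branch_ratio(net) == pytest.approx(0.5)  # 1 bp / 2 filaments


def test_branch_point_density_per_area(t_skeleton):
    net = label_filaments(t_skeleton)
    mask = np.ones(t_skeleton.shape, bool)
    assert branch_point_density(net, mask) == pytest.approx(1 / 900)
    # alternative normalisation by branched-filament length (smoke)
    alt = branch_point_density(net, mask, per_branched_length=True, pixel_size_nm=PX)
    assert alt > 0


# ---------------------------------------------------------------------------
# lengths and angles
# ---------------------------------------------------------------------------


def test_length_2d_examples():
    horizontal = np.array([(5, c) for c in range(10)])
    assert filament_length_2d(horizontal, PX) == pytest.approx(950.0)
    diagonal = np.array([(i, i) for i in range(5)])
    expected = (5 + 4 * (math.sqrt(2) - 1)) * PX
    assert filament_length_2d(diagonal, PX) == pytest.approx(expected)
    assert filament_length_2d(np.array([(3, 3)]), PX) == pytest.approx(95.0)


def test_angle_2d_examples():
    assert filament_angle_2d(np.array([(5, 0), (5, 9)])) == pytest.approx(0.0)
    # rows increase downward: (0,0)->(10,10) points down-right = -45 deg in y-up
    diag = np.array([(i, i) for i in range(11)])
    assert filament_angle_2d(diag) == pytest.approx(-math.pi / 4)
    up = np.array([(i, 10 - i) for i in range(11)])
    assert filament_angle_2d(up) == pytest.approx(math.pi / 4)
    vertical = np.array([(i, 4) for i in range(8)])
    assert filament_angle_2d(vertical) == pytest.approx(math.pi / 2)


def test_angle_3d_and_length_3d():
    path = np.array([(0, 0), (0, 10)])
    z = np.array([0.0, 550.0])
    theta, capped = filament_angle_3d(path, z, PX)
    assert not capped
    assert math.degrees(theta) == pytest.approx(math.degrees(math.atan(550 / 950)), abs=1e-6)
    # flat filament: 3D length equals 2D length
    assert filament_length_3d(950.0, 0.0) == pytest.approx(950.0)
    # 60 degrees doubles the length
    assert filament_length_3d(950.0, math.radians(60)) == pytest.approx(1900.0)


def test_angle_3d_caps_degenerate_vertical():
    path = np.array([(0, 0), (0, 0)])
    theta, capped = filament_angle_3d(path, np.array([0.0, 1100.0]), PX)
    assert capped
    assert theta == pytest.approx(math.radians(85))


def test_estimate_z_brightest_plane_and_ties():
    stack = np.zeros((5, 8, 8))
    stack[3] = 1.0
    img = ImageStack(stack, z_spacing_nm=550.0)
    path = np.array([(2, 2), (2, 3), (2, 4)])
    assert np.allclose(estimate_z(path, img), 3 * 550.0)
    # ties resolve to the lowest plane index
    stack2 = np.ones((4, 8, 8))
    img2 = ImageStack(stack2, z_spacing_nm=550.0)
    assert np.allclose(estimate_z(path, img2), 0.0)


def test_estimate_z_monotone_for_tilted_filament():
    """A filament brightest in successively higher planes yields monotone z."""
    stack = np.zeros((6, 10, 30)) + 0.01
    for c in range(30):
        stack[c // 5, 5, c] = 1.0
    img = ImageStack(stack, z_spacing_nm=550.0)
    path = np.array([(5, c) for c in range(30)])
    z = estimate_z(path, img)
    assert (np.diff(z) >= 0).all()
    assert z[0] == 0.0 and z[-1] == 5 * 550.0


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------


def test_menger_examples():
    assert menger_curvature((0, 0), (1, 1), (2, 2)) == 0.0
    assert abs(menger_curvature((0, 0), (1, 1), (2, 0))) == pytest.approx(1.0)
    # three points on a circle of radius 2
    ang = np.radians([10.0, 80.0, 200.0])
    pts = [(2 * math.cos(a), 2 * math.sin(a)) for a in ang]
    assert abs(menger_curvature(*pts)) == pytest.approx(0.5)


@settings(max_examples=50, deadline=None)
@given(
    st.floats(-math.pi, math.pi),
    st.floats(-50, 50),
    st.floats(-50, 50),
)
def test_menger_invariant_under_rigid_motion(angle, tx, ty):
    """|Menger curvature| is unchanged by rotation + translation."""
    pts = np.array([(0.0, 0.0), (1.0, 1.0), (2.0, 0.5)])
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    moved = pts @ rot.T + (tx, ty)
    k0 = menger_curvature(*pts)
    k1 = menger_curvature(*moved)
    assert abs(k1) == pytest.approx(abs(k0), rel=1e-6, abs=1e-9)


def circle_path(radius_px, n=None):
    """Digitised circular arc (upper half) as an ordered path."""
    n = n or int(radius_px * 4)
    theta = np.linspace(0, math.pi, n)
    rows = np.round(radius_px * (1 - np.sin(theta))).astype(int)
    cols = np.round(radius_px * np.cos(theta) + radius_px).astype(int)
    pts = np.stack([rows, cols], axis=1)
    keep = np.any(np.diff(pts, axis=0, prepend=pts[:1] - 1) != 0, axis=1)
    return pts[keep]


def test_curvature_straight_path_is_zero():
    path = np.array([(5, c) for c in range(30)])
    signed, unsigned = filament_curvature(path, CurvatureParams())
    assert signed == 0.0 and unsigned == 0.0


def test_curvature_circle_matches_radius():
    """A digitised arc of radius R recovers curvature ~ 1/R (in 1/nm).

    R = 4 lambda keeps the true curvature above the pixel-jitter floor of
    the unsigned mean (for much larger radii jitter inflates it).
    """
    radius_px = 20
    path = circle_path(radius_px)
    params = CurvatureParams()
    signed, unsigned = filament_curvature(path, params)
    expected = 1.0 / (radius_px * PX)
    assert unsigned == pytest.approx(expected, rel=0.15)
    assert signed == pytest.approx(expected, rel=0.15)
    # signed recovery stays accurate even for a gentle arc (jitter cancels)
    gentle = circle_path(60)
    signed60, unsigned60 = filament_curvature(gentle, params)
    assert signed60 == pytest.approx(1.0 / (60 * PX), rel=0.15)
    assert signed60 <= unsigned60


def test_curvature_s_curve_sign_cancellation():
    """Opposite bends cancel in the signed mean but not the unsigned mean."""
    theta = np.linspace(0, math.pi, 60)
    r = 20
    upper = np.stack(
        [np.round(r - r * np.sin(theta)), np.round(r - r * np.cos(theta))], axis=1
    )
    lower = np.stack(
        [np.round(r + r * np.sin(theta)), np.round(3 * r - r * np.cos(theta))], axis=1
    )
    path = np.vstack([upper, lower]).astype(int)
    keep = np.any(np.diff(path, axis=0, prepend=path[:1] - 1) != 0, axis=1)
    path = path[keep]
    signed, unsigned = filament_curvature(path, CurvatureParams())
    assert unsigned > 0
    assert signed < 0.2 * unsigned


def test_curvature_too_short_path_undefined():
    assert filament_curvature(np.array([(0, 0), (0, 1)]), CurvatureParams()) == (
        None,
        None,
    )


# ---------------------------------------------------------------------------
# deviation
# ---------------------------------------------------------------------------


def test_deviation_straight_is_zero():
    path = np.array([(2, c) for c in range(20)])
    assert filament_deviation(path, PX) == 0.0


def test_deviation_v_shape_matches_brute_force():
    left = [(10 - i, i) for i in range(11)]
    right = [(i + 1, 10 + i + 1) for i in range(10)]
    path = np.array(left + right)
    # brute-force point-to-chord distances
    p0, p1 = path[0], path[-1]
    chord = (p1 - p0).astype(float)
    expected = np.mean(
        [
            abs(chord[0] * (p - p0)[1] - chord[1] * (p - p0)[0])
            / np.linalg.norm(chord)
            for p in path
        ]
    ) * PX
    assert filament_deviation(path, PX) == pytest.approx(expected)
    assert expected > 0


def test_deviation_semicircle_analytic():
    """Mean distance of a semicircular arc from its diameter chord = 2r/pi."""
    radius_px = 60
    path = circle_path(radius_px, n=600)
    expected = 2 * radius_px / math.pi * PX
    assert filament_deviation(path, PX) == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# width
# ---------------------------------------------------------------------------


def test_width_one_pixel_line_is_one():
    binary = np.zeros((9, 30), bool)
    binary[4, 2:28] = True
    path = np.array([(4, c) for c in range(2, 28)])
    assert filament_width(path, binary) == pytest.approx(1.0, abs=0.1)


def test_width_three_pixel_bar():
    binary = np.zeros((11, 30), bool)
    binary[4:7, 2:28] = True
    path = np.array([(5, c) for c in range(2, 28)])
    assert filament_width(path, binary) == pytest.approx(3.0, abs=0.25)


def test_width_varying_bar_averages():
    binary = np.zeros((13, 40), bool)
    binary[5:7, 0:20] = True  # width 2
    binary[4:8, 20:40] = True  # width 4
    path = np.array([(5, c) for c in range(40)])
    assert filament_width(path, binary) == pytest.approx(3.0, abs=0.3)


# ---------------------------------------------------------------------------
# branch angles
# ---------------------------------------------------------------------------


def _t_network(stem_angle_deg=90):
    """Straight horizontal main filament with a stem leaving at a given angle."""
    grid = draw_line((41, 41), 20, 2, 20, 38)
    rad = math.radians(stem_angle_deg)
    # stem leaving junction (20, 20) downward at the given angle to the bar
    r1 = 20 + int(round(15 * math.sin(rad)))
    c1 = 20 + int(round(15 * math.cos(rad)))
    grid |= draw_line((41, 41), 20, 20, r1, c1)
    return label_filaments(grid)


def test_branch_angle_perpendicular_t():
    net = _t_network(90)
    angles = branch_angle_2d(net.branch_points[0], net)
    assert len(angles) == 1
    assert angles[0] == pytest.approx(math.pi / 2, abs=0.05)


def test_branch_angle_45_degree_stem():
    net = _t_network(45)
    angles = branch_angle_2d(net.branch_points[0], net)
    assert angles[0] == pytest.approx(math.pi / 4, abs=0.12)


def test_branch_angle_collinear_branch_is_zero():
    """A branch continuing exactly along the main direction deviates by 0."""
    from actinet.labelling import BranchPoint, LabelledNetwork

    main = np.array([(20, c) for c in range(10, 31)])
    branch = np.array([(20, c) for c in range(21, 31)])  # same heading as main
    net = LabelledNetwork(
        labels=np.zeros((41, 41), int),
        branch_points=[BranchPoint(coord=(20, 20), filaments={1, 2}, main=1)],
        paths={1: main, 2: branch},
    )
    angles = branch_angle_2d(net.branch_points[0], net)
    assert angles[0] == pytest.approx(0.0, abs=1e-9)


def test_branch_angle_30_degree_stem():
    net = _t_network(30)
    angles = branch_angle_2d(net.branch_points[0], net)
    assert angles[0] == pytest.approx(math.pi / 6, abs=0.15)


def test_branch_angle_3d_flat_equals_2d():
    net = _t_network(90)
    z = {fid: np.zeros(len(p)) for fid, p in net.paths.items()}
    a2 = branch_angle_2d(net.branch_points[0], net)
    a3 = branch_angle_3d(net.branch_points[0], net, z, PX)
    assert a3 == pytest.approx(a2, abs=1e-9)


def test_branch_angle_3d_rising_branch_matches_vector_oracle():
    net = _t_network(90)
    bp = net.branch_points[0]
    rise = 200.0  # nm per px step along the stem
    z = {}
    for fid, p in net.paths.items():
        if fid == bp.main:
            z[fid] = np.zeros(len(p))
        else:
            dist = np.max(np.abs(p - np.array(bp.coord)), axis=1)
            z[fid] = dist * rise
    a3 = branch_angle_3d(bp, net, z, PX)
    # independent oracle: explicit 3D vectors at the +/-5-step window points
    branch_id = next(f for f in bp.filaments if f != bp.main)
    p = net.paths[branch_id]
    d0 = np.max(np.abs(p[0] - np.array(bp.coord)))
    idx = 5 if d0 <= np.max(np.abs(p[-1] - np.array(bp.coord))) else len(p) - 6
    bvec = np.array(
        [*(p[idx] - np.array(bp.coord)) * PX, z[branch_id][idx]]
    )
    main = net.paths[bp.main]
    midx = int(np.argmin(np.max(np.abs(main - np.array(bp.coord)), axis=1)))
    best = math.inf
    for t in (midx + 5, midx - 5):
        mvec = np.array([*(main[t] - np.array(bp.coord)) * PX, 0.0])
        cosang = np.dot(bvec, mvec) / (np.linalg.norm(bvec) * np.linalg.norm(mvec))
        best = min(best, math.acos(float(np.clip(cosang, -1, 1))))
    assert a3[0] == pytest.approx(best, abs=1e-6)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def test_compute_all_emits_seventeen_measures(t_skeleton):
    from actinet.extraction import Skeleton

    net = label_filaments(Skeleton(t_skeleton))
    result = compute_all(net, np.ones(t_skeleton.shape, bool))
    d = result.to_dict()
    assert len(d) == 17
    assert tuple(d) == MEASURE_CODES


def test_compute_all_toy_t_scalars(t_skeleton):
    from actinet.extraction import Skeleton

    net = label_filaments(Skeleton(t_skeleton))
    mask = np.ones(t_skeleton.shape, bool)
    result = compute_all(net, mask, curvature_params=CurvatureParams())
    d = result.to_dict()
    assert d["cellSize"] == 900
    assert d["orientation"] == 0.0
    assert d["skelDensity"] == pytest.approx(t_skeleton.sum() / 900)
    assert d["Structures"] == [int(t_skeleton.sum())]
    assert d["branchRatio"] == pytest.approx(0.5)
    assert d["cellBPDensity"] == pytest.approx(1 / 900)
    assert len(d["filLenXY"]) == 2
    # flat network: 3D lengths equal 2D lengths, avgLen is their mean
    assert d["filLenXYZ"] == pytest.approx(d["filLenXY"])
    assert d["avgLen"] == pytest.approx(np.mean(d["filLenXY"]))
    # main bar is horizontal, stem vertical
    assert min(abs(a) for a in d["filamentAng.angXY"]) == pytest.approx(0, abs=1e-9)
    assert max(abs(a) for a in d["filamentAng.angXY"]) == pytest.approx(
        math.pi / 2, abs=1e-9
    )
    assert d["branchAng.angXY"][0] == pytest.approx(math.pi / 2, abs=0.05)


def test_compute_all_empty_network_no_crash():
    from actinet.extraction import Skeleton

    net = label_filaments(Skeleton(np.zeros((20, 20), bool)))
    result = compute_all(net, np.ones((20, 20), bool))
    d = result.to_dict()
    assert d["skelDensity"] == 0.0
    assert d["filLenXY"] == []
    assert d["avgLen"] == 0.0


def test_measure_invariants_on_synthetic_network():
    """len3D >= len2D and |signed| <= unsigned on an extracted network."""
    scene = generate_scene(SceneParams(shape=(120, 120), n_filaments=5), seed=9)
    stack_data = np.stack([scene.image * 0.3, scene.image, scene.image * 0.5])
    stack = ImageStack(stack_data, z_spacing_nm=550.0)
    skel = extract_skeleton(stack, np.ones(scene.image.shape, bool))
    net = label_filaments(skel)
    result = compute_all(net, np.ones(scene.image.shape, bool), stack)
    for m in result.filaments:
        assert m.length_3d_nm >= m.length_2d_nm - 1e-9
        if m.curvature_signed is not None:
            assert m.curvature_signed <= m.curvature_unsigned + 1e-12
        assert m.deviation_nm >= 0
        assert m.width_px >= 1.0


def test_length_recovery_on_synthetic_scene():
    """Measured filament lengths track the generating splines' arc lengths."""
    params = SceneParams(shape=(150, 150), n_filaments=1, midpoint_offset_frac=0.15)
    total_measured, total_truth = 0.0, 0.0
    for seed in (21, 22, 23):
        scene = generate_scene(params, seed=seed)
        skel = extract_skeleton(scene.image, np.ones(scene.image.shape, bool))
        net = label_filaments(skel)
        result = compute_all(net, np.ones(scene.image.shape, bool))
        total_measured += sum(m.length_2d_nm for m in result.filaments)
        total_truth += sum(scene.arclengths_nm)
    assert total_measured == pytest.approx(total_truth, rel=0.05)
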