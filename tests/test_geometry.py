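"""Spherical ROI system: segmentation, ellipsoid fits, frames, binning."""

import numpy as np
import pytest

import sphericell as sc
from sphericell.geometry import _assign_rois


# ---------------------------------------------------------------------------
# RoiGrid


def test_grid_partitions_into_18_rois():
    grid = sc.RoiGrid()
    assert grid.n_shells * grid.n_sectors == 18
    assert grid.n_rois == 18


def test_grid_scores_are_monotone_midpoints():
    grid = sc.RoiGrid()
    np.testing.assert_allclose(grid.r_mu, (np.arange(1, 7) - 0.5) / 6)
    np.testing.assert_allclose(grid.phi_nu, [15.0, 45.0, 75.0])
    assert np.all(np.diff(grid.r_mu) > 0)
    assert np.all(np.diff(grid.phi_nu) > 0)


def test_grid_volume_fractions_sum_to_one():
    frac = sc.RoiGrid().roi_volume_fractions()
    assert frac.shape == (6, 3)
    assert frac.min() > 0
    np.testing.assert_allclose(frac.sum(), 1.0, atol=1e-12)
    # equatorial band holds half the sphere: sin(30 deg) = 0.5
    np.testing.assert_allclose(frac[:, 2].sum(), 0.5, atol=1e-12)


# ---------------------------------------------------------------------------
# segmentation + ellipsoid fitting


def test_segment_metaphase_yields_single_component(metaphase_phantom):
    _, stack, _ = metaphase_phantom
    comps = sc.segment_chromatin(stack)
    assert len(comps) == 1


def test_segment_segregation_yields_two_components(segregation_phantom):
    _, stack, _ = segregation_phantom
    comps = sc.segment_chromatin(stack)
    assert len(comps) == 2


def test_component_volume_matches_analytic_ellipsoid(metaphase_phantom):
    cfg, stack, _ = metaphase_phantom
    comps = sc.segment_chromatin(stack)
    vol = comps[0].sum() * np.prod(stack.spacing)
    a, b, c = cfg.chromatin_half_axes
    expected = 4.0 / 3.0 * np.pi * a * b * c
    assert abs(vol - expected) / expected < 0.10


def test_segment_raises_when_nothing_survives():
    voxels = np.zeros((1, 8, 8, 8))
    voxels[0, 4, 4, 4] = 100.0  # single bright voxel, far below min volume
    stack = sc.ImageStack(voxels, (1.0, 1.0, 1.0), ["DAPI"])
    with pytest.raises(ValueError, match="no chromatin"):
        sc.segment_chromatin(stack, min_volume=20.0)


def test_fit_ellipsoid_on_digital_sphere():
    # solid ball of radius 10 um at 0.5 um spacing
    n = 48
    coords = (np.indices((n, n, n)).reshape(3, -1).T - n / 2) * 0.5
    mask = (np.linalg.norm(coords, axis=1) <= 10.0).reshape(n, n, n)
    fit = sc.fit_ellipsoid(mask, (0.5, 0.5, 0.5))
    assert np.all(fit.half_axes > 9.5) and np.all(fit.half_axes < 10.5)


def test_fit_ellipsoid_recovers_phantom_geometry(metaphase_phantom):
    cfg, stack, truth = metaphase_phantom
    comps = sc.segment_chromatin(stack)
    fit = sc.fit_ellipsoid(comps[0], stack.spacing)
    np.testing.assert_allclose(
        fit.half_axes, cfg.chromatin_half_axes, rtol=0.05
    )
    angle = np.degrees(
        np.arccos(np.clip(abs(fit.axes[2] @ truth.true_axis), 0, 1))
    )
    assert angle < 2.0


def test_fit_ellipsoid_rejects_degenerate_input():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    with pytest.raises(ValueError):
        sc.fit_ellipsoid(mask, (1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# frames


def test_metaphase_frame_radius_and_axis():
    fit = sc.EllipsoidFit(
        centroid=np.array([5.0, 5.0, 5.0]),
        half_axes=np.array([8.0, 8.0, 4.0]),
        axes=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
    )
    frame = sc.build_frame(sc.METAPHASE, [fit])
    assert frame.sphere_radius == pytest.approx(12.0)  # 1.5 * 8
    np.testing.assert_allclose(frame.axis, [1.0, 0.0, 0.0])


def test_segregation_frame_radius_from_centroid_distance():
    mk = lambda c: sc.EllipsoidFit(
        centroid=np.asarray(c, dtype=float),
        half_axes=np.array([3.0, 2.5, 2.0]),
        axes=np.eye(3),
    )
    frame = sc.build_frame(sc.SEGREGATION, [mk([0, 0, 0]), mk([10, 0, 0])])
    assert frame.sphere_radius == pytest.approx(7.5)  # 1.5 * 10 / 2
    np.testing.assert_allclose(frame.center, [5.0, 0.0, 0.0])


def test_segregation_frame_rejects_coincident_centroids():
    mk = lambda: sc.EllipsoidFit(
        centroid=np.zeros(3), half_axes=np.array([3.0, 2.5, 2.0]), axes=np.eye(3)
    )
    with pytest.raises(ValueError, match="coincident"):
        sc.build_frame(sc.SEGREGATION, [mk(), mk()])


def test_tilted_phantom_axis_recovered_within_3_degrees():
    axis = np.array([np.cos(np.radians(30)), np.sin(np.radians(30)), 0.0])
    cfg = sc.PhantomConfig(
        axis_direction=tuple(axis),
        chromatin_half_axes=(7.0, 6.0, 3.5),
        channel_patterns=[sc.ChannelPattern("DAPI", "chromatin")],
    )
    stack, truth = sc.make_phantom(cfg, seed=7)
    comps = sc.segment_chromatin(stack)
    frame = sc.build_frame(sc.METAPHASE, [sc.fit_ellipsoid(comps[0], stack.spacing)])
    angle = np.degrees(np.arccos(np.clip(abs(frame.axis @ truth.true_axis), 0, 1)))
    assert angle < 3.0


# ---------------------------------------------------------------------------
# ROI assignment


def _oracle_assign(point, frame):
    """Independent trigonometric oracle for a single point."""
    rel = np.asarray(point, dtype=float) - frame.center
    rho = np.sqrt(float(rel @ rel))
    if rho > frame.sphere_radius:
        return None
    shell = 1 if rho == 0 else min(6, int(np.floor(6 * rho / frame.sphere_radius)) + 1)
    if rho == 0:
        lat = 90.0
    else:
        cosang = abs(float(rel @ frame.axis)) / rho
        lat = 90.0 - np.degrees(np.arccos(min(1.0, cosang)))
    if lat >= 60.0:
        sector = "polar"
    elif lat >= 30.0:
        sector = "diagonal"
    else:
        sector = "equatorial"
    return shell, sector


@pytest.fixture(scope="module")
def tilted_frame():
    axis = np.array([2.0, -1.0, 0.5])
    return sc.MitoticFrame(
        phase=sc.METAPHASE,
        center=np.array([3.0, -2.0, 7.0]),
        axis=axis / np.linalg.norm(axis),
        sphere_radius=9.0,
    )


def test_assign_roi_on_axis_point_is_polar_shell_one(tilted_frame):
    point = tilted_frame.center + 0.05 * tilted_frame.sphere_radius * tilted_frame.axis
    assert sc.assign_roi(point, tilted_frame) == (1, "polar")


def test_assign_roi_equatorial_rim():
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]),
        sphere_radius=10.0,
    )
    point = np.array([0.0, 9.5, 0.0])  # division plane, 0.95 R
    assert sc.assign_roi(point, frame) == (6, "equatorial")


def test_assign_roi_matches_oracle_on_random_points(tilted_frame):
    rng = np.random.default_rng(42)
    points = tilted_frame.center + rng.uniform(-10, 10, (10_000, 3))
    shells, sectors = _assign_rois(points, tilted_frame)
    names = sc.SECTOR_NAMES
    for k in range(points.shape[0]):
        expected = _oracle_assign(points[k], tilted_frame)
        got = (
            None if shells[k] < 0 else (shells[k], names[sectors[k]])
        )
        assert got == expected


def test_assign_roi_invariant_to_axis_sign(tilted_frame):
    import dataclasses

    flipped = dataclasses.replace(tilted_frame, axis=-tilted_frame.axis)
    rng = np.random.default_rng(0)
    points = tilted_frame.center + rng.uniform(-9, 9, (2000, 3))
    s1, v1 = _assign_rois(points, tilted_frame)
    s2, v2 = _assign_rois(points, flipped)
    np.testing.assert_array_equal(s1, s2)
    np.testing.assert_array_equal(v1, v2)


# ---------------------------------------------------------------------------
# binning


def _uniform_stack(value=7.0, n=64, spacing=0.25):
    voxels = np.full((1, n, n, n), value)
    return sc.ImageStack(voxels, (spacing,) * 3, ["DAPI"])


def _center_frame(n=64, spacing=0.25, radius=7.0):
    center = np.full(3, (n - 1) * spacing / 2)
    return sc.MitoticFrame(
        phase=sc.METAPHASE, center=center, axis=np.array([1.0, 0.0, 0.0]),
        sphere_radius=radius,
    )


def test_bin_uniform_stack_gives_constant_map():
    stack = _uniform_stack(7.0)
    spheri_map = sc.bin_stack(stack, _center_frame())
    np.testing.assert_allclose(spheri_map.intensities, 7.0)
    assert np.all(spheri_map.voxel_counts > 0)


def test_bin_stack_partition_counts_every_in_sphere_voxel_once():
    stack = _uniform_stack()
    frame = _center_frame()
    spheri_map = sc.bin_stack(stack, frame)
    n = stack.voxels.shape[1]
    coords = np.indices((n, n, n)).reshape(3, -1).T * stack.spacing[0]
    inside = np.linalg.norm(coords - frame.center, axis=1) <= frame.sphere_radius
    assert spheri_map.voxel_counts.sum() == inside.sum()


def test_bin_stack_shell_volume_ratio_matches_analytic():
    spheri_map = sc.bin_stack(_uniform_stack(), _center_frame())
    shell_vols = spheri_map.volumes.sum(axis=1)
    ratio = shell_vols[5] / shell_vols[0]
    assert abs(ratio - 91.0) / 91.0 < 0.10  # (6^3 - 5^3) / 1^3


def test_bin_stack_total_volume_close_to_sphere():
    frame = _center_frame()
    spheri_map = sc.bin_stack(_uniform_stack(), frame)
    sphere = 4.0 / 3.0 * np.pi * frame.sphere_radius**3
    assert abs(spheri_map.volumes.sum() - sphere) / sphere < 0.05


def test_bin_stack_deterministic(metaphase_phantom):
    _, stack, truth = metaphase_phantom
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
        sphere_radius=truth.true_sphere_radius,
    )
    m1 = sc.bin_stack(stack, frame)
    m2 = sc.bin_stack(stack, frame)
    np.testing.assert_array_equal(m1.intensities, m2.intensities)


def test_bin_stack_errors_when_sphere_outside():
    stack = _uniform_stack(n=16)
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=np.array([100.0, 100.0, 100.0]),
        axis=np.array([1.0, 0.0, 0.0]), sphere_radius=5.0,
    )
    with pytest.raises(ValueError, match="outside"):
        sc.bin_stack(stack, frame)


def test_anisotropic_binning_matches_isotropic():
    """Linear z-interpolation to isotropy preserves ROI means of a smooth
    field within a few percent."""
    n = 64
    spacing = 0.25
    zz, yy, xx = np.meshgrid(*(np.arange(n) * spacing,) * 3, indexing="ij")
    field = 50.0 + 20.0 * np.sin(zz / 2.0) * np.cos(yy / 3.0) + xx
    iso = sc.ImageStack(field[None], (spacing,) * 3, ["DAPI"])
    aniso = sc.ImageStack(
        field[None, ::2], (spacing * 2, spacing, spacing), ["DAPI"]
    )
    frame = _center_frame()
    map_iso = sc.bin_stack(iso, frame)
    map_aniso = sc.bin_stack(aniso, frame)
    np.testing.assert_allclose(
        map_aniso.intensities, map_iso.intensities, rtol=0.02
    )


def test_rotation_equivariance_of_roi_means():
    """Rotating the cell and the axis together leaves ROI means unchanged
    within interpolation tolerance (well-resolved structures)."""
    channels = [
        sc.ChannelPattern("DAPI", "chromatin", amplitude=100.0),
        sc.ChannelPattern("spindle", "spindle", amplitude=80.0, sigma=3.0),
        sc.ChannelPattern("uniform", "uniform", amplitude=30.0),
    ]
    maps = []
    for angle in (0.0, 40.0):
        axis = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle)), 0.0])
        cfg = sc.PhantomConfig(
            axis_direction=tuple(axis),
            chromatin_half_axes=(7.0, 6.0, 3.5),
            channel_patterns=channels,
        )
        stack, truth = sc.make_phantom(cfg, seed=1)
        frame = sc.MitoticFrame(
            phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
            sphere_radius=truth.true_sphere_radius,
        )
        maps.append(sc.bin_stack(stack, frame))
    for ci in range(3):
        a, b = maps[0].intensities[ci], maps[1].intensities[ci]
        assert np.nanmax(np.abs(a - b) / np.abs(a)) < 0.02


# ---------------------------------------------------------------------------
# projection


def test_project_constant_map_normalizes_to_zero(metaphase_phantom):
    _, stack, truth = metaphase_phantom
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
        sphere_radius=truth.true_sphere_radius,
    )
    spheri_map = sc.bin_stack(stack, frame)
    spheri_map.intensities[:] = 5.0
    values = sc.project_values(spheri_map, "DAPI", normalize=True)
    np.testing.assert_allclose(values, 0.0)  # degenerate min-max rule


def test_project_minmax_endpoints(metaphase_phantom):
    _, stack, truth = metaphase_phantom
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
        sphere_radius=truth.true_sphere_radius,
    )
    spheri_map = sc.bin_stack(stack, frame)
    values = sc.project_values(spheri_map, "DAPI", normalize=True)
    assert values.max() == pytest.approx(1.0)
    assert values.min() == pytest.approx(0.0)


def test_spindle_channel_peaks_on_polar_axis(metaphase_phantom):
    _, stack, truth = metaphase_phantom
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
        sphere_radius=truth.true_sphere_radius,
    )
    spheri_map = sc.bin_stack(stack, frame)
    spindle = spheri_map.channel("b-tubulin")
    # the fibre runs pole to pole: polar sectors outshine equatorial ones in
    # the mid shells, and the brightest ROI lies in the polar column
    mu_max, nu_max = np.unravel_index(np.nanargmax(spindle), spindle.shape)
    assert nu_max == 0
    assert np.nanmean(spindle[2:5, 0]) > 2 * np.nanmean(spindle[2:5, 2])


def test_project_all_masked_raises(metaphase_phantom):
    _, stack, truth = metaphase_phantom
    frame = sc.MitoticFrame(
        phase=sc.METAPHASE, center=truth.true_center, axis=truth.true_axis,
        sphere_radius=truth.true_sphere_radius,
    )
    spheri_map = sc.bin_stack(stack, frame)
    with pytest.raises(ValueError, match="masked"):
        sc.project_values(spheri_map, "DAPI", dapi_floor=1e9)
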