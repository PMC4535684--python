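"""Edge map, GVF field and snake behaviour, each checked against an
independent oracle (finite differences, analytic geometry, generator truth)."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from dafish.pipeline import SegmentationConfig, segment_cell
from dafish.segmentation import (
    EdgeMap,
    PeakDetectionError,
    SnakeParams,
    compute_edge_map,
    compute_gvf,
    detect_probe_peaks,
    evolve_snake,
    initialize_contour,
)
from dafish.synthetic import SceneSpec, render_scene_2d


def _disk_image(n=64, radius=10.0, value=50.0, background=5.0):
    rr, cc = np.mgrid[:n, :n]
    r = np.hypot(rr - n / 2, cc - n / 2)
    return np.where(r <= radius, value, background).astype(float), n / 2


# ---------------------------------------------------------------------- edges


def test_constant_image_gives_zero_edge_map():
    em = compute_edge_map(np.full((32, 32), 7.0), smoothing_sigma=1.5)
    assert np.all(em.values == 0.0)


def test_step_edge_response_matches_finite_difference_oracle():
    img = np.full((40, 60), 10.0)
    img[:, 30:] = 50.0
    em = compute_edge_map(img, smoothing_sigma=1.0)
    # independent oracle: central differences of an independently smoothed image
    sm = ndi.gaussian_filter(img, 1.0, mode="nearest")
    dr = np.zeros_like(sm)
    dc = np.zeros_like(sm)
    dr[1:-1, :] = (sm[2:, :] - sm[:-2, :]) / 2.0
    dc[:, 1:-1] = (sm[:, 2:] - sm[:, :-2]) / 2.0
    dr[0], dr[-1] = sm[1] - sm[0], sm[-1] - sm[-2]
    dc[:, 0], dc[:, -1] = sm[:, 1] - sm[:, 0], sm[:, -1] - sm[:, -2]
    oracle = np.hypot(dr, dc)
    oracle /= oracle.max()
    assert np.allclose(em.values, oracle, atol=1e-12)
    # maximal response along the step, symmetric about it
    row = em.values[20]
    assert row.argmax() in (29, 30)
    assert row[28] == pytest.approx(row[31], rel=1e-9)


def test_disk_edge_map_peaks_on_ring():
    img, c = _disk_image(radius=10.0)
    em = compute_edge_map(img, smoothing_sigma=1.0)
    rr, cc = np.mgrid[: img.shape[0], : img.shape[1]]
    radii = np.hypot(rr - c, cc - c)
    ring_radius = radii.flat[em.values.argmax()]
    assert abs(ring_radius - 10.0) <= 1.0


def test_binarized_edge_map_is_binary():
    img, _ = _disk_image()
    em = compute_edge_map(img, smoothing_sigma=1.0, binarize_fraction=0.5)
    assert set(np.unique(em.values)) <= {0.0, 1.0}


# ----------------------------------------------------------------------- GVF


def test_gvf_zero_edge_map_is_fixed_point():
    field = compute_gvf(EdgeMap(np.zeros((32, 32)), 1.0))
    assert field.converged
    assert np.all(field.u == 0.0) and np.all(field.v == 0.0)


def _euler_residual(field, f):
    """Independent residual oracle with its own replicate-edge stencils."""
    fp = np.pad(f, 1, mode="edge")
    fr = (fp[2:, 1:-1] - fp[:-2, 1:-1]) / 2.0
    fc = (fp[1:-1, 2:] - fp[1:-1, :-2]) / 2.0
    b = fr**2 + fc**2

    def lap(a):
        ap = np.pad(a, 1, mode="edge")
        return ap[2:, 1:-1] + ap[:-2, 1:-1] + ap[1:-1, 2:] + ap[1:-1, :-2] - 4 * a

    ru = field.mu * lap(field.u) - (field.u - fc) * b
    rv = field.mu * lap(field.v) - (field.v - fr) * b
    return np.sqrt(np.mean(ru**2 + rv**2))


def test_gvf_satisfies_euler_equation_residual_oracle():
    img, c = _disk_image()
    em = compute_edge_map(img, smoothing_sigma=1.5)
    field = compute_gvf(em, tolerance=1e-4, max_iterations=2000)
    assert field.converged
    assert _euler_residual(field, em.values) < 1e-4
    # field points toward the ring along a radial line (here: +col axis)
    col_ring = int(c + 10)
    assert field.u[int(c), col_ring + 4] < 0  # outside: back toward ring
    assert field.u[int(c), col_ring - 4] > 0  # inside: out toward ring


def test_gvf_extends_capture_range_beyond_plain_gradient():
    n = 64
    rr, cc = np.mgrid[:n, :n]
    r = np.hypot(rr - 32, cc - 32)
    ring = ((r > 11) & (r < 13)).astype(float)
    field = compute_gvf(EdgeMap(ring, 0.0), tolerance=1e-6, max_iterations=2000)
    mag = np.hypot(field.u, field.v)
    probe = (32, 32 + 22)  # 10 px outside the ring
    assert mag[probe] > 1e-3 * mag.max()
    fr, fc = np.gradient(ring)
    assert np.hypot(fr, fc)[probe] == 0.0


def test_gvf_divergence_detected_for_reckless_time_step():
    img, _ = _disk_image()
    em = compute_edge_map(img, smoothing_sigma=1.0)
    with pytest.raises(FloatingPointError):
        compute_gvf(em, mu=0.1, gamma=50.0, max_iterations=200)


# ---------------------------------------------------------------------- peaks


def test_two_gaussians_recovered_within_one_pixel():
    spec = SceneSpec(seed=2)
    probe, _, _ = render_scene_2d(spec)
    peaks = detect_probe_peaks(probe, 2, smoothing_sigma=2.0)
    found = {tuple(p) for p in peaks}
    for r0, c0 in spec.spot_positions:
        assert any(np.hypot(r - r0, c - c0) <= 1.0 for r, c in found)


def test_flat_image_raises_peak_detection_error():
    with pytest.raises(PeakDetectionError):
        detect_probe_peaks(np.full((48, 48), 3.0), 2)


def test_missing_second_spot_raises():
    spec = SceneSpec(amplitude_b=0.0, seed=4)
    probe, _, _ = render_scene_2d(spec)
    with pytest.raises(PeakDetectionError):
        detect_probe_peaks(probe, 2, smoothing_sigma=2.0)


# -------------------------------------------------------------------- contour


def test_initial_contour_is_circle():
    c = initialize_contour((10.0, 20.0), radius=5.0, n_vertices=32)
    dist = np.hypot(c.vertices[:, 0] - 10.0, c.vertices[:, 1] - 20.0)
    assert np.allclose(dist, 5.0, atol=1e-9)
    # inscribed regular polygon area: (n/2) r^2 sin(2 pi / n)
    assert c.area() == pytest.approx(16 * 25 * np.sin(2 * np.pi / 32), rel=1e-12)


def test_initial_contour_vertex_floor():
    with pytest.raises(ValueError):
        initialize_contour((0.0, 0.0), radius=5.0, n_vertices=7)
    with pytest.raises(ValueError):
        initialize_contour((0.0, 0.0), radius=-1.0)


# ---------------------------------------------------------------------- snake


def test_snake_near_fixed_point_on_disk_ring():
    img, c = _disk_image(radius=10.0)
    em = compute_edge_map(img, smoothing_sigma=1.0)
    gvf = compute_gvf(em, max_iterations=1000)
    init = initialize_contour((c, c), radius=10.0, n_vertices=64)
    final = evolve_snake(init, gvf, SnakeParams(alpha=0.05, beta=0.05, kappa=2.0))
    radii = np.hypot(final.vertices[:, 0] - c, final.vertices[:, 1] - c)
    assert np.all(np.abs(radii - 10.0) < 0.5)


def test_snake_from_outside_recovers_disk_area():
    img, c = _disk_image(radius=10.0)
    em = compute_edge_map(img, smoothing_sigma=1.0)
    gvf = compute_gvf(em, max_iterations=1000)
    init = initialize_contour((c, c), radius=15.0, n_vertices=64)
    final = evolve_snake(init, gvf, SnakeParams(max_iterations=800))
    assert final.converged
    assert final.area() == pytest.approx(np.pi * 100.0, rel=0.10)


def test_snake_without_external_force_shrinks_monotonically():
    zero = compute_gvf(EdgeMap(np.zeros((64, 64)), 1.0))
    contour = initialize_contour((32.0, 32.0), radius=12.0, n_vertices=48)
    params = SnakeParams(alpha=0.2, beta=0.0, kappa=0.0, max_iterations=1,
                         convergence_tol=0.0)
    perimeters = [contour.perimeter()]
    for _ in range(20):
        contour = evolve_snake(contour, zero, params)
        perimeters.append(contour.perimeter())
    assert all(b < a for a, b in zip(perimeters, perimeters[1:]))


def test_segmentation_rotation_equivariance(noise_free_scene):
    """Rotating the image by 90 degrees rotates the contour correspondingly."""
    probe, _, _ = render_scene_2d(noise_free_scene)
    h, w = probe.shape
    positions = noise_free_scene.spot_positions
    contour, _ = segment_cell(probe, 2.0, expected_positions=positions)
    rotated = np.ascontiguousarray(np.rot90(probe))  # (r, c) -> (w-1-c, r)
    rot_positions = tuple((w - 1 - c, r) for r, c in positions)
    contour_rot, _ = segment_cell(rotated, 2.0, expected_positions=rot_positions)
    # map rotated-frame vertices back into the original frame
    back = np.column_stack(
        [contour_rot.vertices[:, 1], w - 1 - contour_rot.vertices[:, 0]]
    )
    d = np.hypot(
        back[:, None, 0] - contour.vertices[None, :, 0],
        back[:, None, 1] - contour.vertices[None, :, 1],
    )
    hausdorff = max(d.min(axis=1).max(), d.min(axis=0).max())
    assert hausdorff < 0.5


def test_contour_recovers_spot_mass_region_and_center():
    """Over >= 50 synthetic spots at SNR >= 10, the contour area stays within
    15 % of the region enclosing 95 % of the true Gaussian mass, and its
    center within 1 px of truth."""
    rng = np.random.default_rng(42)
    sigma = 2.0
    target_area = np.pi * (sigma * np.sqrt(2 * np.log(20))) ** 2
    n_spots = 0
    for i in range(25):
        amps = rng.uniform(100.0, 300.0, size=2)
        jitter = rng.uniform(-3.0, 3.0, size=4)
        spec = SceneSpec(
            amplitude_a=float(amps[0]),
            amplitude_b=float(amps[1]),
            spot_positions=(
                (48.0 + jitter[0], 40.0 + jitter[1]),
                (48.0 + jitter[2], 88.0 + jitter[3]),
            ),
            seed=1000 + i,
        )
        probe, _, _ = render_scene_2d(spec)
        contours = segment_cell(probe, sigma, SegmentationConfig(),
                                expected_positions=spec.spot_positions)
        for contour, center in zip(contours, spec.spot_positions):
            assert abs(contour.area() - target_area) / target_area < 0.15
            assert np.hypot(*(contour.centroid() - np.asarray(center))) < 1.0
            n_spots += 1
    assert n_spots >= 50
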