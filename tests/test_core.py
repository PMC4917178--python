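"""DS core: derivative maps, tanh mask, per-slice Otsu, 3D components."""

import numpy as np
import pytest
from scipy import ndimage

from dsseg.core import (
    MaskParams,
    SegmentedObject,
    apply_mask,
    compute_derivative_maps,
    connected_components_3d,
    ds_segment,
    gauss_gradient_magnitude,
    hessian_det_negative_abs,
    laplacian_positive,
    masking_function,
    otsu_threshold_slices,
    remove_small_objects,
)
from dsseg.pipeline import BENCHMARK_DENOISE, BENCHMARK_MASK
from dsseg.stacks import ImageStack


def _stack(arr2d, spacing):
    return ImageStack(np.asarray(arr2d, float)[np.newaxis], spacing)


def _grid(n):
    y, x = np.mgrid[0:n, 0:n].astype(float)
    return x, y


class TestDerivativeOperators:
    SIGMA = 1.5

    def test_constant_gives_zero_gradient(self, spacing):
        g = gauss_gradient_magnitude(_stack(np.full((16, 16), 9.0), spacing), self.SIGMA)
        np.testing.assert_allclose(g, 0.0, atol=1e-10)

    def test_ramp_gradient_magnitude(self, spacing):
        x, _ = _grid(32)
        g = gauss_gradient_magnitude(_stack(3.0 * x, spacing), self.SIGMA)
        interior = g[0, 8:-8, 8:-8]
        np.testing.assert_allclose(interior, 3.0, rtol=0.01)

    def test_bowl_laplacian(self, spacing):
        x, y = _grid(32)
        lap = laplacian_positive(_stack(x**2 + y**2, spacing), self.SIGMA)
        np.testing.assert_allclose(lap[0, 10:-10, 10:-10], 4.0, rtol=0.01)
        neg = laplacian_positive(_stack(2000.0 - (x**2 + y**2), spacing), self.SIGMA)
        np.testing.assert_allclose(neg[0, 10:-10, 10:-10], 0.0, atol=1e-8)

    def test_saddle_hessian(self, spacing):
        x, y = _grid(32)
        h = hessian_det_negative_abs(_stack((x - 16.0) * (y - 16.0) + 300.0, spacing), self.SIGMA)
        np.testing.assert_allclose(h[0, 10:-10, 10:-10], 1.0, rtol=0.01)
        bowl = hessian_det_negative_abs(_stack(x**2 + y**2, spacing), self.SIGMA)
        np.testing.assert_allclose(bowl[0, 10:-10, 10:-10], 0.0, atol=1e-8)

    def test_matches_finite_difference_oracle(self, rng, spacing):
        """All three maps agree with central differences of the smoothed slice."""
        img = rng.random((40, 40)) * 100
        smooth = ndimage.gaussian_filter(img, self.SIGMA, mode="nearest")
        iy, ix = np.gradient(smooth)
        iyy, iyx = np.gradient(iy)
        ixy, ixx = np.gradient(ix)
        stack = _stack(img, spacing)
        g = gauss_gradient_magnitude(stack, self.SIGMA)
        np.testing.assert_allclose(g[0], np.sqrt(ix**2 + iy**2), atol=1e-6)
        lap = laplacian_positive(stack, self.SIGMA)
        np.testing.assert_allclose(lap[0], np.maximum(ixx + iyy, 0), atol=1e-6)
        h = hessian_det_negative_abs(stack, self.SIGMA)
        np.testing.assert_allclose(
            h[0], np.abs(np.minimum(ixx * iyy - ixy * iyx, 0)), atol=1e-6
        )


class TestMask:
    def test_zero_maps_closed_form(self, spacing):
        zero = np.zeros((1, 8, 8))
        derivs = compute_derivative_maps(_stack(np.full((8, 8), 5.0), spacing), 1.5)
        m = masking_function(derivs, MaskParams())
        expected = 0.5 * (1 + np.tanh(1.0))  # S = 0 everywhere
        np.testing.assert_allclose(m, expected, atol=1e-12)
        assert expected == pytest.approx(0.8808, abs=1e-4)
        assert np.all((m > 0) & (m < 1))

    def test_monotone_decreasing_in_s(self):
        s = np.linspace(0, 3, 50)
        m = 0.5 * (1 + np.tanh(1.0 - s))
        assert np.all(np.diff(m) < 0)

    def test_gamma_steepens(self):
        s = np.linspace(0, 3, 50)
        m1 = np.abs(0.5 * (1 + np.tanh(-1.0 * s)) - 0.5)
        m2 = np.abs(0.5 * (1 + np.tanh(-2.0 * s)) - 0.5)
        assert np.all(m2 >= m1)

    def test_apply_mask(self, rng, spacing):
        img = _stack(rng.random((10, 10)) * 10, spacing)
        np.testing.assert_array_equal(apply_mask(img, np.ones((1, 10, 10))).voxels, img.voxels)
        half = apply_mask(img, np.full((1, 10, 10), 0.5))
        np.testing.assert_allclose(half.voxels, img.voxels * 0.5)
        with pytest.raises(ValueError):
            apply_mask(img, np.ones((2, 10, 10)))

    def test_mask_never_increases_intensity(self, rng, spacing):
        img = _stack(rng.random((12, 12)) * 50, spacing)
        derivs = compute_derivative_maps(img, 1.5)
        m = masking_function(derivs, MaskParams())
        assert np.all(apply_mask(img, m).voxels <= img.voxels + 1e-12)


def _otsu_oracle(values, nbins=256):
    """Exhaustive between-class variance maximisation over histogram bins."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = None, -1.0
    total = hist.sum()
    for i in range(1, nbins):
        w0 = hist[:i].sum() / total
        w1 = 1 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:i] * centers[:i]).sum() / hist[:i].sum()
        mu1 = (hist[i:] * centers[i:]).sum() / hist[i:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i - 1 : i + 1].mean()
    return best_t


class TestOtsu:
    def test_bimodal_slice(self, spacing):
        img = np.full((10, 10), 10.0)
        img[:, 5:] = 200.0
        binary = otsu_threshold_slices(_stack(img, spacing))
        assert binary[0, :, 5:].all()
        assert not binary[0, :, :5].any()

    def test_constant_slice_background(self, spacing):
        binary = otsu_threshold_slices(_stack(np.full((8, 8), 77.0), spacing))
        assert not binary.any()

    def test_threshold_matches_exhaustive_oracle(self, rng, spacing):
        from skimage.filters import threshold_otsu

        vals = np.concatenate([rng.normal(30, 4, 600), rng.normal(160, 12, 400)])
        img = vals.reshape(25, 40).clip(0)
        t = threshold_otsu(img, nbins=256)
        t_oracle = _otsu_oracle(img.ravel())
        # same histogram bin: within one 256-bin width
        assert abs(t - t_oracle) <= (img.max() - img.min()) / 256 + 1e-9

    def test_noise_only_slice_guarded(self, rng, spacing):
        noise = rng.gamma(4.0, 6.25, size=(40, 40))
        binary = otsu_threshold_slices(_stack(noise, spacing))
        assert not binary.any()


def _bfs_labels(binary, connectivity):
    """Flood-fill component labelling oracle."""
    from collections import deque

    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) > 1:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(binary.shape, dtype=int)
    nxt = 1
    for idx in np.argwhere(binary):
        if labels[tuple(idx)]:
            continue
        q = deque([tuple(idx)])
        labels[tuple(idx)] = nxt
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < binary.shape[i] for i in range(3)):
                    if binary[n] and not labels[n]:
                        labels[n] = nxt
                        q.append(n)
        nxt += 1
    return labels, nxt - 1


class TestComponents:
    def test_single_cube(self, spacing):
        binary = np.zeros((5, 5, 5), bool)
        binary[1:4, 1:4, 1:4] = True
        objs = connected_components_3d(binary, spacing)
        assert len(objs) == 1
        assert objs[0].volume == 27
        cx, cy, cz = objs[0].centroid_um
        assert cx == pytest.approx(2.5 * spacing.dx)
        assert cz == pytest.approx(2.5 * spacing.dz)

    def test_two_separated_cubes(self, spacing):
        binary = np.zeros((9, 4, 4), bool)
        binary[0:2, :2, :2] = True
        binary[5:7, :2, :2] = True
        assert len(connected_components_3d(binary, spacing)) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle(self, rng, spacing, connectivity):
        binary = rng.random((8, 12, 12)) < 0.2
        objs = connected_components_3d(binary, spacing, connectivity)
        oracle_labels, n_oracle = _bfs_labels(binary, connectivity)
        assert len(objs) == n_oracle
        # identical partition: each object maps to exactly one oracle label
        for o in objs:
            labs = {oracle_labels[tuple(v)] for v in o.voxels}
            assert len(labs) == 1
        assert sum(o.volume for o in objs) == binary.sum()

    def test_deterministic_raster_labelling(self, spacing):
        binary = np.zeros((3, 6, 6), bool)
        binary[2, 5, 5] = True  # raster-late
        binary[0, 0, 0] = True  # raster-early
        objs = connected_components_3d(binary, spacing)
        assert tuple(objs[0].voxels[0]) == (0, 0, 0)
        assert objs[0].object_id == 1


class TestRemoveSmall:
    def test_threshold_10(self, spacing):
        objs = [
            SegmentedObject(i + 1, np.zeros((v, 3), dtype=int), spacing)
            for i, v in enumerate([5, 9, 10, 50])
        ]
        kept = remove_small_objects(objs, 10)
        assert [o.volume for o in kept] == [10, 50]

    def test_empty_and_zero_threshold(self, spacing):
        assert remove_small_objects([], 10) == []
        objs = [SegmentedObject(1, np.zeros((3, 3), dtype=int), spacing)]
        assert remove_small_objects(objs, 0) == objs


class TestDsSegment:
    def test_five_separated_nuclei(self, five_separated_scene):
        scene = five_separated_scene
        res = ds_segment(scene.stack, BENCHMARK_DENOISE, BENCHMARK_MASK)
        assert len(res.objects) == 5
        truth = scene.true_centroids_um
        for det in res.centroids_um:
            assert np.linalg.norm(truth - det, axis=1).min() < 2.0

    def test_all_zero_stack(self, spacing):
        res = ds_segment(ImageStack(np.zeros((4, 16, 16)), spacing))
        assert res.objects == []
        assert not res.label_mask.any()

    def test_deterministic(self, five_separated_scene):
        r1 = ds_segment(five_separated_scene.stack, BENCHMARK_DENOISE, BENCHMARK_MASK)
        r2 = ds_segment(five_separated_scene.stack, BENCHMARK_DENOISE, BENCHMARK_MASK)
        np.testing.assert_array_equal(r1.label_mask, r2.label_mask)

    def test_label_mask_consistent_with_voxel_lists(self, five_separated_scene):
        res = ds_segment(five_separated_scene.stack, BENCHMARK_DENOISE, BENCHMARK_MASK)
        for o in res.objects:
            assert (res.label_mask[o.voxels[:, 0], o.voxels[:, 1], o.voxels[:, 2]] == o.object_id).all()
        assert (res.label_mask > 0).sum() == sum(o.volume for o in res.objects)

    def test_alpha_erodes_volumes(self, five_separated_scene):
        """Heavier gradient weighting shrinks segmented objects."""
        stack = five_separated_scene.stack
        v1 = ds_segment(stack, BENCHMARK_DENOISE, MaskParams(sigma_g=1.1)).volumes.sum()
        v3 = ds_segment(stack, BENCHMARK_DENOISE, MaskParams(alpha=3.0, sigma_g=1.1)).volumes.sum()
        assert v3 < v1
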