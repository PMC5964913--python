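import numpy as np
import pytest
from scipy import ndimage

from pelviseg.markerseg import (
    MarkerImage,
    edit_markers,
    impose_minima,
    skeleton_markers,
    sobel_gradient,
    watershed_transform,
)

from oracles import (
    random_surface_and_markers,
    regional_minima_reference,
    sobel_reference,
    watershed_reference,
)

S8 = np.ones((3, 3), dtype=bool)


class TestSobel:
    def test_constant_image_has_zero_gradient(self):
        g = sobel_gradient(np.full((6, 6), 42.0))
        assert not g.gx.any() and not g.gy.any() and not g.magnitude.any()

    def test_vertical_step_has_expected_column_gradient(self):
        h = 50.0
        img = np.zeros((6, 8))
        img[:, 4:] = h
        g = sobel_gradient(img)
        # template sums across the step give |Gy| = 4h on both edge columns
        assert np.allclose(np.abs(g.gy[2, 3]), 4 * h)
        assert np.allclose(np.abs(g.gy[2, 4]), 4 * h)
        assert np.allclose(g.gy[2, :3], 0)

    def test_matches_double_loop_oracle(self, rng):
        img = rng.integers(0, 255, (8, 8)).astype(float)
        gx_ref, gy_ref = sobel_reference(img)
        g = sobel_gradient(img)
        assert np.allclose(g.gx, gx_ref)
        assert np.allclose(g.gy, gy_ref)
        assert np.allclose(g.magnitude, np.hypot(gx_ref, gy_ref))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            sobel_gradient(np.zeros((2, 5)))


class TestSkeletonMarkers:
    def _blob(self, mask, r, c, rad):
        rr, cc = np.ogrid[: mask.shape[0], : mask.shape[1]]
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2

    def test_three_blobs_give_three_foreground_labels(self):
        mask = np.zeros((48, 48), dtype=bool)
        for r, c in [(10, 10), (10, 36), (36, 24)]:
            self._blob(mask, r, c, 6)
        markers = skeleton_markers(mask)
        assert markers.n_foreground == 3
        assert (markers.labels == markers.background_label).any()
        # foreground markers sit inside the mask, background outside
        fg = (markers.labels > 0) & (markers.labels <= 3)
        assert not (fg & ~mask).any()
        assert not ((markers.labels == markers.background_label) & mask).any()

    def test_single_blob_gives_two_labels(self):
        mask = np.zeros((32, 32), dtype=bool)
        self._blob(mask, 16, 16, 7)
        markers = skeleton_markers(mask)
        assert markers.n_foreground == 1
        assert set(np.unique(markers.labels)) == {0, 1, 2}

    def test_2x2_component_recovered_by_centroid_guard(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:6, 4:6] = True  # thins to nothing
        self._blob(mask, 11, 11, 3)
        markers = skeleton_markers(mask)
        assert markers.n_foreground == 2
        patch = markers.labels[4:6, 4:6]
        assert (patch > 0).sum() == 1  # exactly the centroid pixel

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            skeleton_markers(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            skeleton_markers(np.ones((8, 8), dtype=bool))


class TestImposeMinima:
    def test_minima_equal_marker_set_on_random_surfaces(self, rng):
        for _ in range(30):
            surface, labels, n = random_surface_and_markers(rng)
            if n < 2:
                continue
            markers = MarkerImage(labels=labels, n_foreground=n - 1)
            imposed = impose_minima(surface, markers)
            minima = regional_minima_reference(imposed)
            assert np.array_equal(minima, labels > 0)

    def test_constant_surface_single_marker(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[3, 3] = 1
        markers = MarkerImage(labels=labels, n_foreground=0)
        imposed = impose_minima(np.zeros((8, 8)), markers)
        minima = regional_minima_reference(imposed)
        assert minima.sum() == 1 and minima[3, 3]

    def test_all_marker_degenerate(self):
        labels = np.ones((4, 4), dtype=np.int32)
        imposed = impose_minima(np.arange(16.0).reshape(4, 4), MarkerImage(labels, 1))
        assert np.ptp(imposed) == 0  # constant on the all-marker image

    def test_no_markers_is_an_error(self):
        with pytest.raises(ValueError):
            impose_minima(np.zeros((4, 4)), MarkerImage(np.zeros((4, 4), np.int32), 0))


class TestWatershed:
    def test_one_dimensional_ridge(self):
        surface = np.tile([0.0, 0.0, 9.0, 0.0, 0.0], (5, 1))
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[:, 0] = 1
        labels[:, 4] = 2
        res = watershed_transform(surface, MarkerImage(labels, 1))
        assert (res.labels[:, :2] == 1).all()
        assert (res.labels[:, 3:] == 2).all()
        assert (res.labels[:, 2] == 0).all()  # ridge on the barrier column

    def test_full_marker_partition_is_returned_unchanged(self, rng):
        labels = np.where(np.arange(36).reshape(6, 6) < 18, 1, 2).astype(np.int32)
        res = watershed_transform(rng.random((6, 6)), MarkerImage(labels, 1))
        assert np.array_equal(res.labels, labels)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            surface, labels, n = random_surface_and_markers(rng)
            if n < 2:
                continue
            res = watershed_transform(surface, MarkerImage(labels, n - 1))
            ref = watershed_reference(surface, labels)
            assert np.array_equal(res.labels, ref)

    def test_marker_fidelity_and_partition(self, rng):
        for _ in range(20):
            surface, labels, n = random_surface_and_markers(rng)
            if n < 2:
                continue
            res = watershed_transform(surface, MarkerImage(labels, n - 1))
            marked = labels > 0
            assert np.array_equal(res.labels[marked], labels[marked])
            # every pixel is ridge (0) or carries a valid label
            assert set(np.unique(res.labels)) <= set(range(0, n + 1))

    def test_fewer_than_two_labels_rejected(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[2, 2] = 1
        with pytest.raises(ValueError):
            watershed_transform(np.zeros((5, 5)), MarkerImage(labels, 1))

    def test_contours_are_closed_boundaries(self):
        surface = np.tile([0.0, 0.0, 9.0, 0.0, 0.0], (5, 1))
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[:, 0] = 1
        labels[:, 4] = 2
        res = watershed_transform(surface, MarkerImage(labels, 1))
        contour = res.contours[1]
        region = res.labels == 1
        assert all(region[r, c] for r, c in contour)
        # topmost-then-leftmost start
        assert tuple(contour[0]) == (0, 0)


class TestEditMarkers:
    def _markers(self):
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[2, 2] = 1
        labels[8, 8] = 2
        labels[0, 11] = 3  # background label (n_foreground = 2)
        return MarkerImage(labels=labels, n_foreground=2)

    def test_empty_edit_is_identity(self):
        m = self._markers()
        out = edit_markers(m)
        assert np.array_equal(out.labels, m.labels)
        assert out.n_foreground == 2

    def test_adding_a_new_label_increments_k(self):
        out = edit_markers(self._markers(), add=((5, 5, 9),))
        assert out.n_foreground == 3
        assert out.labels[5, 5] in (1, 2, 3)

    def test_removing_a_label_renumbers_contiguously(self):
        out = edit_markers(self._markers(), remove=((2, 2),))
        assert out.n_foreground == 1
        assert out.labels[8, 8] == 1
        assert out.labels[0, 11] == 2  # background renumbered to K'+1

    def test_remove_nonmarker_rejected(self):
        with pytest.raises(ValueError):
            edit_markers(self._markers(), remove=((5, 5),))

    def test_add_collision_rejected(self):
        with pytest.raises(ValueError):
            edit_markers(self._markers(), add=((2, 2, 2),))


def test_own_mask_segmentation_quality(default_phantom):
    """Markers from a slice's own truth mask reproduce the bones up to the
    one-pixel watershed line: the result contains the eroded truth and covers
    well above the 'accurate' overlap threshold."""
    from pelviseg.pipeline import segment_slice
    from pelviseg.evaluation import overlap_area

    img = default_phantom.stack.images[0]
    truth = default_phantom.truth_masks[0]
    res = segment_slice(img, truth)
    eroded = ndimage.binary_erosion(truth, S8)
    assert not (eroded & ~res.bone_mask).any()
    assert overlap_area(res.bone_mask, truth) >= 90.0
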