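import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from histotract import spatial as sp
from histotract import synthetic


class TestWmMaskFromDii:
    def test_phantom_jaccard(self, line_phantom):
        masks = sp.wm_mask_from_dii(line_phantom.dii_image)
        truth = line_phantom.masks.wm
        jaccard = (masks.wm & truth).sum() / (masks.wm | truth).sum()
        assert jaccard > 0.9

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="white matter"):
            sp.wm_mask_from_dii(np.zeros((64, 64)), threshold=0.5)

    def test_uniform_bright_degenerate(self):
        with pytest.warns(UserWarning, match="interface"):
            masks = sp.wm_mask_from_dii(np.ones((64, 64)), threshold=0.5)
        assert masks.wm.all()
        assert not masks.gm.any()
        assert masks.interface_pixels.shape[0] == 0

    def test_interface_invariant(self, line_phantom):
        masks = sp.wm_mask_from_dii(line_phantom.dii_image)
        for x, y in masks.interface_pixels[::53]:
            sl = np.s_[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2]
            assert masks.wm[sl].any() and masks.gm[sl].any()


class TestTissueMasksValidation:
    def test_overlap_rejected(self):
        full = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="exclusive"):
            sp.TissueMasks(full, full, np.zeros((8, 8), bool), np.empty((0, 2)))

    def test_gap_rejected(self):
        empty = np.zeros((8, 8), bool)
        with pytest.raises(ValueError, match="tile"):
            sp.TissueMasks(empty, empty, empty, np.empty((0, 2)))


class TestDistancesFromInjection:
    def test_paper_unit_conversion(self):
        d_um, excluded = sp.distances_from_injection(
            np.array([[1000.0, 0.0]]), (0.0, 0.0), 1000.0, 1.444
        )
        assert d_um[0] == pytest.approx(1444.0)
        # strict-inside rule: the boundary point is not excluded
        assert not excluded[0]
        _, excluded_in = sp.distances_from_injection(
            np.array([[999.0, 0.0]]), (0.0, 0.0), 1000.0, 1.444
        )
        assert excluded_in[0]

    def test_cluster_at_site(self):
        d_um, excluded = sp.distances_from_injection(
            np.array([[5.0, 5.0]]), (5.0, 5.0), 10.0, 1.0
        )
        assert d_um[0] == 0.0 and excluded[0]

    def test_3_4_5_triangle(self):
        d_um, _ = sp.distances_from_injection(np.array([[300.0, 400.0]]), (0.0, 0.0), 0.0, 1.0)
        assert d_um[0] == pytest.approx(500.0)

    def test_site_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sp.distances_from_injection(
                np.array([[1.0, 1.0]]), (-5.0, 0.0), 10.0, 1.0, image_shape=(64, 64)
            )

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError):
            sp.distances_from_injection(np.array([[1.0, 1.0]]), (0.0, 0.0), 10.0, 0.0)


def loop_weighted_median(values, weights):
    """Independent oracle: scan cumulative weights for the 0.5 quantile."""
    order = np.argsort(values)
    total = float(np.sum(weights))
    acc = 0.0
    for i in order:
        acc += weights[i]
        if acc >= 0.5 * total:
            return float(values[i])
    return float(values[order[-1]])


class TestWeightedCpd:
    def test_equal_weights_median(self):
        assert sp.weighted_cpd([1.0, 2.0, 3.0]).median_um == 2.0

    def test_heavy_first_value(self):
        assert sp.weighted_cpd([1.0, 10.0], [9.0, 1.0]).median_um == 1.0

    def test_single_value(self):
        cpd = sp.weighted_cpd([7.0])
        assert cpd.median_um == 7.0
        np.testing.assert_array_equal(cpd.cum_prob, [1.0])

    def test_cdf_shape_invariants(self):
        rng = np.random.default_rng(0)
        cpd = sp.weighted_cpd(rng.uniform(0, 100, 50), rng.uniform(0.1, 5, 50))
        assert np.all(np.diff(cpd.cum_prob) >= 0)
        assert cpd.cum_prob[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(cpd.distances_um) >= 0)

    def test_ordering_and_rescale_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 50, 30)
        weights = rng.uniform(0.5, 3.0, 30)
        base = sp.weighted_cpd(values, weights)
        perm = rng.permutation(30)
        shuffled = sp.weighted_cpd(values[perm], weights[perm] * 17.0)
        assert shuffled.median_um == base.median_um
        np.testing.assert_allclose(shuffled.cum_prob, base.cum_prob, atol=1e-12)

    @given(
        n=hst.integers(1, 30),
        seed=hst.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_median_matches_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, n)
        weights = rng.uniform(0.1, 4.0, n)
        assert sp.weighted_cpd(values, weights).median_um == loop_weighted_median(
            values, weights
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.weighted_cpd([])


class TestWmFraction:
    def _masks(self):
        wm = np.zeros((20, 20), bool)
        wm[:, :10] = True
        gm = ~wm
        gm[0, 0] = False
        background = np.zeros((20, 20), bool)
        background[0, 0] = True
        wm[0, 0] = False
        return sp.TissueMasks(wm, gm, background, sp.interface_from_masks(wm, gm))

    def test_all_in_wm(self):
        masks = self._masks()
        centers = np.array([[2.0, 5.0], [5.0, 12.0]])
        assert sp.wm_fraction(centers, [1.0, 1.0], masks) == 100.0

    def test_weighted_arithmetic(self):
        masks = self._masks()
        centers = np.array([[2.0, 5.0], [15.0, 5.0], [3.0, 12.0]])  # WM, GM, WM
        assert sp.wm_fraction(centers, [1.0, 1.0, 2.0], masks) == pytest.approx(75.0)

    def test_background_cluster_warns_and_partitions(self):
        masks = self._masks()
        centers = np.array([[0.0, 0.0], [2.0, 5.0]])
        with pytest.warns(UserWarning, match="background"):
            wm_pct = sp.wm_fraction(centers, [1.0, 1.0], masks)
        assert wm_pct == pytest.approx(50.0)

    def test_phantom_weight_fraction_roundtrip(self):
        tract = synthetic.TractSpec("line", dict(x0=40.0, y0=160.0, x1=440.0, y1=160.0))
        phantom = synthetic.make_tract_phantom((320, 480), tract, 20.0, seed=31)
        planted = synthetic.plant_clusters(
            phantom, 10, 1.0, 0.0, [50] * 10, seed=32, t_range=(0.1, 0.9)
        )
        # jitter=0 puts every center on the centerline, i.e. inside WM
        assert sp.wm_fraction(planted.centers, planted.sizes, phantom.masks) == 100.0


class TestInterfaceDistances:
    def test_on_interface_pixel(self, line_phantom):
        masks = line_phantom.masks
        x, y = masks.interface_pixels[0]
        d = sp.interface_distances(np.array([[float(x), float(y)]]), masks)
        assert d[0] == 0.0

    def test_straight_interface(self):
        wm = np.zeros((64, 200), bool)
        wm[:, :100] = True
        gm = ~wm
        masks = sp.TissueMasks(
            wm, gm, np.zeros((64, 200), bool), sp.interface_from_masks(wm, gm),
            pixel_scale_um=1.0,
        )
        # interface pixels sit at x=99 and x=100; a cluster at x=130 is 30 px
        # from the nearest interface pixel column
        d = sp.interface_distances(np.array([[130.0, 30.0]]), masks)
        assert d[0] == pytest.approx(30.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        wm = rng.uniform(size=(128, 128)) < 0.3
        wm[0, 0] = True  # guarantee both classes
        gm = ~wm
        masks = sp.TissueMasks(
            wm, gm, np.zeros((128, 128), bool), sp.interface_from_masks(wm, gm),
            pixel_scale_um=1.0,
        )
        centers = rng.uniform(0, 127, size=(25, 2))
        got = sp.interface_distances(centers, masks)
        pix = masks.interface_pixels.astype(float)
        for (cx, cy), d in zip(centers, got):
            brute = np.min(np.hypot(pix[:, 0] - cx, pix[:, 1] - cy))
            assert abs(d - brute) <= 1e-6

    def test_empty_interface_rejected(self):
        full = np.ones((8, 8), bool)
        masks = sp.TissueMasks(
            full, np.zeros((8, 8), bool), np.zeros((8, 8), bool), np.empty((0, 2))
        )
        with pytest.raises(ValueError, match="interface"):
            sp.interface_distances(np.array([[1.0, 1.0]]), masks)


class TestExclusionMonotonicity:
    def test_median_nondecreasing_in_radius(self):
        rng = np.random.default_rng(13)
        centers = rng.uniform(0, 500, size=(80, 2))
        weights = rng.uniform(0.5, 3.0, 80)
        medians = []
        for radius in (0.0, 50.0, 100.0, 200.0):
            d_um, excluded = sp.distances_from_injection(centers, (250.0, 250.0), radius, 1.0)
            keep = ~excluded
            medians.append(sp.weighted_cpd(d_um[keep], weights[keep]).median_um)
        assert all(b >= a for a, b in zip(medians, medians[1:]))
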