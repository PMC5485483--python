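import numpy as np
import pytest

from lggseg.densecrf import (
    CRFParams,
    PixelFeature,
    energy,
    mean_field,
    pairwise_kernel,
    refine_volume,
    unary_potentials,
)
from lggseg.imaging_core import BinaryMask, ScoreMap, Volume

TABLE_OPT = CRFParams(omega1=5, omega2=5, sigma_alpha=25, sigma_beta=10, sigma_gamma=5,
                      iterations=7)


def _probs(rng, shape):
    return rng.dirichlet((1, 1), size=shape)


class TestUnaryPotentials:
    def test_certain_probability_costs_nothing(self):
        p = np.zeros((1, 1, 2))
        p[..., 0] = 1.0
        u = unary_potentials(p)
        assert u[0, 0, 0] == pytest.approx(0.0)

    def test_analytic_value(self):
        q = np.exp(-2.0)
        p = np.dstack([np.full((1, 1), q), np.full((1, 1), 1 - q)])
        assert unary_potentials(p)[0, 0, 0] == pytest.approx(2.0)

    def test_zero_probability_clamped_finite(self):
        p = np.zeros((1, 1, 2))
        p[..., 1] = 1.0
        u = unary_potentials(p)
        assert u[0, 0, 0] == pytest.approx(-np.log(1e-10))
        assert np.isfinite(u).all()

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            unary_potentials(np.full((2, 2, 2), 0.7))


class TestPairwiseKernel:
    def test_identical_features_give_weight_sum(self):
        f = PixelFeature((3, 4), 50.0)
        assert pairwise_kernel(f, f, TABLE_OPT) == pytest.approx(10.0)

    def test_infinite_separation_decays_to_zero(self):
        a = PixelFeature((0, 0), 0.0)
        b = PixelFeature((1e6, 1e6), 255.0)
        assert pairwise_kernel(a, b, TABLE_OPT) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_at_distance_five(self):
        # 5*exp(-25/1250) + 5*exp(-25/50) with the optimized parameters
        a = PixelFeature((0, 0), 100.0)
        b = PixelFeature((5, 0), 100.0)
        expected = 5 * np.exp(-25 / 1250) + 5 * np.exp(-25 / 50)
        assert expected == pytest.approx(7.934, abs=1e-3)
        assert pairwise_kernel(a, b, TABLE_OPT) == pytest.approx(expected, rel=1e-12)


class TestMeanField:
    def test_zero_weights_leave_argmax_unchanged(self):
        rng = np.random.default_rng(0)
        probs = _probs(rng, (10, 10))
        img = rng.uniform(0, 255, (10, 10))
        params = CRFParams(omega1=0.0, omega2=0.0, iterations=5)
        res = mean_field(unary_potentials(probs), img, params)
        np.testing.assert_array_equal(res.labels, probs[..., 1] > probs[..., 0])

    def test_uniform_unary_stays_uniform(self):
        u = unary_potentials(np.full((8, 8, 2), 0.5))
        img = np.random.default_rng(1).uniform(0, 255, (8, 8))
        res = mean_field(u, img, TABLE_OPT)
        np.testing.assert_allclose(res.marginals, 0.5, atol=1e-12)

    def test_zero_iterations_returns_unary_softmax(self):
        rng = np.random.default_rng(2)
        probs = _probs(rng, (6, 6))
        params = CRFParams(iterations=0)
        res = mean_field(unary_potentials(probs), np.zeros((6, 6)), params)
        assert res.iterations_run == 0
        np.testing.assert_allclose(res.marginals, probs, atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_filtered_matches_dense_oracle(self, seed):
        """Truncated-window filtering equals the O(N^2) dense summation."""
        rng = np.random.default_rng(seed)
        H, W = rng.integers(8, 17, 2)
        probs = _probs(rng, (int(H), int(W)))
        img = rng.uniform(0, 255, (int(H), int(W)))
        params = CRFParams(
            omega1=float(rng.uniform(0, 10)),
            omega2=float(rng.uniform(0, 10)),
            sigma_alpha=float(rng.uniform(20, 70)),
            sigma_beta=float(rng.uniform(3, 10)),
            sigma_gamma=5.0,
            iterations=7,
        )
        u = unary_potentials(probs)
        dense = mean_field(u, img, params, mode="dense_exact")
        filt = mean_field(u, img, params, mode="filtered")
        assert np.abs(dense.marginals - filt.marginals).max() < 1e-6
        np.testing.assert_array_equal(dense.labels, filt.labels)

    def test_marginals_normalized_every_round(self):
        rng = np.random.default_rng(3)
        probs = _probs(rng, (12, 12))
        img = rng.uniform(0, 255, (12, 12))
        for it in (1, 3, 7):
            params = CRFParams(iterations=it)
            res = mean_field(unary_potentials(probs), img, params)
            np.testing.assert_allclose(res.marginals.sum(axis=-1), 1.0, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_field(np.zeros((4, 4, 2)), np.zeros((5, 4)), TABLE_OPT)

    def test_isolated_false_positives_removed(self):
        """CRF flips lone bright-probability pixels on a flat background."""
        rng = np.random.default_rng(0)
        H = W = 24
        truth = np.zeros((H, W))
        truth[8:16, 8:16] = 1
        p_t = np.where(truth > 0, 0.9, 0.1)
        fps = [(2, 2), (20, 3), (4, 20)]
        for r, c in fps:
            p_t[r, c] = 0.85
        img = np.where(truth > 0, 200.0, 60.0) + rng.normal(0, 5, (H, W))
        params = CRFParams(5, 5, 8, 10, 3, 5)
        res = mean_field(unary_potentials(np.dstack([1 - p_t, p_t])), img, params)
        assert all(res.labels[r, c] == 0 for r, c in fps)
        assert res.labels[10:14, 10:14].all()

    def test_spatial_weight_monotonely_smooths(self):
        """More spatial smoothing never adds isolated single-pixel islands."""
        from scipy.ndimage import gaussian_filter
        from skimage.measure import label as cc

        rng = np.random.default_rng(3)
        p_t = rng.uniform(0.2, 0.8, (16, 16))
        u = unary_potentials(np.dstack([1 - p_t, p_t]))
        img = gaussian_filter(rng.uniform(0, 255, (16, 16)), 3)

        def isolated(lbl):
            lab = cc(lbl, connectivity=2)
            return sum((lab == i).sum() == 1 for i in range(1, lab.max() + 1))

        counts = []
        for w2 in (0.0, 1.0, 2.0, 5.0, 10.0):
            res = mean_field(u, img, CRFParams(0.0, w2, 25, 10, 5, 5))
            counts.append(isolated(res.labels))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEnergy:
    def test_zero_weights_reduce_to_unary_sum(self):
        rng = np.random.default_rng(4)
        probs = _probs(rng, (5, 5))
        u = unary_potentials(probs)
        lab = (probs[..., 1] > 0.5).astype(int)
        params = CRFParams(omega1=0.0, omega2=0.0)
        expected = u.reshape(-1, 2)[np.arange(25), lab.ravel()].sum()
        assert energy(lab, u, rng.uniform(0, 255, (5, 5)), params) == pytest.approx(expected)

    def test_agreeing_pair_has_no_pairwise_cost(self):
        u = unary_potentials(np.full((1, 2, 2), 0.5))
        img = np.full((1, 2), 100.0)
        lab = np.array([[1, 1]])
        assert energy(lab, u, img, TABLE_OPT) == pytest.approx(2 * np.log(2))

    def test_two_pixel_disagreement_adds_kernel_value(self):
        u = unary_potentials(np.full((1, 2, 2), 0.5))
        img = np.full((1, 2), 100.0)
        k = pairwise_kernel(PixelFeature((0, 0), 100.0), PixelFeature((0, 1), 100.0), TABLE_OPT)
        e = energy(np.array([[0, 1]]), u, img, TABLE_OPT)
        assert e == pytest.approx(2 * np.log(2) + k)


class TestRefineVolume:
    def _scores(self, labels, stride=4):
        """Confident score maps whose upsampled argmax equals ``labels``."""
        maps = []
        for z in range(labels.shape[0]):
            sub = labels[z, ::stride, ::stride].astype(float)
            p_t = np.where(sub > 0, 0.99, 0.01)
            maps.append(ScoreMap(np.dstack([1 - p_t, p_t]), stride=stride))
        return maps

    def test_zero_pairwise_weights_reproduce_thresholded_scores(self):
        from lggseg.pipeline import raw_cnn_mask

        lab = np.zeros((2, 16, 16), dtype=np.uint8)
        lab[:, 4:12, 4:12] = 1
        vol = Volume(100.0 + 50.0 * lab.astype(float))
        params = CRFParams(omega1=0.0, omega2=0.0, iterations=3)
        maps = self._scores(lab)
        out = refine_volume(maps, vol, params)
        np.testing.assert_array_equal(out.labels, raw_cnn_mask(maps, vol.shape).labels)

    def test_runs_exactly_the_configured_rounds(self):
        lab = np.zeros((2, 16, 16), dtype=np.uint8)
        lab[:, 4:12, 4:12] = 1
        vol = Volume(100.0 + 50.0 * lab.astype(float))
        _, info = refine_volume(self._scores(lab), vol, TABLE_OPT, with_info=True)
        assert info["rounds"] == [7, 7]

    def test_noisy_unary_moves_toward_truth(self, block_volume):
        """CRF flips isolated false positives toward the ground truth."""
        vol, mask = block_volume
        rng = np.random.default_rng(6)
        maps = []
        for z in range(vol.shape[0]):
            sub = mask.labels[z, ::4, ::4].astype(float)
            p_t = np.where(sub > 0, 0.9, 0.1)
            # isolated false-positive scores sprinkled on the background
            n = p_t.size
            flip = rng.choice(n, size=3, replace=False)
            p_t.ravel()[flip] = np.maximum(p_t.ravel()[flip], 0.8)
            maps.append(ScoreMap(np.dstack([1 - p_t, p_t]), stride=4))
        params = CRFParams(5, 5, 8, 10, 3, 5)
        refined = refine_volume(maps, vol, params)
        from lggseg.pipeline import raw_cnn_mask

        raw = raw_cnn_mask(maps, vol.shape)
        err_raw = int((raw.labels != mask.labels).sum())
        err_ref = int((refined.labels != mask.labels).sum())
        assert err_ref < err_raw
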