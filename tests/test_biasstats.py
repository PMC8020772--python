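import numpy as np
import pytest

import serialrepro as sr
from serialrepro.biasstats import BiasField
from serialrepro.chains import ChainDataset, ChainRecord


def two_step_dataset(seeds, responses):
    chains = [
        ChainRecord(chain_id=i, points=np.array([s, r]))
        for i, (s, r) in enumerate(zip(seeds, responses))
    ]
    return ChainDataset(chains=chains)


class TestBiasField:
    def test_identity_chains_give_zero_field(self):
        rng = np.random.default_rng(0)
        pts = rng.random((50, 2))
        ds = two_step_dataset(pts, pts)
        field = sr.bias_field(ds, iteration=1)
        assert np.allclose(field.vectors, 0.0)

    def test_single_attractor_cam_biases_point_to_prototype(self):
        proto = np.array([0.6, 0.6])
        params = sr.CAMParams(w=0.7, c=5.0, prototypes=[proto])
        rng = np.random.default_rng(1)
        seeds = rng.random((200, 2))
        responses = sr.cam_predict(seeds, params)
        ds = two_step_dataset(seeds, responses)
        field = sr.bias_field(ds, iteration=1)
        toward = proto[None, :] - field.points
        dist = np.linalg.norm(toward, axis=1)
        cosines = np.sum(field.vectors * toward, axis=1) / (
            np.linalg.norm(field.vectors, axis=1) * dist
        )
        # direction is ill-defined right at the attractor; elsewhere the
        # binned average bias points at the prototype (bin-center quantization
        # allows a small angular wobble)
        assert np.all(cosines[dist > 0.05] > 0.95)

    def test_one_bin_equals_global_mean_bias(self):
        rng = np.random.default_rng(2)
        seeds = rng.random((40, 2))
        responses = np.clip(seeds + rng.normal(0, 0.05, (40, 2)), 0, 1)
        ds = two_step_dataset(seeds, responses)
        field = sr.bias_field(ds, iteration=1, bin_size=1.0)
        assert field.points.shape[0] == 1
        assert np.allclose(field.vectors[0], (responses - seeds).mean(axis=0))


class TestAngularCoherence:
    def test_identical_vectors_hit_maximum_ratio(self):
        rng = np.random.default_rng(0)
        pts = rng.random((30, 2)) * 0.2  # all within neighbor radius of peers
        field = BiasField(pts, np.tile([0.01, 0.02], (30, 1)), np.ones(30, dtype=int))
        out = sr.angular_coherence(field, neighbor_radius=0.5)
        assert out["band_ratio"] == pytest.approx(360.0 / 24.0)

    def test_uniform_random_directions_give_ratio_near_one(self):
        rng = np.random.default_rng(3)
        n = 400
        pts = rng.random((n, 2))
        theta = rng.uniform(-np.pi, np.pi, n)
        vecs = 0.02 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        field = BiasField(pts, vecs, np.ones(n, dtype=int))
        out = sr.angular_coherence(field, neighbor_radius=0.2)
        assert out["n_pairs"] > 5000
        assert out["band_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_no_qualifying_pairs_is_an_error(self):
        field = BiasField(
            np.array([[0.1, 0.1], [0.9, 0.9]]),
            np.array([[0.01, 0.0], [0.0, 0.01]]),
            np.ones(2, dtype=int),
        )
        with pytest.raises(ValueError, match="pairs"):
            sr.angular_coherence(field, neighbor_radius=0.05)


class TestBootstrapCI:
    def test_constant_statistic_gives_zero_width(self):
        ds = two_step_dataset(np.random.rand(10, 2), np.random.rand(10, 2))
        lo, hi = sr.bootstrap_ci(lambda d: 3.14, ds, n_boot=100, rng_seed=0)
        assert lo == hi == 3.14

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        ds = two_step_dataset(rng.random((30, 2)), rng.random((30, 2)))

        def stat(d):
            return float(d.response_points().mean())

        a = sr.bootstrap_ci(stat, ds, n_boot=200, rng_seed=11)
        b = sr.bootstrap_ci(stat, ds, n_boot=200, rng_seed=11)
        assert a == b

    def test_mean_ci_covers_truth_at_nominal_rate(self):
        # ~95% coverage for the mean of i.i.d. normals over replications
        cover = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            vals = rng.normal(0.5, 0.1, (40, 1, 2))
            ds = ChainDataset(
                chains=[
                    ChainRecord(chain_id=i, points=np.clip(
                        np.vstack([[[0.5, 0.5]], vals[i]]), 0, 1))
                    for i in range(40)
                ]
            )

            def stat(d):
                return float(d.response_points()[:, 0].mean())

            lo, hi = sr.bootstrap_ci(stat, ds, n_boot=150, rng_seed=rep)
            cover += lo <= 0.5 <= hi
        assert 0.88 <= cover / reps <= 0.99

    def test_fewer_than_two_chains_rejected(self):
        ds = two_step_dataset(np.random.rand(1, 2), np.random.rand(1, 2))
        with pytest.raises(ValueError):
            sr.bootstrap_ci(lambda d: 0.0, ds, n_boot=100, rng_seed=0)


class TestCorrelateMaps:
    def test_self_correlation_is_one(self, grid_2d, trimodal_prior_2d):
        assert sr.correlate_maps(trimodal_prior_2d, trimodal_prior_2d) == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self, grid_2d, trimodal_prior_2d):
        flipped = sr.DPrimeMap(grid_2d, -trimodal_prior_2d.mass + 1.0)
        assert sr.correlate_maps(trimodal_prior_2d, flipped) == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self, grid_2d):
        rng = np.random.default_rng(9)
        a = sr.DPrimeMap(grid_2d, rng.random(grid_2d.n_cells))
        b = sr.DPrimeMap(grid_2d, rng.random(grid_2d.n_cells))
        x, y = a.values, b.values
        manual = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert sr.correlate_maps(a, b) == pytest.approx(manual, abs=1e-12)

    def test_constant_map_rejected(self, grid_2d, trimodal_prior_2d):
        flat = sr.DPrimeMap(grid_2d, np.ones(grid_2d.n_cells))
        with pytest.raises(FloatingPointError):
            sr.correlate_maps(trimodal_prior_2d, flat)


class TestDisattenuate:
    def test_perfect_reliability_is_identity(self):
        for r in (-0.8, 0.0, 0.33):
            assert sr.disattenuate(r, 1.0, 1.0) == r

    def test_direct_formula(self):
        assert sr.disattenuate(0.5, 0.8, 0.8) == pytest.approx(0.625)

    def test_capped_at_one(self):
        assert sr.disattenuate(0.9, 0.5, 0.5) == 1.0

    def test_nonpositive_reliability_rejected(self):
        with pytest.raises(sr.DomainError):
            sr.disattenuate(0.5, 0.0, 0.8)


class TestUniformityTest:
    def test_equal_counts_give_zero_statistic(self):
        g = sr.Grid((4, 4))
        pts = g.centers.repeat(10, axis=0)
        stat, p = sr.uniformity_test(pts, grid_bins=4)
        assert stat == 0.0 and p == 1.0

    def test_concentrated_points_give_expected_statistic(self):
        # all N points in one of 16 bins: chi2 = N*15
        pts = np.tile([0.1, 0.1], (80, 1))
        stat, p = sr.uniformity_test(pts, grid_bins=4)
        assert stat == pytest.approx(80 * 15)
        assert p < 1e-10

    def test_null_p_values_roughly_uniform(self):
        # a light calibration check on the p-value distribution
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            _, p = sr.uniformity_test(rng.random((320, 2)), grid_bins=4)
            ps.append(p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 1e-3


class TestCenterOfMassPrior:
    def test_single_square_region_bump_at_centroid(self):
        mask = np.zeros((32, 32), dtype=int)
        mask[4:12, 20:28] = 1  # rows 4..11 (top), cols 20..27
        g = sr.Grid((64, 64))
        field = sr.center_of_mass_prior(mask, 0.05, g)
        peak = g.centers[np.argmax(field.mass)]
        assert peak[0] == pytest.approx((24.0) / 32, abs=1.0 / 32)  # x = col center
        assert peak[1] == pytest.approx(1.0 - 8.0 / 32, abs=1.0 / 32)  # y flipped

    def test_two_equal_regions_two_equal_bumps(self):
        mask = np.zeros((32, 32), dtype=int)
        mask[12:20, 2:10] = 1
        mask[12:20, 22:30] = 2
        g = sr.Grid((64, 64))
        field = sr.center_of_mass_prior(mask, 0.04, g)
        arr = field.as_array()
        assert np.allclose(arr, arr[::-1, :], atol=1e-9)  # symmetric in x

    def test_l_shaped_region_centroid_outside_region(self):
        mask = np.zeros((30, 30), dtype=int)
        mask[0:30, 0:6] = 1
        mask[24:30, 0:30] = 1
        g = sr.Grid((64, 64))
        field = sr.center_of_mass_prior(mask, 0.05, g)
        peak = g.centers[np.argmax(field.mass)]
        # centroid of the L lies off the arms (toward the corner's inside)
        ys, xs = np.nonzero(mask)
        cx, cy = (xs.mean() + 0.5) / 30, 1.0 - (ys.mean() + 0.5) / 30
        assert np.allclose(peak, [cx, cy], atol=1.5 / 64)
        col = int(np.floor(cx * 30))
        row = int(np.floor((1 - cy) * 30))
        assert mask[row, col] == 0  # the bump sits where the mask is empty

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sr.center_of_mass_prior(np.zeros((8, 8), dtype=int), 0.05, sr.Grid((16, 16)))
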