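import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import serialrepro as sr


@pytest.fixture(scope="module")
def fine_uniform():
    # grid chosen so that probes 0.45/0.55 sit exactly on cell centers
    g = sr.Grid((250,))
    return g, sr.normalize(np.ones(250), g)


class TestReproductionMoments:
    def test_identity_kernel_has_zero_variance(self, grid_1d, bimodal_prior_1d):
        lik = sr.LikelihoodMatrix(grid_1d, np.eye(grid_1d.n_cells))
        mu, cov = sr.reproduction_moments(bimodal_prior_1d, lik, 12)
        assert np.allclose(mu, grid_1d.cell_center(12))
        assert np.allclose(cov, 0.0, atol=1e-15)

    def test_fixed_uniform_interior_variance_is_twice_sigma_sq(self, fine_uniform):
        # encoding noise sigma^2 plus posterior-sampling noise sigma^2
        g, prior = fine_uniform
        sigma = 0.05
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(sigma), g)
        cell = g.point_to_cell([0.5])
        mu, cov = sr.reproduction_moments(prior, lik, cell)
        assert mu[0] == pytest.approx(g.cell_center(cell)[0], abs=1e-6)
        assert cov[0, 0] == pytest.approx(2 * sigma**2, rel=1e-3)

    def test_efficient_reproduction_displaced_near_mode(self, grid_1d, bimodal_prior_1d):
        # just inside the flank of a landmark the reproduction mean moves off
        # the stimulus (skewed noise); magnitude grows toward sparse regions
        lik = sr.build_likelihood(
            sr.EfficientEncodingObserver(bimodal_prior_1d, 0.1), grid_1d
        )
        pred = sr.DiscriminationPredictor(bimodal_prior_1d, lik)
        at_mode = grid_1d.point_to_cell([0.3])
        flank = grid_1d.point_to_cell([0.4])
        bias_mode = abs(pred.means[at_mode, 0] - grid_1d.cell_center(at_mode)[0])
        bias_flank = abs(pred.means[flank, 0] - grid_1d.cell_center(flank)[0])
        assert bias_flank > bias_mode


class TestPredictDprime:
    def test_identical_points_give_zero(self, grid_1d, bimodal_prior_1d):
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid_1d)
        assert sr.predict_dprime(bimodal_prior_1d, lik, [0.4], [0.4]) == 0.0

    def test_closed_form_limit_fixed_uniform(self, fine_uniform):
        g, prior = fine_uniform
        sigma, delta = 0.05, 0.1
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(sigma), g)
        d = sr.predict_dprime(prior, lik, [0.55], [0.45])
        assert d == pytest.approx(delta / (sigma * np.sqrt(2)), rel=0.02)

    def test_antisymmetric(self, fine_uniform):
        g, prior = fine_uniform
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), g)
        assert sr.predict_dprime(prior, lik, [0.45], [0.55]) == pytest.approx(
            -sr.predict_dprime(prior, lik, [0.55], [0.45]), abs=1e-12
        )

    def test_monotone_in_separation(self, fine_uniform):
        g, prior = fine_uniform
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), g)
        pred = sr.DiscriminationPredictor(prior, lik)
        deltas = [0.02, 0.05, 0.1, 0.15]
        values = [abs(pred.dprime([0.5 - d / 2], [0.5 + d / 2])) for d in deltas]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_mode_straddling_contrast_between_models(self, grid_1d, bimodal_prior_1d):
        # efficient: d' higher across a landmark than in the trough;
        # fixed: the reverse
        pair_mode = ([0.25], [0.35])
        pair_trough = ([0.45], [0.55])
        eff = sr.build_likelihood(
            sr.EfficientEncodingObserver(bimodal_prior_1d, 0.08), grid_1d
        )
        fix = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid_1d)
        pe = sr.DiscriminationPredictor(bimodal_prior_1d, eff)
        pf = sr.DiscriminationPredictor(bimodal_prior_1d, fix)
        assert abs(pe.dprime(*pair_mode)) > abs(pe.dprime(*pair_trough))
        assert abs(pf.dprime(*pair_mode)) < abs(pf.dprime(*pair_trough))


class TestDprimeMap:
    def test_uniform_prior_fixed_observer_map_is_flat(self):
        g = sr.Grid((32, 32))
        prior = sr.normalize(np.ones(g.n_cells), g)
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.06), g)
        dmap = sr.dprime_map_predicted(prior, lik, sr.Grid((16, 16)), radius=0.08)
        vals = dmap.values[dmap.retained & dmap.probe_grid.interior_mask(3)]
        assert vals.std() / vals.mean() < 0.02

    def test_sign_contrast_on_trimodal_prior(self, grid_2d, trimodal_prior_2d):
        from serialrepro.cli import _resample_density

        probe = sr.Grid((32, 32))
        prior_probe = _resample_density(trimodal_prior_2d, probe)
        eff = sr.build_likelihood(
            sr.EfficientEncodingObserver(trimodal_prior_2d, 0.1), grid_2d
        )
        fix = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid_2d)
        r_eff = sr.correlate_maps(
            prior_probe,
            sr.dprime_map_predicted(trimodal_prior_2d, eff, probe, 0.05),
            exclude_edge=2,
        )
        r_fix = sr.correlate_maps(
            prior_probe,
            sr.dprime_map_predicted(trimodal_prior_2d, fix, probe, 0.05),
            exclude_edge=2,
        )
        assert r_eff > 0 > r_fix

    def test_edge_probes_dropped(self, grid_2d, trimodal_prior_2d):
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid_2d)
        dmap = sr.dprime_map_predicted(
            trimodal_prior_2d, lik, sr.Grid((16, 16)), radius=0.1
        )
        arr = dmap.as_array()
        assert np.isnan(arr[0, 0]) and np.isnan(arr[-1, -1])
        assert np.isfinite(arr[8, 8])

    def test_radius_below_spacing_rejected(self, grid_2d, trimodal_prior_2d):
        lik = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid_2d)
        with pytest.raises(ValueError, match="radius"):
            sr.dprime_map_predicted(trimodal_prior_2d, lik, sr.Grid((16, 16)), 0.01)


class TestDprimeFromCounts:
    @pytest.mark.parametrize(
        "h,m,f,c,expected",
        [
            (10, 10, 10, 10, 0.0),  # chance
            (16, 4, 4, 16, norm.ppf(0.8) - norm.ppf(0.2)),
            (20, 0, 0, 20, norm.ppf(0.975) - norm.ppf(0.025)),  # 1/(2N) rule
        ],
    )
    def test_standard_quantile_oracle(self, h, m, f, c, expected):
        assert sr.dprime_from_counts(h, m, f, c) == pytest.approx(expected, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(sr.DomainError):
            sr.dprime_from_counts(-1, 5, 5, 5)

    def test_estimator_consistency_at_large_n(self):
        # equal-variance SDT generative model, unbiased criterion
        rng = np.random.default_rng(0)
        true_d = 1.2
        n = 2000
        hits = rng.binomial(n, norm.cdf(true_d / 2))
        fas = rng.binomial(n, norm.cdf(-true_d / 2))
        est = sr.dprime_from_counts(hits, n - hits, fas, n - fas)
        assert est == pytest.approx(true_d, abs=0.05)


class TestAnalyze2AFC:
    def test_recovers_per_probe_counts(self):
        g = sr.Grid((2, 2))
        rows = []
        # probe (0.25, 0.25): 16/20 hits, 4/20 false alarms
        for resp, cond, k in [
            ("shifted", "shifted", 16),
            ("same", "shifted", 4),
            ("shifted", "same", 4),
            ("same", "same", 16),
        ]:
            rows += [
                {"probe_x": 0.25, "probe_y": 0.25, "condition": cond, "response": resp}
            ] * k
        ds = sr.TwoAFCDataset(frame=pd.DataFrame(rows), radius=0.05)
        dmap = sr.analyze_2afc(ds, g)
        cell = g.point_to_cell([0.25, 0.25])
        assert dmap.values[cell] == pytest.approx(
            norm.ppf(0.8) - norm.ppf(0.2), abs=1e-9
        )
        assert np.isnan(np.delete(dmap.values, cell)).all()


class TestSmoothing:
    def test_zero_sd_same_resolution_is_identity(self):
        g = sr.Grid((8, 8))
        vals = np.arange(64, dtype=float)
        dmap = sr.DPrimeMap(g, vals)
        out = sr.smooth_dprime_map(dmap, kernel_sd=0.0)
        assert np.array_equal(out.values, vals)

    def test_constant_map_stays_constant(self):
        g = sr.Grid((8, 8))
        dmap = sr.DPrimeMap(g, np.full(64, 2.5))
        out = sr.smooth_dprime_map(dmap, kernel_sd=1.5, target_resolution=(16, 16))
        assert np.allclose(out.values, 2.5, atol=1e-6)

    def test_spike_peak_equals_kernel_center_weight(self):
        g = sr.Grid((15, 15))
        vals = np.zeros(225)
        vals[g.point_to_cell([0.5, 0.5])] = 1.0
        sd = 1.0
        out = sr.smooth_dprime_map(sr.DPrimeMap(g, vals), kernel_sd=sd)
        # independent arithmetic: truncated discrete Gaussian center weight
        k = np.exp(-0.5 * (np.arange(-4, 5) / sd) ** 2)
        k /= k.sum()
        assert out.as_array()[7, 7] == pytest.approx(k[4] ** 2, rel=1e-6)

    def test_coarser_target_rejected(self):
        g = sr.Grid((8, 8))
        dmap = sr.DPrimeMap(g, np.zeros(64))
        with pytest.raises(ValueError, match="resolution"):
            sr.smooth_dprime_map(dmap, 1.0, target_resolution=(4, 4))
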