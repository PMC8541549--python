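import numpy as np
import pandas as pd
import pytest

from eegcompare import topo
from eegcompare.montage import shared_montage


@pytest.fixture(scope="module")
def montage():
    return shared_montage()


class TestBiharmonicInterpolation:
    def test_reproduces_electrode_values_exactly(self, montage):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(29)
        w = topo.biharmonic_weights(montage.positions, v)
        at_electrodes = topo.biharmonic_evaluate(w, montage.positions,
                                                 montage.positions)
        assert np.max(np.abs(at_electrodes - v)) < 1e-8

    def test_constant_values_give_constant_map(self, montage):
        tm = topo.biharmonic_interpolate(np.full(29, 3.3), montage.positions,
                                         topo.HeadGrid(31))
        assert np.allclose(tm.values, 3.3, atol=1e-6)

    def test_plane_reproduced_in_interior(self, montage):
        """v(x, y) = 2x + 1 is recovered within 5% of the value range in
        the electrode-covered interior."""
        v = 2 * montage.positions[:, 0] + 1
        tm = topo.biharmonic_interpolate(v, montage.positions,
                                         topo.HeadGrid(67))
        r = np.linalg.norm(tm.grid.points, axis=1)
        interior = r < 0.6
        truth = 2 * tm.grid.points[interior, 0] + 1
        err = np.abs(tm.values[interior] - truth)
        assert err.max() < 0.05 * (v.max() - v.min())

    def test_duplicate_positions_rejected(self):
        pos = np.array([[0, 0], [0, 0], [1, 0]])
        with pytest.raises(ValueError, match="duplicate"):
            topo.biharmonic_weights(pos, np.arange(3.0))

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            topo.biharmonic_interpolate([1.0, 2.0],
                                        np.array([[0, 0], [0.5, 0]]))


class TestTopoMap:
    def test_default_grid_has_3409_pixels(self):
        grid = topo.HeadGrid()
        assert abs(grid.n_pixels - 3409) <= 0.03 * 3409

    def test_standardized_map_has_mean_zero_sd_one(self, montage):
        rng = np.random.default_rng(1)
        tm = topo.make_topomap(rng.standard_normal(29), montage,
                               standardize=True, grid=topo.HeadGrid(31))
        assert abs(tm.values.mean()) < 1e-9
        assert abs(tm.values.std(ddof=0) - 1) < 1e-9

    def test_missing_channels_drop_out(self, montage):
        values = pd.Series(np.arange(29.0), index=montage.labels)
        values = values.drop(["Oz", "Pz"])
        tm = topo.make_topomap(values, montage, grid=topo.HeadGrid(21))
        assert np.isfinite(tm.values).all()

    def test_global_shift_leaves_standardized_map_unchanged(self, montage):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(29)
        g = topo.HeadGrid(21)
        a = topo.make_topomap(v, montage, standardize=True, grid=g)
        b = topo.make_topomap(v + 42.0, montage, standardize=True, grid=g)
        assert np.allclose(a.values, b.values, atol=1e-8)


def oracle_permutation(D, alpha=0.05):
    """Independent transcription of the pixel-corrected sign-flip test:
    plain loops over all sign patterns, t -> Z via per-pixel H0 moments,
    thresholds from percentiles of the map extremes."""
    n, n_pix = D.shape
    patterns = []
    for code in range(2 ** n):
        signs = [1.0 if (code >> k) & 1 == 0 else -1.0 for k in range(n)]
        patterns.append(signs)
    t_all = np.empty((len(patterns), n_pix))
    for r, signs in enumerate(patterns):
        flipped = np.array([s * D[k] for k, s in enumerate(signs)])
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        t_all[r] = mean / (sd / np.sqrt(n))
    h0_mean = t_all.mean(axis=0)
    h0_sd = t_all.std(axis=0, ddof=0)
    z_all = (t_all - h0_mean) / h0_sd
    lower = np.percentile(z_all.min(axis=1), 100 * alpha / 2)
    upper = np.percentile(z_all.max(axis=1), 100 * (1 - alpha / 2))
    z_obs = (t_all[0] - h0_mean) / h0_sd  # pattern 0 is the identity
    return z_obs, lower, upper


class TestPermutationTest:
    def test_identical_conditions_nothing_significant(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((6, 40))
        res = topo.permutation_pixel_test(maps, maps)
        assert not res.sig_mask.any()
        assert np.allclose(res.observed_z, 0.0)

    def test_matches_exhaustive_oracle_n4(self):
        rng = np.random.default_rng(4)
        D = rng.standard_normal((4, 9))
        res = topo.permutation_pixel_test(D)
        z_obs, lower, upper = oracle_permutation(D)
        assert res.n_iter == 16
        assert res.lower_thr == pytest.approx(lower, abs=1e-10)
        assert res.upper_thr == pytest.approx(upper, abs=1e-10)
        assert np.allclose(res.observed_z, z_obs, atol=1e-10)

    def test_full_enumeration_ignores_seed(self):
        rng = np.random.default_rng(5)
        D = rng.standard_normal((6, 25))
        a = topo.permutation_pixel_test(D, seed=1)
        b = topo.permutation_pixel_test(D, seed=999)
        assert a.lower_thr == b.lower_thr and a.upper_thr == b.upper_thr
        assert np.array_equal(a.sig_mask, b.sig_mask)

    def test_monte_carlo_keeps_identity_pattern(self):
        rng = np.random.default_rng(6)
        D = rng.standard_normal((25, 16)) + 0.1
        res = topo.permutation_pixel_test(D, n_iter=400, seed=3,
                                          enumeration_cutoff=10)
        assert res.n_iter == 400
        # with the identity included, the observed max-Z cannot exceed the
        # largest recorded H0 maximum
        assert res.observed_z.max() <= res.max_t.max() + 1e-12

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(7)
        D = rng.standard_normal((10, 30))
        D[:, 5] += 4.0  # consistent shift on one pixel
        res = topo.permutation_pixel_test(D)
        assert res.sig_mask[5]


class TestElectrodePairSpearman:
    def test_identical_metrics_rho_one(self):
        rng = np.random.default_rng(8)
        m = rng.random((15, 22))
        rho, p = topo.electrode_pair_spearman(m, m)
        assert rho == pytest.approx(1.0)

    def test_independent_metrics_near_zero(self):
        """|rho| < 0.2 in at least 95 of 100 seeds for 15 x 22 null data."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a, b = rng.random((15, 22)), rng.random((15, 22))
            rho, _ = topo.electrode_pair_spearman(a, b)
            hits += abs(rho) < 0.2
        assert hits >= 95

    def test_missing_entries_removed_pairwise(self):
        a = np.array([[1.0, 2.0, np.nan, 4.0]])
        b = np.array([[1.5, np.nan, 3.0, 4.5]])
        with pytest.raises(ValueError, match="3 matched pairs"):
            topo.electrode_pair_spearman(a, b)


class TestPairedBandComparison:
    def _tables(self, n=15, seed=9, scale=None):
        rng = np.random.default_rng(seed)
        bands = ["delta", "theta", "alpha", "beta", "gamma"]
        a = pd.DataFrame(rng.gamma(4, 1, (n, 5)), columns=bands)
        b = pd.DataFrame(rng.gamma(4, 1, (n, 5)), columns=bands)
        if scale:
            a[scale] = b[scale] * 2.0 + rng.gamma(2, 0.2, n)
        return a, b

    def test_bonferroni_alpha_for_five_bands(self):
        a, b = self._tables()
        out = topo.paired_band_comparison(a, b, n_tests=5)
        assert np.allclose(out["alpha_adjusted"], 0.01, atol=1e-12)

    def test_identical_tables_rejected(self):
        a, _ = self._tables()
        with pytest.raises(ValueError, match="zero"):
            topo.paired_band_comparison(a, a.copy())

    def test_doubled_delta_detected_not_gamma(self):
        a, b = self._tables(scale="delta")
        out = topo.paired_band_comparison(a, b, n_tests=5)
        assert out.loc["delta", "significant"]
        assert not out.loc["gamma", "significant"]
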