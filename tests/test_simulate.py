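"""Synthetic spectra generator: determinism, mixing physics, distributions."""

import numpy as np
import pytest

from nircal import simulate
from nircal.simulate import (COMPONENTS, PURE_COMPONENTS, DistortionConfig,
                             gen_pure_spectra, gen_realistic_samples,
                             gen_standard_samples, kernel_population,
                             realistic_composition, standards_composition)


@pytest.fixture(scope="module")
def grid():
    return np.linspace(4000.0, 9000.0, 150)


class TestPureSpectra:
    def test_same_seed_identical_curves(self, grid):
        a, b = gen_pure_spectra(3, grid), gen_pure_spectra(3, grid)
        for name in PURE_COMPONENTS:
            np.testing.assert_array_equal(a.curves[name], b.curves[name])

    def test_curves_non_negative(self, grid):
        lib = gen_pure_spectra(4, grid)
        for c in lib.curves.values():
            assert (c >= 0).all()

    def test_different_seeds_differ_widely(self, grid):
        a, b = gen_pure_spectra(5, grid), gen_pure_spectra(6, grid)
        frac = np.mean(~np.isclose(a.curves["protein"], b.curves["protein"]))
        assert frac > 0.5


class TestStandards:
    def test_default_count_is_99(self, grid):
        lib = gen_pure_spectra(7, grid)
        ds = gen_standard_samples(lib, standards_composition(), seed=1)
        assert ds.n_samples == 99
        assert set(ds.roles) == {"synthetic"}

    def test_noiseless_mixing_is_exactly_linear(self, grid):
        lib = gen_pure_spectra(8, grid)
        cfg = standards_composition()
        ds = gen_standard_samples(lib, cfg, n=5, seed=2, noise_sd=0.0,
                                  baseline_sd=0.0)
        for i in range(5):
            conc = {k: ds.components.iloc[i][k] for k in PURE_COMPONENTS}
            np.testing.assert_array_equal(ds.absorbance[i], lib.mix(conc))

    def test_total_sugar_is_sum_of_sugars(self, grid):
        lib = gen_pure_spectra(9, grid)
        ds = gen_standard_samples(lib, standards_composition(), n=20, seed=3)
        sugars = ds.components[["fructose", "glucose", "sucrose"]].sum(axis=1)
        np.testing.assert_allclose(ds.components["total_sugar"], sugars)

    def test_sample_mean_matches_configured_mean(self, grid):
        lib = gen_pure_spectra(10, grid)
        cfg = standards_composition()
        ds = gen_standard_samples(lib, cfg, n=5000, seed=4)
        for name in PURE_COMPONENTS:
            vals = ds.components[name].to_numpy()
            # truncation pulls the realised mean slightly off; stay within
            # 3 standard errors of the (truncation-adjusted) sample spread
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - cfg.means[name]) <= max(3 * se, 0.25 * cfg.sds[name])


class TestRealistic:
    def test_zero_distortion_matches_standards_generator(self, grid):
        lib = gen_pure_spectra(11, grid)
        cfg = realistic_composition()
        ds = gen_realistic_samples(lib, cfg, DistortionConfig.none(), n=5,
                                   seed=5)
        for i in range(5):
            conc = {k: ds.components.iloc[i][k] for k in PURE_COMPONENTS}
            np.testing.assert_allclose(ds.absorbance[i], lib.mix(conc),
                                       atol=1e-12)

    def test_configured_correlation_reproduced(self, grid):
        lib = gen_pure_spectra(12, grid)
        cfg = realistic_composition()
        ds = gen_realistic_samples(lib, cfg, DistortionConfig.none(), n=5000,
                                   seed=6)
        r = np.corrcoef(ds.components["fructose"], ds.components["glucose"])[0, 1]
        target = cfg.correlation.loc["fructose", "glucose"]
        assert abs(r - target) <= 0.05

    def test_reference_bias_shifts_recorded_values(self, grid):
        lib = gen_pure_spectra(13, grid)
        cfg = realistic_composition()
        base = gen_realistic_samples(lib, cfg, DistortionConfig.none(), n=50,
                                     seed=7)
        dist = DistortionConfig.none()
        dist.reference_bias = {"protein": 2.0}
        shifted = gen_realistic_samples(lib, cfg, dist, n=50, seed=7)
        np.testing.assert_allclose(
            shifted.components["protein"] - base.components["protein"], 2.0)

    def test_saturation_increases_error_of_linear_world_model(self, grid):
        # a network trained on undistorted standards predicts distorted
        # spectra worse than undistorted ones
        from nircal import ANNConfig, PCNNCalibration
        from nircal.metrics import score

        lib = gen_pure_spectra(14, grid)
        std = gen_standard_samples(lib, standards_composition(), n=60,
                                   seed=8, noise_sd=0.0, baseline_sd=0.0)
        cfg = realistic_composition()
        clean = gen_realistic_samples(lib, cfg, DistortionConfig.none(),
                                      n=60, seed=9)
        sat = DistortionConfig.none()
        sat.saturation_gamma = 0.8
        warped = gen_realistic_samples(lib, cfg, sat, n=60, seed=9)
        pnn_cfg = ANNConfig(n_neurons=10, activation="tanh", epochs=4000,
                            seed=15)
        cnn_cfg = ANNConfig(n_neurons=2, activation="tanh", epochs=10, seed=16)
        res = PCNNCalibration(std, clean.subset(range(10)), "protein",
                              pnn_cfg, cnn_cfg, k=10, threshold=0.0).fit()
        y = clean.component_values("protein")
        rmse_clean = score(y, res.predict(clean).y0).rmse
        rmse_warped = score(warped.component_values("protein"),
                            res.predict(warped).y0).rmse
        assert rmse_warped > rmse_clean

    def test_standards_spread_wider_than_kernels(self, grid):
        lib = gen_pure_spectra(15, grid)
        std = gen_standard_samples(lib, standards_composition(), n=500,
                                   seed=10)
        krn = gen_realistic_samples(lib, kernel_population(),
                                    DistortionConfig.none(), n=500, seed=11)
        for name in COMPONENTS:
            iqr_std = np.subtract(*np.percentile(std.components[name],
                                                 [75, 25]))
            iqr_krn = np.subtract(*np.percentile(krn.components[name],
                                                 [75, 25]))
            assert iqr_std > iqr_krn, name


class TestBenchmark:
    def test_shapes_and_seed_structure(self, bench):
        assert bench.standards.n_samples == 99
        assert bench.realistic.n_samples == 246
        assert len(set(bench.shuffle_seeds)) == 10
        assert all(0 <= s < 2**31 for s in bench.shuffle_seeds)

    def test_reproducible_byte_identical_csv(self, tmp_path):
        from nircal import write_spectra

        a = simulate.benchmark_suite(33)
        b = simulate.benchmark_suite(33)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(a.standards, pa)
        write_spectra(b.standards, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_give_different_data(self):
        a = simulate.benchmark_suite(1)
        b = simulate.benchmark_suite(2)
        assert not np.array_equal(a.standards.absorbance,
                                  b.standards.absorbance)
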