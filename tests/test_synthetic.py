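import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoniche.io import DriverLayer, GridSpec
from isoniche.synthetic import (DTDF, REGION_BOXES, PUBLISHED_PARAMS, ScenarioSpec,
                                SourceGroup, SpeciesRegionParams,
                                gen_driver_layers, gen_isotope_samples,
                                gen_longline_sets, gen_mixture_consumers,
                                gen_scenario)

BS_MED = next(p for p in PUBLISHED_PARAMS
              if p.species == "blue_shark" and p.region == "w_mediterranean")


class TestIsotopeSamples:
    def test_published_parameterization_reproduced(self):
        # Mediterranean blue shark: n=45, mu=(-17.49, 11.29), sd=(0.96, 1.32)
        df = gen_isotope_samples([BS_MED], seed=5)
        assert len(df) == 45
        for col, mu, sd in (("d13c", -17.49, 0.96), ("d15n", 11.29, 1.32)):
            assert abs(df[col].mean() - mu) < 3 * sd / np.sqrt(45)

    def test_zero_n_gives_empty_table(self):
        p = SpeciesRegionParams("x", "canary", 0, 0, 1, 0, 1)
        df = gen_isotope_samples([p], seed=0)
        assert len(df) == 0

    def test_independent_axes_have_near_zero_correlation(self):
        p = SpeciesRegionParams("x", "canary", 100_000, 0, 1, 0, 1, rho=0)
        df = gen_isotope_samples([p], seed=1)
        r = np.corrcoef(df["d13c"], df["d15n"])[0, 1]
        assert abs(r) < 0.02

    def test_moments_converge_at_three_se(self):
        n = 10_000
        p = SpeciesRegionParams("x", "canary", n, -18.0, 0.5, 11.0, 1.0, rho=0.3)
        df = gen_isotope_samples([p], seed=2)
        assert abs(df["d13c"].mean() + 18.0) < 3 * 0.5 / np.sqrt(n)
        assert abs(df["d15n"].mean() - 11.0) < 3 * 1.0 / np.sqrt(n)
        # SD standard error ~ sd/sqrt(2n)
        assert abs(df["d13c"].std(ddof=1) - 0.5) < 3 * 0.5 / np.sqrt(2 * n)
        r = np.corrcoef(df["d13c"], df["d15n"])[0, 1]
        assert abs(r - 0.3) < 3 * (1 - 0.3**2) / np.sqrt(n)

    def test_locations_inside_region_box(self):
        df = gen_isotope_samples(seed=3)
        for region, box in REGION_BOXES.items():
            sub = df[df["region"] == region]
            assert sub["lon"].between(box.lon_min, box.lon_max).all()
            assert sub["lat"].between(box.lat_min, box.lat_max).all()

    def test_fixed_seed_is_bit_identical(self):
        a = gen_isotope_samples(seed=11)
        b = gen_isotope_samples(seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SpeciesRegionParams("x", "r", 5, 0, -1.0, 0, 1)
        with pytest.raises(ValueError):
            SpeciesRegionParams("x", "r", 5, 0, 1.0, 0, 1, rho=1.0)


@pytest.fixture(scope="module")
def flat_intensity():
    grid = GridSpec(-10, 30, 1, 8, 6)
    lam = 2.0 / 1000.0  # 2 individuals per 1000 hooks
    return {"sp": DriverLayer("sp", grid, np.full((6, 8), np.log(lam)))}


class TestLonglineSets:
    def test_doubling_hooks_doubles_mean_catch(self, flat_intensity):
        a = gen_longline_sets(flat_intensity, n_sets=10_000, hooks=(1000, 1000), seed=4)
        b = gen_longline_sets(flat_intensity, n_sets=10_000, hooks=(2000, 2000), seed=4)
        ratio = b["catch_sp"].mean() / a["catch_sp"].mean()
        assert abs(ratio - 2.0) < 0.15

    def test_large_dispersion_approaches_poisson(self, flat_intensity):
        df = gen_longline_sets(flat_intensity, n_sets=20_000, hooks=(1000, 1000),
                               dispersion=1e6, seed=5)
        vm = df["catch_sp"].var(ddof=1) / df["catch_sp"].mean()
        assert abs(vm - 1.0) < 0.08

    def test_small_dispersion_is_overdispersed(self, flat_intensity):
        df = gen_longline_sets(flat_intensity, n_sets=20_000, hooks=(1000, 1000),
                               dispersion=1.0, seed=5)
        assert df["catch_sp"].var(ddof=1) / df["catch_sp"].mean() > 1.5

    def test_full_survey_structure(self, flat_intensity):
        df = gen_longline_sets(flat_intensity, n_sets=2534, seed=6)
        assert len(df) == 2534
        for col in ("lon", "lat", "hooks", "year", "month", "boat", "gear", "catch_sp"):
            assert col in df.columns and df[col].notna().all()
        assert df["gear"].nunique() == 5

    def test_nonpositive_hooks_rejected(self, flat_intensity):
        with pytest.raises(ValueError):
            gen_longline_sets(flat_intensity, n_sets=10, hooks=(0, 100), seed=0)


class TestDriverLayers:
    GRID = GridSpec(-21, 24, 1, 30, 19)

    def test_collinear_mode_reproduces_high_spearman(self):
        layers = gen_driver_layers(self.GRID, seed=0, collinear_chl=True)
        rho = stats.spearmanr(layers["Chl"].values.ravel(),
                              layers["OPFish"].values.ravel()).statistic
        assert rho > 0.8

    def test_infinite_smoothness_degenerates_to_constant(self):
        layers = gen_driver_layers(self.GRID, smoothness=np.inf, seed=1)
        assert np.ptp(layers["MLD"].values) == 0

    def test_fields_positive(self):
        layers = gen_driver_layers(self.GRID, seed=2)
        for lay in layers.values():
            assert (lay.values > 0).all()

    def test_two_seeds_distinct_but_same_moments(self):
        a = gen_driver_layers(self.GRID, seed=3)["MLD"].values
        b = gen_driver_layers(self.GRID, seed=4)["MLD"].values
        assert not np.allclose(a, b)
        # log-field is Normal(3.5, 0.5) by construction in both draws
        assert abs(np.log(a).mean() - np.log(b).mean()) < 0.3
        assert abs(np.log(a).std() - np.log(b).std()) < 0.2


class TestMixtureConsumers:
    def test_single_source_zero_noise_is_degenerate(self):
        src = [SourceGroup("s", -18.0, 10.0, 1e-9, 1e-9)]
        dtdf = DTDF((1.0,), (3.4,), (0.0,), (0.0,))
        df = gen_mixture_consumers(src, [1.0], dtdf, n=5, resid_sd=0.0, seed=0)
        assert np.allclose(df["d13c"], -17.0) and np.allclose(df["d15n"], 13.4)

    def test_symmetric_sources_centre_consumers_at_origin(self):
        src = [SourceGroup("a", -1.0, -1.0, 0.3, 0.3), SourceGroup("b", 1.0, 1.0, 0.3, 0.3)]
        dtdf = DTDF((0.0,) * 2, (0.0,) * 2, (0.0,) * 2, (0.0,) * 2)
        df = gen_mixture_consumers(src, [0.5, 0.5], dtdf, n=4000, resid_sd=0.1, seed=1)
        assert abs(df["d13c"].mean()) < 0.05 and abs(df["d15n"].mean()) < 0.05

    def test_moment_formulas_by_method_of_moments(self, three_sources):
        p = np.array([0.5, 0.3, 0.2])
        dtdf = DTDF.constant(3)
        df = gen_mixture_consumers(three_sources, p, dtdf, n=100_000,
                                   resid_sd=0.25, seed=2)
        mu_c = p @ (np.array([s.mu_c for s in three_sources]) + np.array(dtdf.delta_c))
        var_c = (p**2) @ (np.array([s.sd_c for s in three_sources])**2
                          + np.array(dtdf.sd_c)**2) + 0.25**2
        assert abs(df["d13c"].mean() - mu_c) < 4 * np.sqrt(var_c / 1e5)
        assert abs(df["d13c"].var(ddof=1) - var_c) < 4 * var_c * np.sqrt(2 / 1e5)

    def test_invalid_simplex_rejected(self, three_sources):
        with pytest.raises(ValueError):
            gen_mixture_consumers(three_sources, [0.5, 0.3], DTDF.constant(2), n=5)
        with pytest.raises(ValueError):
            gen_mixture_consumers(three_sources, [0.5, 0.3, 0.3], DTDF.constant(3), n=5)


class TestScenario:
    def test_zero_separation_gives_zero_ccd(self):
        from isoniche.competition import compute_ccd
        df, _ = gen_scenario(ScenarioSpec("high", "low", separation=0.0),
                             n_per_species=4000, seed=0)
        cents = (df.groupby("species").agg(c_d13c=("d13c", "mean"),
                                           c_d15n=("d15n", "mean")).reset_index())
        cents["key"] = "q"
        ccd = compute_ccd(cents)
        assert ccd["ccd"].max() < 0.05

    def test_configured_separation_recovered(self):
        from isoniche.competition import compute_ccd
        df, info = gen_scenario(ScenarioSpec("low", "high", separation=5.0),
                                n_per_species=4000, seed=1)
        cents = (df.groupby("species").agg(c_d13c=("d13c", "mean"),
                                           c_d15n=("d15n", "mean")).reset_index())
        cents["key"] = "q"
        ccd = compute_ccd(cents)
        assert np.allclose(ccd["ccd"], 5.0, atol=0.1)
        assert info["abundance"] > 5  # high-abundance level

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("medium", "low")
        with pytest.raises(ValueError):
            ScenarioSpec("high", "low", separation=-1.0)
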