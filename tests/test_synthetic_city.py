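"""Synthetic-city generator tests: determinism, planted structure, survey."""

import numpy as np
import pytest
from scipy import stats

from epirisk import taxonomy
from epirisk.synthetic_city import (
    SyntheticCityConfig,
    generate_city,
    generate_survey,
)


def small_config(**kw):
    base = dict(
        extent_m=(4000.0, 4000.0),
        n_hotspots=2,
        n_poi=400,
        n_sites=40,
        n_respondents=50,
        seed=0,
    )
    base.update(kw)
    return SyntheticCityConfig(**base)


class TestConfigValidation:
    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            SyntheticCityConfig(extent_m=(0.0, 100.0))
        with pytest.raises(ValueError):
            SyntheticCityConfig(hotspot_sigma_m=-1.0)

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            SyntheticCityConfig(poi_category_props={"a": 0.5, "b": 0.4})

    def test_rejects_bad_survey_means(self):
        with pytest.raises(ValueError):
            SyntheticCityConfig(survey_means={"catering_service": 0.5})


class TestGenerateCity:
    def test_deterministic_given_seed(self):
        a = generate_city(small_config(seed=7))
        b = generate_city(small_config(seed=7))
        assert np.array_equal(a.population.values, b.population.values)
        assert np.array_equal(a.night_light.values, b.night_light.values)
        assert a.pois.equals(b.pois)
        assert np.array_equal(a.sites, b.sites)
        assert np.array_equal(a.truth_hotspots, b.truth_hotspots)
        assert all(np.array_equal(r1, r2) for r1, r2 in zip(a.roads, b.roads))

    def test_different_seeds_differ(self):
        a = generate_city(small_config(seed=1))
        b = generate_city(small_config(seed=2))
        assert not np.array_equal(a.population.values, b.population.values)

    def test_no_hotspots_population_within_noise_band(self):
        cfg = small_config(n_hotspots=0, pop_hotspot_gain=0.0, noise_sigma=0.1)
        city = generate_city(cfg)
        vals = city.population.values
        # lognormal(0, 0.1) multiplicative noise: 5 sigma band around the base
        assert np.all(vals > cfg.pop_base * np.exp(-0.5))
        assert np.all(vals < cfg.pop_base * np.exp(0.5))

    def test_all_pois_inside_extent(self):
        city = generate_city(small_config(seed=3))
        w, h = city.config.extent_m
        assert city.pois["x"].between(0, w).all()
        assert city.pois["y"].between(0, h).all()

    def test_rasters_nonnegative(self):
        city = generate_city(small_config(seed=4))
        assert np.all(city.population.values >= 0)
        assert np.all(city.night_light.values >= 0)

    def test_roads_form_connected_network(self):
        from epirisk.road_network import build_graph

        city = generate_city(small_config(seed=5))
        graph = build_graph(city.roads, snap_tol_m=0.5)
        assert graph.is_connected()

    def test_commercial_share_matches_inventory(self):
        cfg = small_config(n_poi=50_000, seed=11)
        city = generate_city(cfg)
        share = (city.pois["category"] == "commercial").mean()
        assert share == pytest.approx(
            taxonomy.category_proportions()["commercial"], abs=0.01
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_category_counts_multinomial_gof(self, seed):
        cfg = small_config(n_poi=50_000, seed=seed)
        city = generate_city(cfg)
        props = cfg.poi_category_props
        counts = city.pois["category"].value_counts()
        obs = np.array([counts.get(c, 0) for c in props])
        exp = np.array([p * cfg.n_poi for p in props.values()])
        _, p_value = stats.chisquare(obs, exp)
        assert p_value > 0.001

    @pytest.mark.parametrize("seed", range(8))
    def test_population_elevated_inside_hotspot_footprints(self, seed):
        cfg = small_config(seed=seed)  # gain 400 >> 3 x noise scale
        city = generate_city(cfg)
        cx, cy = city.population.cell_centers()
        inside = np.zeros(cx.shape, dtype=bool)
        for hx, hy in city.truth_hotspots:
            inside |= np.hypot(cx - hx, cy - hy) <= 2 * cfg.hotspot_sigma_m
        assert city.population.values[inside].mean() > city.population.values[~inside].mean()

    def test_sites_concentrate_near_hotspots(self):
        cfg = small_config(n_sites=400, seed=6)
        city = generate_city(cfg)
        d = np.min(
            np.hypot(
                city.sites[:, 0:1] - city.truth_hotspots[:, 0][None, :],
                city.sites[:, 1:2] - city.truth_hotspots[:, 1][None, :],
            ),
            axis=1,
        )
        frac_near = (d <= 2 * cfg.hotspot_sigma_m).mean()
        assert frac_near >= 0.8


class TestGenerateSurvey:
    def test_boundary_mean_five_is_exact(self):
        cfg = small_config(survey_means={"catering_service": 5.0}, n_respondents=30)
        sampled, exact = generate_survey(cfg)
        assert sampled.table["mean"].iloc[0] == 5.0
        assert sampled.table["sd"].iloc[0] == 0.0
        assert exact.table["mean"].iloc[0] == 5.0

    def test_large_sample_mean_concentrates(self):
        cfg = small_config(
            survey_means={"catering_service": 3.0}, n_respondents=10_000, seed=2
        )
        sampled, _ = generate_survey(cfg)
        assert 2.95 <= sampled.table["mean"].iloc[0] <= 3.05

    def test_noiseless_table_equals_targets(self):
        cfg = small_config()
        _, exact = generate_survey(cfg)
        for sub, mu in cfg.survey_means.items():
            row = exact.table[exact.table["subcategory"] == sub]
            assert row["mean"].iloc[0] == mu

    def test_default_sample_means_near_targets(self):
        cfg = small_config(n_respondents=204, seed=8)
        sampled, _ = generate_survey(cfg)
        for sub, mu in cfg.survey_means.items():
            m = sampled.table.loc[sampled.table["subcategory"] == sub, "mean"].iloc[0]
            assert abs(m - mu) <= 0.15

    def test_responses_are_valid_likert(self):
        cfg = small_config(n_respondents=2)
        sampled, _ = generate_survey(cfg)
        assert sampled.table["mean"].between(1, 5).all()

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            generate_survey(small_config(n_respondents=1))
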