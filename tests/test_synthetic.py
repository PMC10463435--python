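"""Synthetic study generator: determinism, calibration, known ground truth."""

import numpy as np
import pandas as pd
import pytest

from stratq import (Coupling, StrataAssignment, StrataEffect, SyntheticConfig,
                    build_weights, factor_q, generate_city_lattice,
                    generate_individuals, generate_pollutants,
                    generate_response, morans_i, strata_means_for_q)
from stratq.synthetic import POLLUTANTS


class TestCityLattice:
    def test_empty_when_zero_cities(self):
        cfg = SyntheticConfig(n_cities=0, n_individuals=0)
        assert len(generate_city_lattice(cfg)) == 0

    def test_study_scale_both_regions_nonempty(self):
        cfg = SyntheticConfig(seed=2)
        cities = generate_city_lattice(cfg)
        assert len(cities) == 122
        assert set(cities["region"]) == {"north", "south"}
        lon0, lat0, lon1, lat1 = cfg.bbox
        assert cities["lon"].between(lon0, lon1).all()
        assert cities["lat"].between(lat0, lat1).all()

    def test_region_is_latitude_threshold(self):
        cities = generate_city_lattice(SyntheticConfig(seed=5))
        north = cities["region"] == "north"
        assert (cities.loc[north, "lat"] >= 33.0).all()
        assert (cities.loc[~north, "lat"] < 33.0).all()

    def test_deterministic_for_fixed_seed(self):
        a = generate_city_lattice(SyntheticConfig(seed=9))
        b = generate_city_lattice(SyntheticConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_bbox_rejected(self):
        with pytest.raises(ValueError, match="bbox"):
            generate_city_lattice(SyntheticConfig(bbox=(10, 40, 5, 50),
                                                  region_split_latitude=45))


class TestPollutants:
    def test_positive_and_deterministic(self, small_config, small_cities):
        assert (small_cities[list(POLLUTANTS)] > 0).all().all()
        again = generate_pollutants(generate_city_lattice(small_config),
                                    small_config)
        pd.testing.assert_frame_equal(small_cities, again)

    def test_mean_calibration_at_large_n(self):
        # 2000 cities with no spatial correlation: each pollutant's
        # region-wise sample mean sits within 3 SE of its target
        cfg = SyntheticConfig(n_cities=2000, n_individuals=0, seed=4)
        for s in cfg.pollutant_specs.values():
            s.corr_range_km = 0.0
        cities = generate_pollutants(generate_city_lattice(cfg), cfg)
        north = cities["region"] == "north"
        for name in POLLUTANTS:
            spec = cfg.pollutant_specs[name]
            for mask, mean, sd in ((north, spec.mean_north, spec.sd_north),
                                   (~north, spec.mean_south, spec.sd_south)):
                x = cities.loc[mask, name]
                se = sd / np.sqrt(mask.sum())
                assert abs(x.mean() - mean) < 3 * se, name

    def test_zero_range_uncorrelated_between_cities(self):
        # split one long run into pairs: correlation across distinct
        # cities is statistically indistinguishable from zero
        cfg = SyntheticConfig(n_cities=2000, n_individuals=0, seed=8)
        for s in cfg.pollutant_specs.values():
            s.corr_range_km = 0.0
        cities = generate_pollutants(generate_city_lattice(cfg), cfg)
        x = cities["pm25"].to_numpy()
        r = np.corrcoef(x[::2], x[1::2])[0, 1]
        assert abs(r) < 3 / np.sqrt(1000)

    def test_long_range_field_positively_autocorrelated(self):
        """With correlation range far beyond the bbox extent, the field's
        Moran's I is positive on average over 200 replicates."""
        i_vals = []
        for rep in range(200):
            cfg = SyntheticConfig(n_cities=40, n_individuals=0, seed=1000 + rep,
                                  bbox=(100.0, 30.0, 104.0, 34.0),
                                  region_split_latitude=32.0)
            for s in cfg.pollutant_specs.values():
                s.corr_range_km = 5000.0
            cities = generate_pollutants(generate_city_lattice(cfg), cfg)
            w = build_weights(cities[["lon", "lat"]].to_numpy(), k=5)
            i_vals.append(morans_i(cities["so2"].to_numpy(), w,
                                   inference="normal").I)
        i_vals = np.asarray(i_vals)
        assert i_vals.mean() > 3 * i_vals.std() / np.sqrt(len(i_vals))

    def test_negative_target_mean_rejected(self):
        cfg = SyntheticConfig()
        cfg.pollutant_specs["so2"].mean_north = -5.0
        with pytest.raises(ValueError, match="positive"):
            cfg.validate()


class TestResponse:
    @staticmethod
    def equal_strata(n, L=2):
        return StrataAssignment.from_labels(np.repeat(np.arange(L), n // L))

    def test_closed_form_theoretical_q(self):
        # means (0.4, 0.6) in equal strata, sigma_w = 0.1:
        # Var_between = 0.01, q = 0.01 / (0.01 + 0.01) = 0.5
        cities = generate_city_lattice(SyntheticConfig(n_cities=100, seed=1))
        draw = generate_response(cities, self.equal_strata(100),
                                 StrataEffect([0.4, 0.6], 0.1), seed=1)
        assert draw.theoretical_q == pytest.approx(0.5)

    def test_zero_noise_gives_q_one(self):
        cities = generate_city_lattice(SyntheticConfig(n_cities=10, seed=1))
        draw = generate_response(cities, self.equal_strata(10),
                                 StrataEffect([0.2, 0.8], 0.0), seed=1)
        assert draw.theoretical_q == 1.0
        assert factor_q(draw.values, self.equal_strata(10)).q == 1.0

    def test_equal_means_give_q_zero(self):
        cities = generate_city_lattice(SyntheticConfig(n_cities=10, seed=1))
        draw = generate_response(cities, self.equal_strata(10),
                                 StrataEffect([0.5, 0.5], 0.1), seed=1)
        assert draw.theoretical_q == 0.0

    def test_missing_stratum_mean_rejected(self):
        cities = generate_city_lattice(SyntheticConfig(n_cities=9, seed=1))
        strata = StrataAssignment.from_labels(np.repeat([0, 1, 2], 3))
        with pytest.raises(ValueError, match="means configured"):
            generate_response(cities, strata, StrataEffect([0.4, 0.6], 0.1),
                              seed=1)

    def test_clipping_recorded(self):
        cities = generate_city_lattice(SyntheticConfig(n_cities=50, seed=1))
        draw = generate_response(cities, self.equal_strata(50),
                                 StrataEffect([0.05, 0.95], 0.2), seed=3,
                                 clip_to_unit=True)
        assert draw.clipped and draw.n_clipped > 0
        assert ((draw.values >= 0) & (draw.values <= 1)).all()

    def test_strata_means_for_q_inverts_decomposition(self):
        for target in (0.1, 0.5, 0.9):
            means = strata_means_for_q(target, within_sd=0.1, L=5)
            n_h = np.full(5, 20)
            var_b = np.average((np.asarray(means) - np.mean(means)) ** 2,
                               weights=n_h)
            assert var_b / (var_b + 0.01) == pytest.approx(target)


class TestIndividuals:
    def test_exact_count_and_validity(self, small_cities, small_config):
        ind = generate_individuals(small_cities, small_config)
        assert len(ind) == small_config.n_individuals
        assert (ind["age"] >= 45).all()
        assert (ind["height_cm"] > 0).all() and (ind["weight_kg"] > 0).all()
        assert set(ind["city_id"]) <= set(small_cities["city_id"])

    def test_study_scale_proportions(self):
        cfg = SyntheticConfig(seed=6)
        cities = generate_pollutants(generate_city_lattice(cfg), cfg)
        ind = generate_individuals(cities, cfg)
        assert len(ind) == 16171
        middle = (ind["age"] < 60).mean()
        female = (ind["sex"] == "female").mean()
        assert abs(middle - 0.491) < 3 * np.sqrt(0.25 / len(ind))
        assert abs(female - 0.537) < 3 * np.sqrt(0.25 / len(ind))

    def test_degenerate_bmi_forces_full_prevalence(self, small_cities,
                                                   small_config):
        from stratq import aggregate_prevalence
        from stratq.synthetic import BMIGroupModel

        cfg = small_config
        cfg.bmi_model = {"middle_aged": BMIGroupModel(25.0, 0.0),
                         "elderly": BMIGroupModel(25.0, 0.0)}
        cfg.region_bmi_shift = {}
        ind = generate_individuals(small_cities, cfg)
        prev = aggregate_prevalence(ind)
        assert (prev["prevalence"] == 1.0).all()

    def test_deterministic_for_fixed_seed(self, small_cities, small_config):
        a = generate_individuals(small_cities, small_config)
        b = generate_individuals(small_cities, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_coupling_induces_detectable_q(self):
        from stratq import GeoDetector, aggregate_prevalence

        cfg = SyntheticConfig(n_cities=100, n_individuals=20000, seed=12,
                              coupling=Coupling(pollutant="so2", n_strata=5,
                                                bmi_shifts=[-2, -1, 0, 1, 2]),
                              region_bmi_shift={})
        cities = generate_pollutants(generate_city_lattice(cfg), cfg)
        ind = generate_individuals(cities, cfg)
        prev = aggregate_prevalence(ind)
        merged = (prev[prev["age_group"] == "middle_aged"]
                  .merge(cities, on="city_id"))
        res = GeoDetector.from_dataframe(merged, "prevalence", ["so2", "o3"]).fit()
        ft = res.factor_table().set_index("factor")
        assert ft.loc["so2", "q"] > 0.5
        assert ft.loc["so2", "q"] > ft.loc["o3", "q"] + 0.2

    def test_config_round_trips_through_dict(self):
        cfg = SyntheticConfig(seed=3, coupling=Coupling(),
                              strata_effect=StrataEffect([0.4, 0.6], 0.1))
        again = SyntheticConfig.from_dict(cfg.to_dict())
        assert again == cfg
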