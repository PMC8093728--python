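"""Synthetic-data generator: determinism, variance control, fixture
round-trips."""

import numpy as np
import pandas as pd
import pytest

from foragerep.io import load_fixture_dir, read_depth
from foragerep.lmm import anova_variance_components
from foragerep.simulate import (MORPH_COLUMNS, SimulationConfig, SimulationTruth,
                                simulate_population, write_fixtures)
from conftest import small_sim_config


class TestConfigValidation:
    def test_zero_trips_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(trips_per_individual=0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_var_between=-1.0)

    def test_propensity_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(benthic_propensity_mean=1.2)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = small_sim_config(n_individuals=3, seed=99)
        g1, d1, m1, t1 = simulate_population(cfg)
        g2, d2, m2, t2 = simulate_population(small_sim_config(n_individuals=3, seed=99))
        for iid in g1:
            assert np.array_equal(g1[iid].t, g2[iid].t)
            assert np.array_equal(g1[iid].lon, g2[iid].lon)
            assert np.array_equal(d1[iid].depth, d2[iid].depth)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1.trips, t2.trips)
        assert t1.realized_r == t2.realized_r

    def test_different_seed_differs(self):
        g1, *_ = simulate_population(small_sim_config(n_individuals=2, seed=1))
        g2, *_ = simulate_population(small_sim_config(n_individuals=2, seed=2))
        iid = next(iter(g1))
        assert not np.array_equal(g1[iid].lon, g2[iid].lon)


class TestVarianceControl:
    def test_zero_between_variance_gives_common_bearing(self):
        cfg = small_sim_config(n_individuals=5, bearing_var_between=0.0, seed=3)
        *_, truth = simulate_population(cfg)
        assert truth.individuals["bearing_mean"].nunique() == 1
        assert truth.individuals["bearing_mean"].iloc[0] == pytest.approx(203.5)

    def test_realized_duration_r_recovers_configured_r(self):
        # target R = 0.6: vb = 0.15, vw = 0.10; oracle = one-way ANOVA
        # decomposition of the drawn latent log durations.  A single
        # 50-individual draw has ~0.05 sampling SD on R, so the check
        # averages a few replicate populations.
        rs = []
        for seed in range(5):
            cfg = small_sim_config(n_individuals=50, trips_per_individual=10,
                                   duration_var_between=0.15,
                                   duration_var_within=0.10, seed=seed,
                                   log_duration_mean=float(np.log(18.0)),
                                   patch_distance_mean_km=25.0,
                                   patch_distance_sd_km=4.0)
            *_, truth = simulate_population(cfg)
            y = np.log(truth.trips["duration_h_latent"].to_numpy())
            sa2, se2 = anova_variance_components(y, truth.trips["individual_id"])
            r_anova = sa2 / (sa2 + se2)
            rs.append(r_anova)
            assert truth.realized_r["log_duration"] == pytest.approx(r_anova,
                                                                     abs=0.1)
        assert float(np.mean(rs)) == pytest.approx(0.6, abs=0.1)

    def test_realized_r_increases_with_between_variance(self):
        levels = (0.02, 0.1, 0.4)
        means = []
        for vb in levels:
            rs = []
            for rep in range(20):
                cfg = small_sim_config(
                    n_individuals=10, trips_per_individual=3,
                    duration_var_between=vb, duration_var_within=0.1,
                    seed=1000 + rep, log_duration_mean=float(np.log(14.0)),
                    patch_distance_mean_km=18.0, patch_distance_sd_km=3.0)
                *_, truth = simulate_population(cfg)
                rs.append(truth.realized_r["log_duration"])
            means.append(float(np.mean(rs)))
        assert means[0] < means[1] < means[2]

    def test_population_benthic_fraction_matches_configured_mean(self):
        cfg = small_sim_config(n_individuals=8, trips_per_individual=4, seed=6)
        *_, truth = simulate_population(cfg)
        assert len(truth.dives) >= 2000
        assert truth.dives["is_benthic"].mean() == pytest.approx(0.75, abs=0.05)

    def test_morphometrics_near_population_means(self):
        *_, morph, _ = simulate_population(small_sim_config(n_individuals=34, seed=7))
        assert morph["mass_kg"].mean() == pytest.approx(70.4, abs=5.0)
        assert morph["standard_length_cm"].mean() == pytest.approx(151.4, abs=4.0)

    def test_realized_r_in_unit_interval_enforced(self):
        with pytest.raises(ValueError):
            SimulationTruth(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(),
                            {"x": 1.3})


class TestTruthGeometry:
    def test_patch_centres_reproduce_bearing_means(self, small_pop):
        truth = small_pop["truth"]
        for iid, sub in truth.trips.groupby("individual_id"):
            b = np.degrees(np.arctan2(sub["patch_x_m"], sub["patch_y_m"])) % 360
            rad = np.radians(b)
            mean_b = np.degrees(np.arctan2(np.mean(np.sin(rad)),
                                           np.mean(np.cos(rad)))) % 360
            want = truth.individuals.set_index("individual_id") \
                .loc[iid, "bearing_mean"]
            diff = (mean_b - want + 180) % 360 - 180
            # circular SE of the trip-level bearing draws plus patch jitter
            assert abs(diff) < 45.0

    def test_every_dive_labelled(self, small_pop):
        truth = small_pop["truth"]
        assert truth.dives["is_benthic"].isin([True, False]).all()

    def test_track_speeds_below_filter_threshold(self, small_pop):
        from foragerep.geo import haversine_m
        for tr in small_pop["gps"].values():
            d = haversine_m(tr.lon[:-1], tr.lat[:-1], tr.lon[1:], tr.lat[1:])
            v = d / np.diff(tr.t)
            assert v.max() < 6.0  # clean tracks pass the speed filter


class TestFixtures:
    def test_round_trip_identity(self, tmp_path):
        cfg = small_sim_config(n_individuals=2, seed=8)
        gps, depth, morph, truth = simulate_population(cfg)
        write_fixtures(gps, depth, morph, truth, tmp_path)
        gps2, depth2, morph2 = load_fixture_dir(tmp_path)
        assert set(gps2) == set(gps)
        for iid in gps:
            assert np.array_equal(gps[iid].t, gps2[iid].t)
            assert np.array_equal(gps[iid].lon, gps2[iid].lon)
            assert np.array_equal(gps[iid].lat, gps2[iid].lat)
            assert np.array_equal(depth[iid].t, depth2[iid].t)
            assert np.array_equal(depth[iid].depth, depth2[iid].depth)
            assert depth2[iid].sample_interval == depth[iid].sample_interval
        pd.testing.assert_frame_equal(morph, morph2)

    def test_empty_population_writes_header_only_morphometrics(self, tmp_path):
        truth = SimulationTruth(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), {})
        write_fixtures({}, {}, pd.DataFrame(columns=["individual_id",
                                                     *MORPH_COLUMNS]),
                       truth, tmp_path)
        df = pd.read_csv(tmp_path / "morphometrics.csv")
        assert len(df) == 0
        assert list(df.columns) == ["individual_id", *MORPH_COLUMNS]

    def test_one_second_interval_autodetected(self, tmp_path):
        cfg = small_sim_config(n_individuals=1, trips_per_individual=3,
                               depth_interval=1.0, seed=9,
                               log_duration_mean=float(np.log(14.0)),
                               patch_distance_mean_km=18.0)
        gps, depth, morph, truth = simulate_population(cfg)
        write_fixtures(gps, depth, morph, truth, tmp_path)
        iid = next(iter(depth))
        se = read_depth(tmp_path / f"depth_{iid}.csv")
        assert se.sample_interval == 1.0
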