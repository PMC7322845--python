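"""Synthetic generators: baseline fields, tracks, plasma samples, SSH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmascape.errors import (InvalidFieldError, InvalidSpecError,
                                NoDataError)
from plasmascape.grids import GridSpec
from plasmascape.synth import (COLONY, FieldSpec, SimulationConfig,
                               generate_baseline_field, generate_ssh_field,
                               make_study_bundle, sample_plasma,
                               simulate_track)

from conftest import make_trip

GRID = GridSpec.from_extent(30.0, 45.0, -55.0, -40.0, 0.5)


def _field(spec13, spec15=None):
    return generate_baseline_field(spec13, spec15 or spec13, grid=GRID, seed=0)


class TestBaselineField:
    def test_constant_field(self):
        f = _field(FieldSpec(slope=0.0, intercept=-21.0))
        assert np.all(f.d13c == -21.0)

    def test_published_combined_gradient(self):
        # plasma-level combined regression: 0.21*lat - 11.25
        f = _field(FieldSpec(slope=0.21, intercept=-11.25))
        iy = np.argmin(np.abs(f.grid.lat_centers() - (-50.25)))
        lat = f.grid.lat_centers()[iy]
        np.testing.assert_allclose(f.d13c[iy], 0.21 * lat - 11.25, atol=1e-12)
        # interpolated exactly at an arbitrary latitude on a linear field
        assert f.value_at(37.0, -50.0, "d13c") == pytest.approx(
            0.21 * (-50.0) - 11.25, abs=1e-9)

    def test_front_step_mean_difference(self):
        f = _field(FieldSpec(slope=0.0, intercept=-21.0,
                             front_steps=((-45.0, 1.0),)))
        lat = f.grid.lat_centers()
        north = f.d13c[lat > -45.0].mean()
        south = f.d13c[lat < -45.0].mean()
        assert north - south == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_spec_rejected(self):
        with pytest.raises(InvalidSpecError):
            FieldSpec(slope=np.nan, intercept=-21.0)

    def test_noise_reproducible(self):
        s = FieldSpec(slope=0.1, intercept=-20.0, noise_sd=0.3)
        a = generate_baseline_field(s, s, grid=GRID, seed=5)
        b = generate_baseline_field(s, s, grid=GRID, seed=5)
        np.testing.assert_array_equal(a.d13c, b.d13c)


class TestSimulateTrack:
    def test_stationary_when_speed_zero(self):
        cfg = SimulationConfig(mean_speed_kmh=0.0, speed_sd_kmh=0.0,
                               trip_duration_h=12.0)
        trip = simulate_track(cfg, seed=1)
        np.testing.assert_allclose(trip.df["lon"], COLONY[0], atol=1e-9)
        np.testing.assert_allclose(trip.df["lat"], COLONY[1], atol=1e-9)

    def test_mean_step_displacement_matches_speed_law(self):
        # free CRW (no homing, no foraging slow-down), truncated-normal speeds
        cfg = SimulationConfig(mean_speed_kmh=30.0, speed_sd_kmh=6.0,
                               trip_duration_h=1000.0, p_switch=0.0,
                               return_to_colony=False)
        trip = simulate_track(cfg, seed=42)
        from plasmascape.geo import haversine_km
        lon = trip.df["lon"].to_numpy()
        lat = trip.df["lat"].to_numpy()
        steps = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        a = (0.0 - 30.0) / 6.0
        expected = stats.truncnorm.mean(a, np.inf, loc=30.0, scale=6.0)
        se = steps.std(ddof=1) / np.sqrt(len(steps))
        assert abs(steps.mean() - expected) < 3 * se

    def test_same_seed_identical(self):
        cfg = SimulationConfig(trip_duration_h=24.0)
        a = simulate_track(cfg, seed=9)
        b = simulate_track(cfg, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_first_and_last_fix_at_colony(self):
        trip = simulate_track(SimulationConfig(trip_duration_h=48.0), seed=3)
        assert (trip.df["lon"].iloc[0], trip.df["lat"].iloc[0]) == COLONY
        assert (trip.df["lon"].iloc[-1], trip.df["lat"].iloc[-1]) == COLONY

    def test_zero_duration_rejected(self):
        from plasmascape.errors import EmptyTrackError
        with pytest.raises(EmptyTrackError):
            SimulationConfig(trip_duration_h=0.0)


class TestSamplePlasma:
    def test_constant_field_gives_offset_value(self):
        f = _field(FieldSpec(slope=0.0, intercept=-21.0))
        trip = make_trip([36, 37, 38], [-46, -47, -48])
        s = sample_plasma(trip, f, trophic_offset=(2.0, 2.0),
                          noise_sd=(0.0, 0.0))
        assert s.d13c_raw == pytest.approx(-19.0, abs=1e-9)

    def test_two_cell_weighted_mean(self):
        # field linear in lon: -20 at lon 36, -24 at lon 40
        f = _field(FieldSpec(slope=0.0, intercept=-20.0))
        f.d13c[:] = -20.0 + (f.grid.lon_centers()[None, :] - 36.0) * (-1.0)
        lons = [36.0] * 6 + [40.0] * 2   # 75% / 25% residence
        trip = make_trip(lons, [-46.0] * 8)
        s = sample_plasma(trip, f, trophic_offset=(0.0, 0.0), noise_sd=(0, 0))
        assert s.d13c_raw == pytest.approx(0.75 * -20 + 0.25 * -24, abs=1e-9)

    def test_linear_field_value_at_weighted_location(self):
        f = _field(FieldSpec(slope=0.21, intercept=-11.25))
        trip = make_trip([36.0, 38.0], [-46.0, -50.0])
        s = sample_plasma(trip, f, trophic_offset=(0.0, 0.0), noise_sd=(0, 0))
        assert s.d13c_raw == pytest.approx(
            f.value_at(s.truth["lon"], s.truth["lat"], "d13c"), abs=1e-9)

    def test_no_fixes_in_window_raises(self):
        f = _field(FieldSpec(slope=0.0, intercept=-21.0))
        trip = make_trip([0.0, 1.0], [0.0, 1.0])  # outside the field grid
        with pytest.raises(NoDataError):
            sample_plasma(trip, f)

    def test_foraging_fixes_only_when_labelled(self):
        f = _field(FieldSpec(slope=0.0, intercept=-20.0))
        f.d13c[:] = -20.0 + (f.grid.lon_centers()[None, :] - 36.0) * (-1.0)
        states = ["transit", "forage", "forage", "transit"]
        trip = make_trip([40, 36, 36, 40], [-46] * 4, true_state=states)
        s = sample_plasma(trip, f, trophic_offset=(0, 0), noise_sd=(0, 0))
        assert s.d13c_raw == pytest.approx(-20.0, abs=1e-9)
        assert s.truth["lon"] == pytest.approx(36.0)


class TestSshField:
    FRONTS = ([-50.5, -45.0, -41.5], [-0.48, 0.03, 0.92])

    def test_passes_through_anchors(self):
        # gridded profile crosses each planted (front latitude, level) pair
        # to within the grid's linear-interpolation accuracy
        ssh = generate_ssh_field(*self.FRONTS)
        lat = ssh.grid.lat_centers()
        for flat, level in zip(*self.FRONTS):
            prof = ssh.values[:, 0]
            assert np.interp(flat, lat, prof) == pytest.approx(level, abs=5e-3)

    def test_single_level_linear_profile(self):
        ssh = generate_ssh_field([-45.0], [0.1], end_slope=0.05)
        lat = ssh.grid.lat_centers()
        np.testing.assert_allclose(ssh.values[:, 0],
                                   0.1 + 0.05 * (lat - (-45.0)), atol=1e-12)

    def test_monotone_northward(self):
        ssh = generate_ssh_field(*self.FRONTS)
        assert np.all(np.diff(ssh.values[:, 0]) > 0)

    def test_non_monotone_levels_rejected(self):
        with pytest.raises(InvalidFieldError):
            generate_ssh_field([-50.0, -45.0], [0.5, 0.1])


class TestStudyBundle:
    def test_reproducible_and_complete(self):
        a = make_study_bundle(n_per_species=2, seed=11)
        b = make_study_bundle(n_per_species=2, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert len(a[1]) == 6
        assert {"d13c_raw", "d15n", "cn_raw", "blood_time"} <= set(a[1].columns)

    def test_truth_recoverable_from_paired_samples(self, flying_bundle):
        tracks_df, plasma_df, field, truth = flying_bundle
        # noiseless check is done at module level; here: plasma values sit on
        # the generating gradient within a few noise SDs
        merged = plasma_df.merge(truth, on="id")
        resid = merged["d13c_del"].dropna() - (
            0.21 * merged.loc[merged["d13c_del"].notna(), "lat"] - 11.25)
        assert resid.abs().max() < 2.0
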