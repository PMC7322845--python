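"""Track cleaning: distances, trip segmentation, speed filter, resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmascape import ctcrw
from plasmascape.errors import (DegenerateTripError, InvalidPointError,
                                InvalidTripError)
from plasmascape.geo import KM_PER_DEGREE, haversine_km
from plasmascape.tracks import (apply_colony_buffer, interpolate_regular,
                                segment_trips, speed_filter)

from conftest import make_trip

COLONY = (37.75, -46.9)


class TestHaversine:
    def test_identity(self):
        assert haversine_km(12.3, -45.6, 12.3, -45.6) == 0.0

    def test_one_degree_equator(self):
        # 2*pi*6371/360 km per degree along a great circle
        assert haversine_km(0, 0, 1, 0) == pytest.approx(111.19, abs=0.01)

    def test_symmetry(self):
        assert haversine_km(10, 20, 30, -40) == haversine_km(30, -40, 10, 20)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidPointError):
            haversine_km(np.nan, 0, 1, 1)
        with pytest.raises(InvalidPointError):
            haversine_km(0, 95.0, 1, 1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-180, 180), st.floats(-89, 89)),
                    min_size=3, max_size=3))
    def test_triangle_inequality(self, pts):
        (a, b, c) = pts
        ab = haversine_km(a[0], a[1], b[0], b[1])
        bc = haversine_km(b[0], b[1], c[0], c[1])
        ac = haversine_km(a[0], a[1], c[0], c[1])
        assert ac <= ab + bc + 1e-6


def _fix_frame(lons, lats, interval_s=3600.0):
    n = len(lons)
    times = (np.datetime64("2016-12-01T00:00:00")
             + (np.arange(n) * interval_s * 1e9).astype("timedelta64[ns]"))
    return pd.DataFrame({"time": times, "lon": lons, "lat": lats})


class TestSegmentTrips:
    def test_never_departs(self):
        fixes = _fix_frame([37.75, 37.751, 37.75], [-46.9, -46.9, -46.9])
        assert segment_trips(fixes, COLONY, 0.5) == []

    def test_two_trips_by_hand(self):
        # land, sea, sea, land, land, sea, land -> trips of 2 and 1 at-sea fixes
        sea = 38.5
        lons = [37.75, sea, sea + 0.1, 37.75, 37.75, sea, 37.75]
        lats = [-46.9] * 7
        trips = segment_trips(_fix_frame(lons, lats), COLONY, 0.5)
        assert [len(t) for t in trips] == [2, 1]
        assert all(t.complete for t in trips)

    def test_track_ending_at_sea_flagged_incomplete(self):
        lons = [37.75, 38.5, 38.6]
        trips = segment_trips(_fix_frame(lons, [-46.9] * 3), COLONY, 0.5)
        assert len(trips) == 1
        assert not trips[0].complete

    def test_unsorted_rejected(self):
        fixes = _fix_frame([37.75, 38.5], [-46.9, -46.9])
        fixes = fixes.iloc[::-1].reset_index(drop=True)
        with pytest.raises(InvalidTripError):
            segment_trips(fixes, COLONY, 0.5)


class TestSpeedFilter:
    def _cruise(self, n=10, step_deg=0.2):
        # ~22 km/h eastward at the equator, hourly
        return make_trip(np.arange(n) * step_deg, np.zeros(n))

    def test_noop_below_threshold(self):
        trip = self._cruise()
        out = speed_filter(trip, 135.0)
        pd.testing.assert_frame_equal(out.df, trip.df)

    def test_single_teleport_removed(self):
        trip = self._cruise()
        lons = trip.df["lon"].to_numpy().copy()
        lons[5] += 5.0  # ~550 km extra in one hour
        bad = make_trip(lons, np.zeros(10))
        out = speed_filter(bad, 135.0)
        assert len(out) == 9
        assert 5.0 + 5 * 0.2 not in out.df["lon"].to_numpy()
        np.testing.assert_array_equal(out.df["lon"],
                                      np.delete(lons, 5))

    def test_two_consecutive_outliers_removed(self):
        lons = np.arange(10) * 0.2
        lons[4] += 5.0
        lons[5] += 5.0
        out = speed_filter(make_trip(lons, np.zeros(10)), 135.0)
        assert len(out) == 8
        assert np.all(np.abs(np.diff(out.df["lon"])) < 1.0)

    def test_idempotent_at_fixation(self):
        lons = np.arange(10) * 0.2
        lons[4] += 5.0
        once = speed_filter(make_trip(lons, np.zeros(10)), 135.0)
        twice = speed_filter(once, 135.0)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_degenerate_trip_raises(self):
        # every later fix needs an absurd speed from the anchor
        lons = [0.0, 50.0, 100.0]
        with pytest.raises(DegenerateTripError):
            speed_filter(make_trip(lons, np.zeros(3)), 135.0)


class TestInterpolate:
    def test_on_grid_idempotent(self):
        trip = make_trip([0, 0.2, 0.4], [0, 0.1, 0.2])
        out = interpolate_regular(trip, 3600.0, "linear")
        np.testing.assert_allclose(out.df["lon"], trip.df["lon"])
        np.testing.assert_allclose(out.df["lat"], trip.df["lat"])

    def test_linear_midpoint(self):
        trip = make_trip([0.0, 1.0], [10.0, 12.0], interval_s=7200.0)
        out = interpolate_regular(trip, 3600.0, "linear")
        assert len(out) == 3
        assert out.df["lon"].iloc[1] == pytest.approx(0.5)
        assert out.df["lat"].iloc[1] == pytest.approx(11.0)

    def test_endpoints_preserved(self):
        trip = make_trip([0, 0.3, 0.9], [0, 0.2, 0.25])
        out = interpolate_regular(trip, 1800.0, "linear")
        assert out.df["lon"].iloc[0] == trip.df["lon"].iloc[0]
        assert out.df["lon"].iloc[-1] == trip.df["lon"].iloc[-1]

    def test_unknown_method(self):
        trip = make_trip([0, 0.2], [0, 0.1])
        with pytest.raises(Exception):
            interpolate_regular(trip, 3600.0, "spline")

    def test_ctcrw_recovers_constant_velocity(self):
        # noiseless linear motion: smoothed positions within 0.001 deg
        t = np.arange(0, 7200, 420.0)
        lon = 37.75 + 0.001 * t / 60.0
        lat = -46.9 + 0.0008 * t / 60.0
        grid = np.arange(0, 7200, 120.0)
        glon, glat = ctcrw.smooth_track(t, lon, lat, grid)
        assert np.max(np.abs(glon - (37.75 + 0.001 * grid / 60))) < 1e-3
        assert np.max(np.abs(glat - (-46.9 + 0.0008 * grid / 60))) < 1e-3


class TestColonyBuffer:
    def _radial_trip(self, dists_km):
        lons = [COLONY[0] + d / (KM_PER_DEGREE * np.cos(np.radians(COLONY[1])))
                for d in dists_km]
        return make_trip(lons, [COLONY[1]] * len(dists_km))

    def test_zero_buffer_noop(self):
        trip = self._radial_trip([1, 3, 10])
        out = apply_colony_buffer(trip, 0.0, COLONY)
        assert len(out) == 3

    def test_counts_by_hand(self):
        trip = self._radial_trip([1, 3, 10, 20, 30])
        out = apply_colony_buffer(trip, 15.0, COLONY)
        assert len(out) == 2
        d = haversine_km(out.df["lon"], out.df["lat"], *COLONY)
        assert np.all(d >= 15.0)

    def test_full_exclusion_flag(self):
        trip = self._radial_trip([1, 3, 5])
        out = apply_colony_buffer(trip, 15.0, COLONY)
        assert len(out) == 0
        assert out.excluded


def test_filter_before_interpolation_is_load_bearing():
    """The canonical order (filter, then resample) differs from the reverse
    on a track with a planted teleport: interpolating first drags the
    outlier into every neighbouring resampled fix."""
    lons = np.arange(10) * 0.2
    lons[5] += 5.0
    trip = make_trip(lons, np.zeros(10))
    canonical = interpolate_regular(speed_filter(trip, 135.0), 1800.0, "linear")
    reversed_order = speed_filter(interpolate_regular(trip, 1800.0, "linear"), 135.0)
    assert np.all(np.abs(np.diff(canonical.df["lon"])) < 0.5)
    # the reversed order keeps fixes dragged toward the teleport
    assert not np.array_equal(
        canonical.df["lon"].to_numpy(),
        reversed_order.df["lon"].to_numpy()[:len(canonical)])
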