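"""Geometry, windowed displacement, effort, ML RMS displacement, jackknife,
kernel density, re-sighting statistics."""

import datetime as dt
import math
import warnings

import numpy as np
import pytest

from codaclan.config import STUDY_ORIGIN
from codaclan.io_catalog import GpsFix
from codaclan.movement_spatial import (
    EffortField,
    SightingRecord,
    _BinLikelihood,
    _pairs_by_bin,
    build_effort,
    compare_scales,
    dedupe_daily,
    from_planar,
    great_circle_km,
    jackknife_se,
    kernel_density,
    rms_ml,
    same_island_fraction,
    to_planar,
    window_displacement,
)
from codaclan.synthetic_data import (
    gen_tracks,
    pure_diffusion_spec,
    sample_sightings,
)

D0 = dt.date(2019, 3, 1)
T0 = dt.datetime(2019, 3, 1, 8, 0)


def _spherical_law_of_cosines(a, b):
    la1, lo1, la2, lo2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    c = math.sin(la1) * math.sin(la2) + math.cos(la1) * math.cos(la2) * math.cos(lo2 - lo1)
    return 6371.0 * math.acos(min(1.0, max(-1.0, c)))


class TestGeometry:
    def test_identical_points_and_one_degree(self):
        assert great_circle_km((15.0, -61.0), (15.0, -61.0)) == 0.0
        assert great_circle_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            math.pi / 180 * 6371, abs=1e-9
        )

    def test_matches_law_of_cosines_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = (rng.uniform(-80, 80), rng.uniform(-179, 179))
            b = (a[0] + rng.uniform(-5, 5), a[1] + rng.uniform(-5, 5))
            assert great_circle_km(a, b) == pytest.approx(
                _spherical_law_of_cosines(a, b), abs=1e-6
            )

    def test_planar_round_trip_and_haversine_agreement(self):
        rng = np.random.default_rng(2)
        # points within a 600-km-wide box about the study origin
        lat = STUDY_ORIGIN[0] + rng.uniform(-2.5, 2.5, 80)
        lon = STUDY_ORIGIN[1] + rng.uniform(-2.5, 2.5, 80)
        x, y = to_planar(lat, lon)
        lat2, lon2 = from_planar(x, y)
        assert np.allclose(lat, lat2) and np.allclose(lon, lon2)
        for i in range(0, 78, 2):
            planar = math.hypot(x[i] - x[i + 1], y[i] - y[i + 1])
            gc = great_circle_km((lat[i], lon[i]), (lat[i + 1], lon[i + 1]))
            if gc > 1.0:
                assert abs(planar - gc) / gc < 0.005


class TestWindowDisplacement:
    @staticmethod
    def _track(n, step_deg_lat):
        return [
            GpsFix(T0 + dt.timedelta(minutes=5 * k), 14.0 + step_deg_lat * k, -61.0)
            for k in range(n)
        ]

    def test_stationary_track_zero(self):
        fixes = self._track(73, 0.0)
        samples, _ = window_displacement(fixes, 1.0)
        assert len(samples) == 6
        assert all(s.displacement_km == 0.0 for s in samples)

    def test_straight_north_one_degree_in_six_hours(self):
        fixes = self._track(73, 1.0 / 72)
        samples, _ = window_displacement(fixes, 6.0, speed_guard_kmh=20.0)
        assert len(samples) == 1
        assert samples[0].displacement_km == pytest.approx(111.19, abs=0.01)

    def test_speed_guard_drops_fast_windows(self):
        fixes = self._track(73, 1.0 / 72)  # 18.5 km/h > default 12 km/h guard
        samples, dropped = window_displacement(fixes, 6.0)
        assert samples == [] and dropped["speed_guard"] == 1

    def test_low_coverage_dropped(self):
        fixes = self._track(73, 0.0)
        sparse = fixes[::3]  # 20 fixes per 6 h < 80% of 72
        samples, dropped = window_displacement(sparse, 6.0)
        assert samples == [] and dropped["low_coverage"] == 1

    def test_monotone_in_window_on_straight_track(self):
        fixes = self._track(12 * 13, 0.004)
        means = []
        for w in (1.0, 3.0, 6.0):
            s, _ = window_displacement(fixes, w, speed_guard_kmh=1e9)
            means.append(np.mean([x.displacement_km for x in s]))
        assert means[0] <= means[1] <= means[2]

    def test_random_walk_speed_bound(self):
        rng = np.random.default_rng(4)
        lat, lon = 14.5, -61.0
        fixes = []
        heading = 0.0
        for k in range(12 * 12):
            fixes.append(GpsFix(T0 + dt.timedelta(minutes=5 * k), lat, lon))
            heading += rng.normal(0, 0.4)
            step = 7.408 / 12 / 111.19  # 4 knots per 5-min
            lat += step * math.cos(heading)
            lon += step * math.sin(heading) / math.cos(math.radians(lat))
        samples, _ = window_displacement(fixes, 1.0)
        mean = np.mean([s.displacement_km for s in samples])
        assert mean <= 7.41  # cannot beat straight-line travel at 4 knots


class TestEffort:
    def test_single_day_single_cell(self):
        fixes = [GpsFix(T0 + dt.timedelta(minutes=5 * k), 15.001, -61.001)
                 for k in range(10)]
        eff = build_effort({"d1": fixes}, {D0}, resolution_deg=0.05)
        assert eff.weights.sum() == 1.0

    def test_two_days_crossing_same_cell(self):
        f1 = [GpsFix(T0 + dt.timedelta(minutes=5 * k), 15.001, -61.001) for k in range(5)]
        f2 = [GpsFix(T0 + dt.timedelta(days=1, minutes=5 * k), 15.001, -61.001)
              for k in range(5)]
        eff = build_effort({"d1": f1, "d2": f2}, {D0, D0 + dt.timedelta(days=1)}, 0.05)
        assert eff.weights.max() == 2.0

    def test_matches_point_in_cell_tally(self):
        rng = np.random.default_rng(5)
        tracks, days = {}, set()
        for d in range(4):
            date = D0 + dt.timedelta(days=d)
            days.add(date)
            t0 = dt.datetime.combine(date, dt.time(8))
            tracks[str(d)] = [
                GpsFix(t0 + dt.timedelta(minutes=5 * k),
                       15.0 + rng.uniform(0, 0.3), -61.0 + rng.uniform(0, 0.3))
                for k in range(30)
            ]
        eff = build_effort(tracks, days, resolution_deg=0.05)
        # brute-force tally: per day, set of visited cells
        expected = np.zeros_like(eff.weights)
        for d, fixes in tracks.items():
            seen = set()
            for f in fixes:
                seen.add(eff.cell_index(f.lat, f.lon))
            for i, j in seen:
                expected[i, j] += 1
        assert np.array_equal(eff.weights, expected)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            EffortField(np.array([0, 1.0]), np.array([0, 1.0]), np.array([[-1.0]]))


def _uniform_effort_for(sightings, resolution=0.2):
    lats = [s.lat for s in sightings]
    lons = [s.lon for s in sightings]
    return EffortField.uniform(
        (min(lats) - 0.1, max(lats) + 0.1), (min(lons) - 0.1, max(lons) + 0.1),
        resolution,
    )


class TestRmsMl:
    def test_zero_displacement_hits_lower_bound(self):
        ss = []
        for i in range(10):
            for d in (0, 3, 6):
                ss.append(SightingRecord(f"I{i}", D0 + dt.timedelta(days=d),
                                         15.0, -61.0))
        eff = EffortField.uniform((14.5, 15.5), (-61.5, -60.5), 0.1)
        est = rms_ml(ss, eff, [(1, 10)])
        assert est[0].at_boundary and est[0].per_axis_sd_km <= 0.11

    def test_recovers_true_sd_under_uniform_effort(self):
        tracks = gen_tracks(pure_diffusion_spec(10.0), n_units_per_clan=60,
                            unit_size=1, n_days=20, seed=8)
        ss = sample_sightings(tracks, every_n_days=2)
        eff = _uniform_effort_for(ss)
        est = rms_ml(ss, eff, [(1, 8)], max_pairs_per_bin=500, seed=0)
        e = est[0]
        true_rms = math.sqrt(2 * 100 * e.mean_lag_days)
        assert abs(e.rms_km - true_rms) / true_rms < 0.1
        # under flat effort the ML estimate collapses to the naive RMS
        pairs = _pairs_by_bin(ss, [(1, 8)], 1.0, eff.origin, 500, 0)
        X, Y, _, _ = pairs[0]
        naive = math.sqrt(np.mean(np.sum((Y - X) ** 2, axis=1)))
        assert abs(e.rms_km - naive) / naive < 0.05

    def test_matches_grid_search_oracle(self):
        tracks = gen_tracks(pure_diffusion_spec(10.0), n_units_per_clan=50,
                            unit_size=1, n_days=12, seed=9)
        ss = sample_sightings(tracks, every_n_days=2)
        eff = _uniform_effort_for(ss)
        est = rms_ml(ss, eff, [(1, 6)], max_pairs_per_bin=400, seed=1)
        pairs = _pairs_by_bin(ss, [(1, 6)], 1.0, eff.origin, 400, 1)
        X, Y, _, _ = pairs[0]
        # independent brute-force maximization of the same likelihood
        L = _BinLikelihood(X, Y, eff)
        grid = np.geomspace(1.0, 200.0, 2000)
        coarse = grid[np.argmin([L.neg_loglik(math.log(s)) for s in grid])]
        fine = np.linspace(coarse * 0.98, coarse * 1.02, 400)
        s_star = fine[np.argmin([L.neg_loglik(math.log(s)) for s in fine])]
        assert est[0].per_axis_sd_km == pytest.approx(s_star, rel=1e-3)

    def test_effort_correction_beats_naive_under_concentrated_effort(self):
        from codaclan.synthetic_data import _island_xy

        tracks = gen_tracks(pure_diffusion_spec(10.0), n_units_per_clan=200,
                            unit_size=1, n_days=30, seed=11)
        home = _island_xy("Martinique")
        R = 25.0
        ss = sample_sightings(
            tracks, detect=lambda x, y: math.hypot(x - home[0], y - home[1]) <= R
        )
        lat0, lon0 = 14.64, -61.02
        eff = EffortField.uniform((lat0 - 0.45, lat0 + 0.45),
                                  (lon0 - 0.45, lon0 + 0.45), 0.05)
        centers, _ = eff.active_cells_planar()
        halfdiag = 0.5 * math.hypot(0.05 * 111.19,
                                    0.05 * 111.19 * math.cos(math.radians(14.5)))
        keep = np.hypot(centers[:, 0] - home[0], centers[:, 1] - home[1]) <= R + halfdiag
        W = eff.weights.reshape(-1)
        W[~keep] = 0.0
        eff = EffortField(eff.lat_edges, eff.lon_edges, W.reshape(eff.weights.shape))
        est = rms_ml(ss, eff, [(2, 5)], max_pairs_per_bin=800, seed=3)
        e = est[0]
        assert e.n_pairs >= 500
        true_rms = math.sqrt(2 * 100 * e.mean_lag_days)
        pairs = _pairs_by_bin(ss, [(2, 5)], 1.0, eff.origin, 800, 3)
        X, Y, _, lag = pairs[0]
        naive = math.sqrt(np.mean(np.sum((Y - X) ** 2, axis=1)))
        assert naive < 0.9 * true_rms              # naive biased low >= 10%
        assert abs(e.rms_km - true_rms) / true_rms < 0.2   # ML within 20%

    def test_empty_bin_warns_and_is_omitted(self):
        ss = [SightingRecord("I0", D0, 15.0, -61.0),
              SightingRecord("I0", D0 + dt.timedelta(days=3), 15.1, -61.0)]
        eff = EffortField.uniform((14.5, 15.5), (-61.5, -60.5), 0.1)
        with pytest.warns(UserWarning, match="no re-sighting pairs"):
            est = rms_ml(ss, eff, [(1, 2), (2, 5)])
        assert len(est) == 1 and est[0].lag_lo == 2


class TestJackknife:
    def test_two_individuals_closed_form(self):
        rng = np.random.default_rng(12)
        ss = []
        for i, spread in ((0, 5.0), (1, 12.0)):
            x0, y0 = 0.0, 0.0
            for d in range(0, 12, 2):
                lat, lon = from_planar(x0 + rng.normal(0, spread),
                                       y0 + rng.normal(0, spread))
                ss.append(SightingRecord(f"I{i}", D0 + dt.timedelta(days=d),
                                         float(lat), float(lon)))
        eff = _uniform_effort_for(ss)
        est = jackknife_se(ss, eff, [(1, 12)])[0]
        # closed form at n=2: se = |theta_(1) - theta_(2)| / 2 * sqrt(2/1 * ...)
        thetas = []
        for leave in ("I0", "I1"):
            keep = [s for s in ss if s.individual_id != leave]
            thetas.append(rms_ml(keep, eff, [(1, 12)])[0].rms_km)
        expected = math.sqrt(0.5 * sum((t - np.mean(thetas)) ** 2 for t in thetas))
        assert est.jackknife_se_km == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(abs(thetas[0] - thetas[1]) / 2, rel=1e-12)

    def test_single_individual_gives_no_se(self):
        ss = [SightingRecord("I0", D0 + dt.timedelta(days=d), 15.0 + 0.01 * d, -61.0)
              for d in range(0, 10, 2)]
        eff = _uniform_effort_for(ss)
        est = jackknife_se(ss, eff, [(1, 10)])[0]
        assert est.jackknife_se_km is None

    def test_se_shrinks_with_more_individuals(self):
        def run(n_ind, seed):
            tracks = gen_tracks(pure_diffusion_spec(10.0), n_units_per_clan=n_ind,
                                unit_size=1, n_days=10, seed=seed)
            ss = sample_sightings(tracks, every_n_days=3)
            eff = _uniform_effort_for(ss)
            return jackknife_se(ss, eff, [(1, 10)], max_pairs_per_bin=300,
                                seed=seed)[0].jackknife_se_km

        assert run(80, 21) < run(10, 22)


class TestKernelDensity:
    def test_single_fix_mass_and_argmax(self):
        g = kernel_density([(15.2, -61.1)], resolution_deg=0.01, bandwidth_km=3.0)
        assert g.integral() == pytest.approx(1.0, rel=1e-3)
        i, j = np.unravel_index(np.argmax(g.density), g.density.shape)
        assert g.lat_centers[i] == pytest.approx(15.2, abs=0.011)
        assert g.lon_centers[j] == pytest.approx(-61.1, abs=0.011)
        assert np.all(g.density >= 0)

    def test_mass_conservation_on_cloud(self):
        rng = np.random.default_rng(14)
        pts = np.column_stack([15.0 + 0.1 * rng.standard_normal(500),
                               -61.0 + 0.1 * rng.standard_normal(500)])
        g = kernel_density(pts, resolution_deg=0.005)
        assert abs(g.integral() - 500) / 500 < 1e-3

    def test_disjoint_clans_do_not_overlap(self):
        a = kernel_density([(15.4, -61.3)] * 5, resolution_deg=0.01, bandwidth_km=2.0)
        b = kernel_density([(13.9, -61.0)] * 5, resolution_deg=0.01, bandwidth_km=2.0)
        assert set(a.lat_centers) & set(b.lat_centers) == set()

    def test_two_cloud_argmaxes_near_centers(self):
        rng = np.random.default_rng(15)
        pts = np.vstack([
            np.column_stack([15.4 + 0.02 * rng.standard_normal(200),
                             -61.3 + 0.02 * rng.standard_normal(200)]),
            np.column_stack([14.6 + 0.02 * rng.standard_normal(200),
                             -61.0 + 0.02 * rng.standard_normal(200)]),
        ])
        g = kernel_density(pts, resolution_deg=0.01, bandwidth_km=2.0)
        i, j = np.unravel_index(np.argmax(g.density), g.density.shape)
        near_a = abs(g.lat_centers[i] - 15.4) < 2.0 / 111.19
        near_b = abs(g.lat_centers[i] - 14.6) < 2.0 / 111.19
        assert near_a or near_b

    def test_no_fixes_warns(self):
        with pytest.warns(UserWarning):
            assert kernel_density([], clan_id="x") is None


class TestSameIsland:
    @staticmethod
    def _sighting(ind, year, island, clan):
        return SightingRecord(ind, dt.date(year, 3, 1), 15.0, -61.0,
                              island=island, clan_id=clan)

    def _constructed(self, n_same, n_diff, clan):
        ss = []
        for i in range(n_same):
            ss.append(self._sighting(f"{clan}S{i}", 2019, "Dominica", clan))
            ss.append(self._sighting(f"{clan}S{i}", 2020, "Dominica", clan))
        for i in range(n_diff):
            ss.append(self._sighting(f"{clan}D{i}", 2019, "Dominica", clan))
            ss.append(self._sighting(f"{clan}D{i}", 2020, "St. Lucia", clan))
        return ss

    def test_printed_fractions(self):
        ss = self._constructed(17, 6, "EC1") + self._constructed(5, 7, "EC2")
        stats = same_island_fraction(ss)
        assert stats["EC1"].n_same == 17 and stats["EC1"].n_total == 23
        assert round(stats["EC1"].fraction * 100) == 74
        assert stats["EC2"].n_same == 5 and stats["EC2"].n_total == 12
        assert round(stats["EC2"].fraction * 100, 1) == 41.7

    def test_single_year_individuals_excluded(self):
        ss = [self._sighting("A", 2019, "Dominica", "EC1")]
        stats = same_island_fraction(ss)
        assert "EC1" not in stats and "all" not in stats

    def test_dedupe_daily_keeps_first(self):
        a = SightingRecord("A", D0, 15.0, -61.0, time_of_day=9 * 3600.0)
        b = SightingRecord("A", D0, 15.5, -61.0, time_of_day=8 * 3600.0)
        assert dedupe_daily([a, b]) == [b]


class TestCompareScales:
    def test_order_of_magnitude_flagged(self):
        df = compare_scales({"yearly_rms_km": 100.0})
        row = df.set_index("quantity").loc["yearly_rms_km"]
        assert row["ratio"] == pytest.approx(10.0)
        assert bool(row["order_of_magnitude"])

    def test_identity_and_linearity(self):
        ref = {"a": 4.0, "b": 10.0}
        df = compare_scales(ref, reference=ref)
        assert np.allclose(df["ratio"], 1.0) and not df["order_of_magnitude"].any()
        df2 = compare_scales({"a": 8.0, "b": 20.0}, reference=ref)
        assert np.allclose(df2["ratio"], 0.5)
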