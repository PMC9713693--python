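"""Velocity, transient positions, spatial maps, 2D KS comparisons."""

import numpy as np
import pytest

from bimodal.containers import BehaviorTrack
from bimodal.spatial import (
    build_spatial_map,
    head_velocity,
    ks2d_compare,
    ks2d_stat,
    map_to_points,
    pairwise_map_tests,
    transient_positions,
)


def _track(xy, rate=30.0):
    xy = np.asarray(xy, dtype=float)
    return BehaviorTrack(times_s=np.arange(len(xy)) / rate, xy_px=xy)


class TestHeadVelocity:
    def test_constant_velocity(self):
        n = 300
        xy = np.column_stack([30.0 * np.arange(n), np.zeros(n)])
        v = head_velocity(_track(xy), smooth_window_s=0.2)
        assert v.shape == (n,)
        np.testing.assert_allclose(v, 900.0, rtol=0.01)

    def test_stationary_zero(self):
        v = head_velocity(_track(np.tile([50.0, 60.0], (100, 1))))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_circular_path_analytic_speed(self):
        rate, R, T = 30.0, 100.0, 8.0
        t = np.arange(int(rate * 3 * T)) / rate
        xy = np.column_stack(
            [
                200 + R * np.cos(2 * np.pi * t / T),
                200 + R * np.sin(2 * np.pi * t / T),
            ]
        )
        v = head_velocity(_track(xy), smooth_window_s=0.5)
        expected = 2 * np.pi * R / T
        interior = v[30:-30]
        np.testing.assert_allclose(interior, expected, rtol=0.02)

    def test_duplicate_timestamps_rejected(self):
        # rejected at construction, and again by head_velocity if a track
        # is mutated after validation
        with pytest.raises(ValueError, match="increasing"):
            BehaviorTrack(
                times_s=np.array([0.0, 0.1, 0.1, 0.2]),
                xy_px=np.zeros((4, 2)),
            )
        track = _track(np.zeros((4, 2)))
        track.times_s = np.array([0.0, 0.1, 0.1, 0.2])
        with pytest.raises(ValueError):
            head_velocity(track)


class TestTransientPositions:
    frame_times = np.arange(300) / 15.0

    def test_single_pulse_yields_position_at_onset(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.01, 300)
        trace[150:160] += 5.0
        xy = np.column_stack(
            [np.linspace(0, 300, 600), np.linspace(0, 300, 600)]
        )
        pos, t_on = transient_positions(
            trace, self.frame_times, _track(xy), threshold_sd=3.0
        )
        assert len(pos) == 1
        # onset frame 150 -> t=10 s -> video frame 300 -> x=y~150.25
        np.testing.assert_allclose(pos[0], xy[300], atol=1.0)
        assert t_on[0] == pytest.approx(10.0)

    def test_threshold_above_max_gives_empty(self):
        trace = np.random.default_rng(1).normal(0, 0.01, 300)
        pos, t_on = transient_positions(
            trace, self.frame_times, _track(np.zeros((600, 2))),
            threshold_sd=1e6,
        )
        assert len(pos) == 0 and len(t_on) == 0

    def test_place_cell_onsets_near_field(self, place_session_small):
        cfg, (traces, _, _, track, truth) = place_session_small
        hits, total = 0, 0
        for i in range(cfg.n_rois):
            pos, _ = transient_positions(
                traces.dff[i], traces.frame_times_s, track, threshold_sd=3.0
            )
            if len(pos) == 0:
                continue
            c = truth.place_field_centers[i]
            d = np.hypot(pos[:, 0] - c[0], pos[:, 1] - c[1])
            hits += (d <= 2 * cfg.place_sigma_px).sum()
            total += len(pos)
        assert total > 0
        assert hits / total >= 0.7


class TestBuildSpatialMap:
    def test_uniform_coverage_flat_map(self):
        # raster-scan every bin center of a 200x200 arena, one imaging
        # frame per video sample, constant trace: exactly uniform
        # occupancy and activity -> flat normalized map
        centers = np.arange(12.5, 200, 25.0)
        xy = np.array([(x, y) for y in centers for x in centers])
        xy = np.tile(xy, (4, 1))
        track = _track(xy, rate=30.0)
        ft = track.times_s.copy()
        trace = np.ones(ft.size)
        m = build_spatial_map(trace, ft, track, (200, 200))
        interior = m.normalized[2:-2, 2:-2]
        assert np.nanmax(interior) / np.nanmin(interior) < 1.05

    def test_single_bin_activity_unsmoothed(self):
        xy = np.tile([30.0, 30.0], (60, 1))
        xy[30:] = [130.0, 130.0]
        track = _track(xy)
        ft = np.arange(30) / 15.0
        trace = np.zeros(30)
        trace[5] = 2.0  # t=1/3 s -> position still (30, 30)
        m = build_spatial_map(trace, ft, track, (200, 200), sigma_px=0.0)
        nz = np.argwhere(np.nan_to_num(m.normalized) > 0)
        assert nz.tolist() == [[1, 1]]

    def test_doubled_occupancy_halves_rate(self):
        # dwell 1 s in bin A, 2 s in bin B, equal summed activity in both:
        # the occupancy division must halve B's rate relative to A's
        xy = np.vstack(
            [np.tile([10.0, 10.0], (30, 1)), np.tile([80.0, 80.0], (60, 1))]
        )
        track = _track(xy, rate=30.0)
        ft = np.arange(45) / 15.0
        trace = np.zeros(45)
        trace[:15] = 1.0  # 15 frames in bin A (t < 1 s)
        trace[15:30] = 1.0  # 15 of the 30 frames spent in bin B
        m = build_spatial_map(trace, ft, track, (100, 100), sigma_px=0.0)
        assert m.occupancy_s[0, 0] == pytest.approx(1.0)
        assert m.occupancy_s[3, 3] == pytest.approx(2.0)
        assert m.activity[0, 0] == pytest.approx(m.activity[3, 3])
        assert m.normalized[3, 3] == pytest.approx(m.normalized[0, 0] / 2)

    def test_occupancy_conserves_tracked_time(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 300, (900, 2))
        track = _track(xy)
        m = build_spatial_map(
            np.ones(100), np.arange(100) / 15.0, track, (300, 300)
        )
        total = m.occupancy_s.sum()
        assert total == pytest.approx(900 / 30.0, abs=1 / 30.0)

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError, match="bin_px"):
            build_spatial_map(
                np.ones(10), np.arange(10.0), _track(np.zeros((20, 2))),
                (100, 100), bin_px=0.0,
            )


class TestKs2d:
    def test_statistic_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            a = rng.uniform(0, 1, (rng.integers(5, 31), 2))
            b = rng.uniform(0, 1, (rng.integers(5, 31), 2))
            d = ks2d_stat(a, b)
            # oracle: loop over every data point and quadrant orientation
            best = 0.0
            for px, py in np.vstack([a, b]):
                for ox in (1, -1):
                    for oy in (1, -1):
                        ina = (
                            ((a[:, 0] <= px) if ox == 1 else (a[:, 0] > px))
                            & ((a[:, 1] <= py) if oy == 1 else (a[:, 1] > py))
                        ).mean()
                        inb = (
                            ((b[:, 0] <= px) if ox == 1 else (b[:, 0] > px))
                            & ((b[:, 1] <= py) if oy == 1 else (b[:, 1] > py))
                        ).mean()
                        best = max(best, abs(ina - inb))
            assert d == pytest.approx(best, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (40, 2))
        b = rng.normal(0.5, 1.3, (35, 2))
        d1 = ks2d_stat(a, b)
        d2 = ks2d_stat(a * 3.0 + 7.0, b * 3.0 + 7.0)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_identical_map_same_seed_zero_distance(self, place_session_small):
        cfg, (traces, _, _, track, _) = place_session_small
        m = build_spatial_map(
            np.abs(traces.dff[0]), traces.frame_times_s, track, cfg.arena_px
        )
        rng = np.random.default_rng(11)
        pa = map_to_points(m, 200, np.random.default_rng(42))
        pb = map_to_points(m, 200, np.random.default_rng(42))
        assert ks2d_stat(pa, pb) == 0.0

    def test_separated_modes_significant(self):
        occ = np.ones((20, 20))
        base = np.zeros((20, 20))
        a_act, b_act = base.copy(), base.copy()
        a_act[4, 4] = 1.0
        b_act[15, 15] = 1.0
        from bimodal.containers import SpatialMap

        def mk(act):
            return SpatialMap(
                occupancy_s=occ, activity=act, normalized=act,
                arena_px=(500, 500), bin_px=25.0, sigma_px=0.0,
            )

        d, p = ks2d_compare(mk(a_act), mk(b_act), n_resample=500, seed=0)
        assert p < 0.01 and d > 0.9

    def test_zero_activity_map_rejected(self):
        from bimodal.containers import SpatialMap

        z = SpatialMap(
            occupancy_s=np.ones((5, 5)), activity=np.zeros((5, 5)),
            normalized=np.zeros((5, 5)), arena_px=(125, 125),
            bin_px=25.0, sigma_px=0.0,
        )
        with pytest.raises(ValueError, match="zero total activity"):
            ks2d_compare(z, z)


class TestPairwiseMapTests:
    def _field_maps(self, place_session_small):
        cfg, (traces, _, _, track, _) = place_session_small
        return [
            build_spatial_map(
                np.clip(traces.dff[i], 0, None),
                traces.frame_times_s,
                track,
                cfg.arena_px,
            )
            for i in range(4)
        ]

    def test_distinct_place_fields_all_pairs_differ(self, place_session_small):
        maps = self._field_maps(place_session_small)
        D, P, sig = pairwise_map_tests(maps, n_resample=400, seed=3)
        n = len(maps)
        iu = np.triu_indices(n, 1)
        assert sig[iu].all()

    def test_identical_maps_no_significant_pairs(self, place_session_small):
        maps = self._field_maps(place_session_small)[:1] * 3
        D, P, sig = pairwise_map_tests(maps, n_resample=300, seed=4)
        assert not sig.any()

    def test_two_maps_single_pair(self, place_session_small):
        maps = self._field_maps(place_session_small)[:2]
        D, P, sig = pairwise_map_tests(maps, n_resample=200, seed=5)
        assert np.isfinite(D[0, 1]) and np.isnan(D[0, 0])

    def test_fewer_than_two_maps_rejected(self, place_session_small):
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_map_tests(self._field_maps(place_session_small)[:1])
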