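import numpy as np
import pandas as pd
import pytest

from hivecrit import trajectories as tj


def _track(x, y, dt=1.0, t0=0.0, coverage=1.0, bee="b"):
    return tj.BeeTrack(individual_id=bee, t0=t0, dt=dt, x=np.asarray(x, float),
                       y=np.asarray(y, float), coverage=coverage)


class TestResample:
    def test_linear_interpolation_forced(self):
        track = tj.resample_track([(0.0, 0.0, 0.0), (2.0, 4.0, 0.0)], dt=1.0)
        np.testing.assert_allclose(track.x, [0.0, 2.0, 4.0])
        np.testing.assert_allclose(track.y, [0.0, 0.0, 0.0])
        assert track.coverage == 1.0

    def test_already_uniform_is_identity(self):
        t = np.arange(10.0)
        x = np.sin(t)
        y = np.cos(t)
        track = tj.resample_track(list(zip(t, x, y)), dt=1.0)
        np.testing.assert_allclose(track.x, x)
        np.testing.assert_allclose(track.y, y)

    def test_matches_pointwise_interpolation_oracle(self, rng):
        # irregular times from a piecewise-linear path
        t = np.sort(rng.uniform(0, 100, size=50))
        t[0], t[-1] = 0.0, 100.0
        x = rng.uniform(-5, 5, size=50)
        y = rng.uniform(-5, 5, size=50)
        track = tj.resample_track(list(zip(t, x, y)), dt=2.5)
        # independent oracle: manual bracket search + linear formula per grid point
        for i, tg in enumerate(track.times):
            j = np.searchsorted(t, tg, side="right") - 1
            j = min(max(j, 0), len(t) - 2)
            w = (tg - t[j]) / (t[j + 1] - t[j])
            w = min(max(w, 0.0), 1.0)
            assert track.x[i] == pytest.approx(x[j] + w * (x[j + 1] - x[j]), abs=1e-9)
            assert track.y[i] == pytest.approx(y[j] + w * (y[j + 1] - y[j]), abs=1e-9)

    def test_extrapolation_holds_endpoint_and_reduces_coverage(self):
        track = tj.resample_track(
            [(10.0, 1.0, 2.0), (12.0, 3.0, 2.0)], dt=1.0, t_start=8.0, t_end=14.0
        )
        np.testing.assert_allclose(track.x, [1.0, 1.0, 1.0, 2.0, 3.0, 3.0, 3.0])
        assert track.coverage == pytest.approx(3 / 7)

    def test_duplicate_timestamps_keep_first(self):
        track = tj.resample_track([(0.0, 0.0, 0.0), (0.0, 9.0, 9.0), (1.0, 1.0, 1.0)], dt=1.0)
        assert track.x[0] == 0.0 and track.y[0] == 0.0

    def test_fewer_than_two_detections_rejected(self):
        with pytest.raises(tj.TrackUnusableError):
            tj.resample_track([(0.0, 1.0, 1.0)], dt=1.0)
        with pytest.raises(tj.TrackUnusableError):
            tj.resample_track([(0.0, 1.0, 1.0), (0.0, 2.0, 2.0)], dt=1.0)


class TestFilterInactive:
    def test_zero_coverage_removed(self):
        tr = _track([0, 1], [0, 1], coverage=0.0)
        assert tj.filter_inactive([tr], min_coverage=0.1) == []

    def test_active_track_retained(self):
        tr = _track([0, 5], [0, 5], coverage=1.0)
        assert tj.filter_inactive([tr], min_coverage=0.8, min_total_displacement=1.0) == [tr]

    def test_matches_brute_force_predicates(self, rng):
        tracks = []
        for i in range(20):
            n = int(rng.integers(2, 8))
            tracks.append(
                _track(rng.normal(size=n), rng.normal(size=n),
                       coverage=float(rng.uniform()), bee=f"b{i}")
            )
        mc, md = 0.55, 3.0
        got = tj.filter_inactive(tracks, min_coverage=mc, min_total_displacement=md)
        expected = []
        for tr in tracks:
            disp = sum(
                np.sqrt((tr.x[i + 1] - tr.x[i]) ** 2 + (tr.y[i + 1] - tr.y[i]) ** 2)
                for i in range(len(tr) - 1)
            )
            if tr.coverage >= mc and disp >= md:
                expected.append(tr)
        assert got == expected

    def test_monotone_in_thresholds(self, rng):
        tracks = [
            _track(rng.normal(size=5), rng.normal(size=5), coverage=float(rng.uniform()))
            for _ in range(15)
        ]
        base = set(id(t) for t in tj.filter_inactive(tracks, 0.3, 1.0))
        stricter = set(id(t) for t in tj.filter_inactive(tracks, 0.6, 2.0))
        assert stricter <= base


class TestKineticEnergy:
    def test_stationary_track_is_zero(self):
        es = tj.kinetic_energy(_track([2, 2, 2], [3, 3, 3]))
        np.testing.assert_array_equal(es.k, [0.0, 0.0])

    def test_three_four_five(self):
        es = tj.kinetic_energy(_track([0, 3], [0, 4]))
        assert es.k[0] == pytest.approx(25.0)

    def test_matches_first_difference_oracle(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        es = tj.kinetic_energy(_track(x, y))
        expect = [(x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2 for i in range(9)]
        np.testing.assert_allclose(es.k, expect)
        assert es.k.size == 9

    def test_rigid_motion_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = tj.kinetic_energy(_track(x, y)).k
        phi = 0.7
        xr = np.cos(phi) * x - np.sin(phi) * y + 10.0
        yr = np.sin(phi) * x + np.cos(phi) * y - 4.0
        np.testing.assert_allclose(tj.kinetic_energy(_track(xr, yr)).k, base, atol=1e-10)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError):
            tj.kinetic_energy(_track([1.0], [1.0]))


class TestHiveActivity:
    def _series(self, k, bee="b"):
        return tj.EnergySeries(individual_id=bee, t0=0.0, dt=1.0, k=np.asarray(k, float))

    def test_single_series_identity(self):
        s = self._series([1, 2, 3])
        out = tj.hive_activity([s])
        np.testing.assert_array_equal(out.k, s.k)

    def test_mean_of_copies_is_the_series(self):
        s = self._series([1, 2, 3])
        out = tj.hive_activity([s, self._series([1, 2, 3], "c")])
        np.testing.assert_array_equal(out.k, s.k)

    def test_matches_elementwise_oracle(self, rng):
        ks = [np.abs(rng.normal(size=6)) for _ in range(3)]
        out = tj.hive_activity([self._series(k, str(i)) for i, k in enumerate(ks)])
        np.testing.assert_allclose(out.k, (ks[0] + ks[1] + ks[2]) / 3.0)
        out_sum = tj.hive_activity(
            [self._series(k, str(i)) for i, k in enumerate(ks)], aggregate="sum"
        )
        np.testing.assert_allclose(out_sum.k, ks[0] + ks[1] + ks[2])

    def test_mismatched_grids_rejected(self):
        a = self._series([1, 2, 3])
        b = tj.EnergySeries(individual_id="c", t0=5.0, dt=1.0, k=np.ones(3))
        with pytest.raises(ValueError):
            tj.hive_activity([a, b])


class TestPartitionWindows:
    def _activity(self, n=10):
        return tj.HiveActivitySeries(t0=0.0, dt=1.0, k=np.arange(n, dtype=float),
                                     n_individuals=1)

    def test_whole_span_window(self):
        s = self._activity()
        seg = tj.partition_windows(s, [tj.DayNightWindow("day", -1.0, 100.0)])[0]
        np.testing.assert_array_equal(seg.values, s.k)

    def test_zero_overlap_window_is_empty(self):
        seg = tj.partition_windows(self._activity(), [tj.DayNightWindow("night", 50.0, 60.0)])[0]
        assert seg.values.size == 0

    def test_abutting_windows_partition_exactly(self):
        s = self._activity(10)
        segs = tj.partition_windows(
            s, [tj.DayNightWindow("day", 0.0, 4.0), tj.DayNightWindow("night", 4.0, 10.0)]
        )
        assert segs[0].values.size + segs[1].values.size == 10
        # boundary sample t=4 lands in the later half-open window only
        assert 4.0 not in segs[0].times and 4.0 in segs[1].times

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            tj.partition_windows(
                self._activity(),
                [tj.DayNightWindow("day", 0.0, 5.0), tj.DayNightWindow("night", 4.0, 9.0)],
            )


def test_detections_roundtrip_comma_and_tab(tmp_path):
    df = pd.DataFrame(
        {"individual_id": ["a", "a"], "timestamp": [0.0, 1.0], "x": [1.5, 2.5], "y": [0.0, 1.0]}
    )
    p_csv = tmp_path / "d.csv"
    df.to_csv(p_csv, index=False)
    p_tsv = tmp_path / "d.tsv"
    df.to_csv(p_tsv, sep="\t", index=False)
    for p in (p_csv, p_tsv):
        back = tj.read_detections(p)
        np.testing.assert_allclose(back["x"], df["x"])


def test_series_write_read_roundtrip(tmp_path):
    s = tj.HiveActivitySeries(t0=3.0, dt=0.5, k=np.array([1.0, 2.25, 0.5]), n_individuals=7)
    path = tmp_path / "series.csv"
    tj.write_series(s, path, metadata={"note": "test"})
    t, v = tj.read_series(path)
    np.testing.assert_allclose(t, s.times)
    np.testing.assert_allclose(v, s.k)
    assert (tmp_path / "series.csv.meta.json").exists()
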