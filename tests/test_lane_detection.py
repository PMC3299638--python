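import numpy as np
import pytest

from gelphylo.errors import ConflictError, DetectionError, NotFoundError
from gelphylo.gel_image import GelImage
from gelphylo.lane_detection import (Lane, LaneDetectionParams, Profile, add_lane,
                                     column_max_profile, detect_lanes, remove_lane,
                                     runs_above, subtract_background)


def profile_of(values):
    return Profile(np.asarray(values, dtype=float), axis="columns")


def plateau_profile(intervals, value=200.0, length=200):
    """Zero profile with rectangular plateaus on the given [a, b) intervals."""
    v = np.zeros(length)
    for a, b in intervals:
        v[a:b] = value
    return profile_of(v)


class TestColumnMaxProfile:
    def test_uniform(self):
        prof = column_max_profile(GelImage(np.full((5, 7), 50.0)))
        assert prof.axis == "columns"
        assert np.all(prof.values == 50)

    def test_single_bright_column(self):
        px = np.zeros((4, 6))
        px[:, 3] = 255
        prof = column_max_profile(GelImage(px))
        expected = np.zeros(6)
        expected[3] = 255
        assert np.array_equal(prof.values, expected)

    def test_elementwise_max(self):
        prof = column_max_profile(GelImage(np.array([[10., 20., 30.], [5., 25., 15.]])))
        assert np.array_equal(prof.values, [10, 25, 30])


class TestRunsAbove:
    @pytest.mark.parametrize("values,threshold,expected", [
        ([0, 0, 9, 9, 0, 9, 0], 5, [(2, 4), (5, 6)]),
        ([1, 2, 3], 5, []),
        ([9, 9, 9], 5, [(0, 3)]),
        ([5, 0, 5], 5, [(0, 1), (2, 3)]),
    ])
    def test_intervals(self, values, threshold, expected):
        assert runs_above(profile_of(values), threshold) == expected


class TestDetectLanes:
    def test_two_plateaus(self):
        # brute-force oracle: both plateaus pass the width band at every level
        prof = plateau_profile([(20, 40), (60, 80)])
        lanes = detect_lanes(prof)
        assert [(l.col_start, l.col_end) for l in lanes] == [(20, 40), (60, 80)]
        assert [l.id for l in lanes] == [0, 1]

    def test_narrow_spike_eliminated(self):
        # hand trace: seed widths (20, 20, 2) -> mean 14 -> spike dropped,
        # final mean 20, deviation band [15, 25] excludes width 2 at all levels
        prof = plateau_profile([(20, 40), (60, 80)])
        prof.values[100:102] = 255.0
        lanes = detect_lanes(prof)
        assert [(l.col_start, l.col_end) for l in lanes] == [(20, 40), (60, 80)]

    def test_flat_profile_is_error(self):
        with pytest.raises(DetectionError):
            detect_lanes(profile_of(np.zeros(50)))

    def test_scale_invariance(self):
        prof = plateau_profile([(10, 30), (50, 70), (90, 112)], value=180.0)
        base = [(l.col_start, l.col_end) for l in detect_lanes(prof)]
        for factor in (0.25, 3.0, 40.0):
            scaled = profile_of(prof.values * factor)
            assert [(l.col_start, l.col_end) for l in detect_lanes(scaled)] == base

    def test_widths_within_deviation_band_and_no_overlap(self, rng):
        values = np.zeros(400)
        for start in range(10, 380, 35):
            width = int(rng.integers(16, 25))
            values[start:start + width] = rng.uniform(120, 255)
        lanes = detect_lanes(profile_of(values))
        widths = np.array([l.width for l in lanes], dtype=float)
        assert len(lanes) >= 2
        m = widths.mean()
        # every returned width obeys the 25% deviation rule around a common mean
        assert np.all(widths >= 0.75 * m - 1e-9) and np.all(widths <= 1.25 * m + 1e-9)
        for a, b in zip(lanes, lanes[1:]):
            assert a.col_end <= b.col_start

    def test_user_lane_width_overrides_estimation(self):
        # lone wide plateau would give mean 40; the user forces 10 so the
        # 40-wide run is rejected and only the 10-wide one survives
        prof = plateau_profile([(20, 60), (100, 110)])
        lanes = detect_lanes(prof, LaneDetectionParams(user_lane_width=10))
        assert [(l.col_start, l.col_end) for l in lanes] == [(100, 110)]

    def test_weak_lane_found_between_thresholds(self):
        # a lane at 25% of max is below the 70% seed but above the 15% floor
        prof = plateau_profile([(20, 40)], value=200.0)
        prof.values[60:80] = 50.0
        lanes = detect_lanes(prof)
        assert [(l.col_start, l.col_end) for l in lanes] == [(20, 40), (60, 80)]


class TestManualEdits:
    def test_add_appends_and_reindexes(self):
        lanes = [Lane(0, 10, 30), Lane(1, 70, 90)]
        out = add_lane(lanes, 100, 120)
        assert [(l.id, l.col_start, l.col_end) for l in out] == \
            [(0, 10, 30), (1, 70, 90), (2, 100, 120)]

    def test_add_between_resorts(self):
        out = add_lane([Lane(0, 10, 30), Lane(1, 70, 90)], 40, 60)
        assert [(l.id, l.col_start) for l in out] == [(0, 10), (1, 40), (2, 70)]

    def test_add_overlap_conflict(self):
        with pytest.raises(ConflictError):
            add_lane([Lane(0, 40, 60)], 0, 50)

    def test_remove(self):
        assert remove_lane([Lane(0, 10, 30)], 0) == []
        with pytest.raises(NotFoundError):
            remove_lane([Lane(0, 10, 30)], 5)


class TestSubtractBackground:
    def test_constant_lane_goes_to_zero(self):
        img = GelImage(np.full((100, 30), 40.0))
        out = subtract_background(img, [Lane(0, 5, 25)])
        assert np.allclose(out.pixels[:, 5:25], 0.0)

    def test_outside_lanes_zeroed(self):
        img = GelImage(np.full((50, 30), 90.0))
        out = subtract_background(img, [Lane(0, 5, 15)])
        assert np.all(out.pixels[:, 0:5] == 0) and np.all(out.pixels[:, 15:] == 0)

    def test_band_survives_baseline_removal(self):
        px = np.full((200, 20), 40.0)
        px[100:103, 5:15] += 100.0
        out = subtract_background(GelImage(px), [Lane(0, 5, 15)])
        band = out.pixels[100:103, 5:15]
        elsewhere = np.delete(out.pixels[:, 5:15], slice(98, 105), axis=0)
        assert band.min() > 80.0
        assert np.abs(elsewhere).max() < 10.0

    def test_never_negative_and_idempotent_on_constant(self, rng):
        img = GelImage(rng.uniform(0, 255, size=(60, 40)))
        lanes = [Lane(0, 2, 18), Lane(1, 22, 38)]
        once = subtract_background(img, lanes)
        assert once.pixels.min() >= 0
        flat = GelImage(np.full((60, 40), 33.0))
        a = subtract_background(flat, lanes)
        b = subtract_background(a, lanes)
        assert np.allclose(a.pixels, b.pixels)
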