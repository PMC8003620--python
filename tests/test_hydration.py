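"""Gel-layer thickness kinetics: percent metrics, plateaus, image fronts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swallowmetrics.hydration import (
    FilmFrame,
    SegmentationError,
    ThicknessSeries,
    cumulative_change,
    gel_layer_change,
    plateau_time,
    thickness_from_frames,
)
from swallowmetrics.synthetic import GeneratorConfig, gen_film_frames, gen_thickness_series


class TestGelLayerChange:
    @pytest.mark.parametrize(
        "t0, tn, expected",
        [
            (100.0, 100.0, 0.0),  # identity: no swelling
            (1000.0, 1250.0, 20.0),  # growth measured against current thickness
            (1250.0, 1000.0, -25.0),  # shrinking film keeps its sign
        ],
    )
    def test_percent_change_against_current_thickness(self, t0, tn, expected):
        series = ThicknessSeries("f", [0.0, 4.0], [[t0, tn]])
        assert gel_layer_change(series, 1) == pytest.approx(expected)

    def test_initial_denominator_gives_conventional_swelling_ratio(self):
        series = ThicknessSeries("f", [0.0, 4.0], [[1000.0, 1250.0]])
        assert gel_layer_change(series, 1, denominator="initial") == pytest.approx(25.0)

    def test_replicates_average_before_the_ratio(self):
        series = ThicknessSeries("f", [0.0, 4.0], [[1000.0, 1200.0], [1000.0, 1300.0]])
        assert gel_layer_change(series, 1) == pytest.approx((1250 - 1000) / 1250 * 100)

    def test_index_out_of_range_rejected(self, simple_series):
        with pytest.raises(IndexError):
            gel_layer_change(simple_series, 3)

    @pytest.mark.parametrize("bad", [0.0, -5.0, np.nan])
    def test_non_positive_thickness_rejected(self, bad):
        with pytest.raises(ValueError):
            ThicknessSeries("f", [0.0, 4.0], [[1000.0, bad]])

    @given(tn=st.floats(min_value=50.0, max_value=5000.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_current_thickness(self, tn):
        t0 = 1000.0
        series = ThicknessSeries("f", [0.0, 4.0], [[t0, tn]])
        bumped = ThicknessSeries("f", [0.0, 4.0], [[t0, tn + 1.0]])
        assert gel_layer_change(bumped, 1) > gel_layer_change(series, 1)
        assert (gel_layer_change(series, 1) == 0) == (tn == t0)


class TestCumulativeChange:
    def test_hand_summed_two_steps(self, simple_series):
        # 100/1100 + 250/1250, scaled by 100
        assert cumulative_change(simple_series, 2) == pytest.approx(29.0909, abs=1e-3)

    def test_constant_series_sums_to_zero(self):
        series = ThicknessSeries("f", [0.0, 4.0, 8.0], [[500.0, 500.0, 500.0]])
        assert cumulative_change(series, 2) == 0.0

    def test_single_step_equals_gel_layer_change(self, simple_series):
        assert cumulative_change(simple_series, 1) == gel_layer_change(simple_series, 1)

    def test_telescoping_increment_is_the_nth_term(self, simple_series):
        inc = cumulative_change(simple_series, 2) - cumulative_change(simple_series, 1)
        assert inc == pytest.approx(gel_layer_change(simple_series, 2))

    def test_requires_n_at_least_one(self, simple_series):
        with pytest.raises(ValueError):
            cumulative_change(simple_series, 0)


class TestPlateauTime:
    def test_detects_injected_plateau_onset(self, quiet_cfg):
        series = gen_thickness_series(300.0, 1.2, 0.05, quiet_cfg, saturate_at_s=24.0)
        assert plateau_time(series, tol=0.01) == 24.0

    def test_strictly_rising_series_never_settles(self):
        thick = 300.0 + 5.0 * np.arange(8.0)
        series = ThicknessSeries("f", np.arange(0, 32, 4.0), thick[None, :])
        assert plateau_time(series, tol=0.01) is None

    def test_constant_series_plateaus_from_the_start(self):
        series = ThicknessSeries("f", [0.0, 4.0, 8.0], [[300.0, 300.0, 300.0]])
        assert plateau_time(series, tol=0.01) == 0.0

    def test_needs_three_points(self):
        series = ThicknessSeries("f", [0.0, 4.0], [[300.0, 300.0]])
        with pytest.raises(ValueError):
            plateau_time(series, tol=0.01)


class TestThicknessFromFrames:
    def test_recovers_injected_front_advance(self, quiet_cfg):
        # front advancing 10 px at 100 px/mm -> 100 µm growth
        frames = gen_film_frames(
            300.0, np.array([0.0, 100.0]), np.array([0.0, 4.0]), quiet_cfg,
            scale_px_per_mm=100.0,
        )
        series = thickness_from_frames(frames)
        growth = series.thickness[0, 1] - series.thickness[0, 0]
        assert growth == pytest.approx(100.0, abs=10.0)  # within 1 px (10 µm)
        assert series.thickness[0, 0] == pytest.approx(300.0, abs=10.0)

    def test_identical_frames_give_zero_change(self, quiet_cfg):
        frames = gen_film_frames(
            300.0, np.zeros(3), np.array([0.0, 4.0, 8.0]), quiet_cfg,
            scale_px_per_mm=100.0,
        )
        series = thickness_from_frames(frames)
        assert gel_layer_change(series, 2) == pytest.approx(0.0, abs=1e-6)

    def test_blank_frame_flagged_and_excluded(self, quiet_cfg):
        frames = gen_film_frames(
            300.0, np.array([0.0, 50.0, 100.0]), np.array([0.0, 4.0, 8.0]),
            quiet_cfg, scale_px_per_mm=100.0, blank={1},
        )
        with pytest.warns(RuntimeWarning, match="excluded"):
            series = thickness_from_frames(frames)
        assert series.times.tolist() == [0.0, 8.0]

    def test_all_blank_frames_is_an_error(self):
        blank = FilmFrame(np.full((50, 50), 0.2), scale=100.0, timestamp=0.0)
        with pytest.warns(RuntimeWarning):
            with pytest.raises(SegmentationError):
                thickness_from_frames([blank])

    def test_mixed_calibrations_rejected(self, quiet_cfg):
        frames = gen_film_frames(
            300.0, np.zeros(2), np.array([0.0, 4.0]), quiet_cfg, scale_px_per_mm=100.0
        )
        frames[1].scale = 50.0
        with pytest.raises(ValueError):
            thickness_from_frames(frames)
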