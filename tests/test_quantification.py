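"""Kinetics quantification against brute-force and arithmetic oracles."""

import numpy as np
import pytest

from mcsmdr.containers import SegMask, TimeLapseStack
from mcsmdr.quantification import (
    EmptyMaskError,
    accumulated_fluorescence,
    anova_tukey,
    density_independence_check,
    log_edge_map,
    mean_channel_over_mask,
    mean_over_edges,
    ros_timeseries,
    uptake_timeseries,
)


def brute_force_mean(frame, mask):
    total, count = 0.0, 0
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            if mask[i, j]:
                total += frame[i, j]
                count += 1
    return total / count


class TestMeanOverMask:
    def test_constant_image(self):
        frame = np.full((8, 8), 5.0)
        mask = np.zeros((8, 8), np.uint8)
        mask[2:5, 2:5] = 1
        assert mean_channel_over_mask(frame, mask) == 5.0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            mean_channel_over_mask(np.ones((4, 4)), np.zeros((4, 4), np.uint8))

    def test_matches_pixel_loop_on_random_fixtures(self, rng):
        for _ in range(100):
            frame = rng.normal(size=(6, 7))
            mask = (rng.random((6, 7)) < 0.4).astype(np.uint8)
            if not mask.any():
                mask[0, 0] = 1
            assert mean_channel_over_mask(frame, mask) == pytest.approx(
                brute_force_mean(frame, mask), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_channel_over_mask(np.ones((4, 4)), np.ones((5, 5), np.uint8))


class TestLogEdges:
    def test_uniform_frame_no_edges(self):
        assert log_edge_map(np.full((32, 32), 7.0)).sum() == 0

    def test_step_edge_localised(self):
        frame = np.zeros((64, 64))
        frame[:, 32:] = 100.0
        edges = log_edge_map(frame, sigma=2.0)
        cols = np.where(edges.any(axis=0))[0]
        assert len(cols) > 0
        assert np.all(np.abs(cols - 31.5) <= 2 * 2.0 + 1)

    def test_blob_perimeter_recall(self):
        # ring of a rendered disk should be recovered by LoG edges
        yy, xx = np.mgrid[0:96, 0:96]
        dist = np.hypot(yy - 48, xx - 48)
        frame = 1000.0 / (1.0 + np.exp(dist - 20.0))
        edges = log_edge_map(frame, sigma=2.0, magnitude_percentile=80.0)
        perimeter = (np.abs(dist - 20.0) < 1.0)
        recall = edges[perimeter].mean()
        assert recall >= 0.8

    def test_mean_over_edges_equals_mask_mean(self, rng):
        frame = rng.normal(size=(20, 20))
        edges = (rng.random((20, 20)) < 0.3).astype(np.uint8)
        edges[0, 0] = 1
        assert mean_over_edges(frame, edges) == pytest.approx(
            mean_channel_over_mask(frame, edges))


def _const_stack(value, n_frames, hours):
    frames = np.full((n_frames, 16, 16), float(value), np.float32)
    times = np.linspace(0, hours, n_frames)
    return TimeLapseStack(phase=frames, green=frames.copy(), times_h=times)


def _full_masks(n, shape=(16, 16)):
    return [SegMask(np.ones(shape, np.uint8), frame_index=k) for k in range(n)]


class TestUptakeSeries:
    def test_constant_stack_accumulates_12c(self):
        stack = _const_stack(7.0, 13, 12.0)
        series = uptake_timeseries(stack, _full_masks(13))
        assert series.accumulated == pytest.approx(12.0 * 7.0)
        assert series.final_value == 7.0

    def test_mask_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            uptake_timeseries(_const_stack(1.0, 4, 1.0), _full_masks(3))

    def test_trapezoid_exact_under_grid_refinement(self):
        # piecewise-linear series: refining the grid must not change the integral
        t1 = np.array([0.0, 2.0, 6.0])
        v1 = np.array([0.0, 4.0, 8.0])
        t2 = np.linspace(0, 6, 25)
        v2 = np.interp(t2, t1, v1)
        assert accumulated_fluorescence(t1, v1) == pytest.approx(
            accumulated_fluorescence(t2, v2), rel=1e-12)

    def test_empty_mask_frames_dropped(self):
        stack = _const_stack(3.0, 4, 3.0)
        masks = _full_masks(4)
        masks[2] = SegMask(np.zeros((16, 16), np.uint8), frame_index=2)
        series = uptake_timeseries(stack, masks)
        assert series.dropped_frames == [2]
        assert len(series.times_h) == 3


class TestRosSeries:
    def test_linear_decay_flagged(self):
        stack = _const_stack(0.0, 4, 1.0)
        for k, v in enumerate([9.0, 7.0, 5.0, 3.0]):
            stack.green[k] = v
        series, flag = ros_timeseries(stack, _full_masks(4))
        slope = np.polyfit(series.times_h, series.mean_fluorescence, 1)[0]
        assert slope == pytest.approx(-6.0)  # -2 per frame at 3 frames/hour
        assert flag is True

    def test_flat_series_not_flagged(self):
        series, flag = ros_timeseries(_const_stack(5.0, 4, 1.0), _full_masks(4))
        assert flag is False

    def test_generator_round_trip(self, sensitive, resistant, geometry128):
        from mcsmdr.synthetic import make_ros_stack

        for ph, expected in ((sensitive, True), (resistant, False)):
            stack, masks = make_ros_stack(ph, geometry128, duration_h=1.0,
                                          frame_interval_min=20.0, seed=11,
                                          image_size=128)
            _, flag = ros_timeseries(stack, masks)
            assert flag is expected


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        comp = anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 10)
        comp = anova_tukey({"a": a, "b": b})
        t = stats.ttest_ind(a, b).statistic
        assert comp.f_statistic == pytest.approx(t**2, rel=1e-10)

    def test_separated_groups_all_significant(self, rng):
        jitter = rng.normal(0, 1e-3, (3, 3))
        comp = anova_tukey({"a": 0 + jitter[0], "b": 10 + jitter[1],
                            "c": 20 + jitter[2]})
        assert all(p < 0.001 for p in comp.tukey_p.values())
        assert comp.stars(("a", "b")) == "***"

    def test_all_constant_identical_handled(self):
        comp = anova_tukey({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert comp.f_statistic == 0.0 and comp.p_value == 1.0

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 2]})


class TestDensityIndependence:
    def test_identical_groups_independent(self):
        comp, verdict = density_independence_check(
            {1e4: [5.0, 5.0, 5.0], 5e4: [5.0, 5.0, 5.0]})
        assert verdict == "independent" and comp.p_value == 1.0

    def test_scaled_uptake_detected_as_dependent(self, rng):
        groups = {d: 100.0 * (1 + i) + rng.normal(0, 1.0, 6)
                  for i, d in enumerate((1e4, 1.5e4, 5e4))}
        _, verdict = density_independence_check(groups)
        assert verdict == "dependent"

    def test_single_density_rejected(self):
        with pytest.raises(ValueError):
            density_independence_check({1e4: [1.0, 2.0]})


def test_plotting_helpers_render(tmp_path):
    import matplotlib.pyplot as plt

    from mcsmdr.plotting import plot_kinetics, pseudocolor_frame

    stack = _const_stack(5.0, 3, 1.0)
    series = uptake_timeseries(stack, _full_masks(3))
    ax = plot_kinetics([series])
    assert ax.get_xlabel() == "time (h)"
    ax2 = pseudocolor_frame(stack, 0)
    assert ax2 is not None
    plt.close("all")


def test_monolayer_edge_fluorescence_rises_for_sensitive_line():
    """Edge-mode quantification of a 2-D culture: mean green over LoG
    edges at 6 h exceeds the value at t=0 for an accumulating line."""
    from mcsmdr.synthetic import PHENOTYPES, make_monolayer_stack

    stack = make_monolayer_stack(PHENOTYPES["sensitive"], n_cells=60,
                                 frame_interval_min=180.0, duration_h=6.0,
                                 seed=4, image_size=128)
    series = uptake_timeseries(stack, mode="monolayer-edges")
    assert series.culture_mode == "2D"
    assert series.mean_fluorescence[-1] > series.mean_fluorescence[0]
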