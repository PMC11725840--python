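"""Core screen statistics: mAI / NVS arithmetic, window counting against a
brute-force oracle, permutation-test behavior, classification thresholds,
baseline comparison, static-bar asymmetry and circular PD differences."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premotion import (RunConfig, build_windows, classify_post, classify_pre,
                       compare_pd, direction_spike_counts,
                       motion_asymmetry_index, normalized_vector_sum,
                       permutation_test)
from premotion.asymmetry import (DirectionalResponse, baseline_comparison,
                                 classify_window, count_in_window,
                                 estimate_baseline_rate,
                                 static_asymmetry_index)
from premotion.geometry import DIRECTIONS_DEG


class TestMotionAsymmetryIndex:
    @pytest.mark.parametrize("pd_count,nd_count,expected", [
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 1.0),
        (15.0, 5.0, 0.5),
    ])
    def test_arithmetic(self, pd_count, nd_count, expected):
        counts = np.full(8, nd_count)
        counts[2] = pd_count  # PD at 90 deg, ND at 270 deg
        mai, pd_deg = motion_asymmetry_index(counts)
        assert mai == pytest.approx(expected)
        if pd_count > nd_count:  # unique maximum, PD well defined
            assert pd_deg == 90.0

    def test_all_zero_flagged(self):
        mai, pd_deg = motion_asymmetry_index(np.zeros(8))
        assert mai == 0.0 and np.isnan(pd_deg)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mai, _ = motion_asymmetry_index(rng.integers(0, 50, 8))
            assert 0.0 <= mai <= 1.0


class TestNormalizedVectorSum:
    def test_uniform_counts(self):
        nvs, _ = normalized_vector_sum(np.full(8, 3.0))
        assert nvs == pytest.approx(0.0, abs=1e-12)

    def test_single_direction(self):
        counts = np.zeros(8)
        counts[3] = 7.0
        nvs, ang = normalized_vector_sum(counts)
        assert nvs == pytest.approx(1.0)
        assert ang == pytest.approx(135.0)

    def test_two_opposed_directions(self):
        counts = np.zeros(8)
        counts[0], counts[4] = 4.0, 2.0
        nvs, ang = normalized_vector_sum(counts)
        assert nvs == pytest.approx(2.0 / 6.0)
        assert ang == pytest.approx(0.0, abs=1e-9)


@settings(deadline=None, max_examples=40)
@given(counts=st.lists(st.integers(0, 30), min_size=8, max_size=8),
       k=st.integers(1, 7))
def test_rotation_equivariance(counts, k):
    """Rotating direction labels rotates the PD and leaves mAI/NVS
    unchanged."""
    from premotion import circular_difference
    c = np.array(counts, float)
    mai0, pd0 = motion_asymmetry_index(c)
    nvs0, ang0 = normalized_vector_sum(c)
    rolled = np.roll(c, k)
    mai1, pd1 = motion_asymmetry_index(rolled)
    nvs1, ang1 = normalized_vector_sum(rolled)
    assert nvs1 == pytest.approx(nvs0)
    # PD-dependent quantities are equivariant when the argmax is unique
    # (ties break by index order, which rolling permutes)
    unique_max = c.sum() > 0 and np.count_nonzero(c == c.max()) == 1
    if unique_max:
        assert mai1 == pytest.approx(mai0)
        assert abs(circular_difference(pd1, pd0 + 45.0 * k)) < 1e-6
    if nvs0 > 1e-9:
        assert abs(circular_difference(ang1, ang0 + 45.0 * k)) < 1e-6


class TestWindowCounting:
    def test_half_open_boundaries(self):
        assert count_in_window([1.0], 1.0, 2.0) == 1   # start inclusive
        assert count_in_window([2.0], 1.0, 2.0) == 0   # end exclusive

    def test_exclusion_interval(self):
        t = np.linspace(0.0, 1.0, 101)
        full = count_in_window(t, 0.0, 1.0)
        part = count_in_window(t, 0.0, 1.0, exclusion=(0.25, 0.5))
        brute = np.count_nonzero((t < 0.25) | (t >= 0.5)) - 1  # t = 1 excl.
        assert part == brute
        assert part < full

    def test_counts_match_bruteforce(self, bar_recording):
        rec = bar_recording
        cell = rec.ground_truth[0]
        windows = build_windows(cell.rf_center, rec.geometry, 900.0, 600.0)
        spikes = rec.spikes_of(cell.cell_id, 0)
        resp = direction_spike_counts(spikes, rec.trials, windows, "PRE",
                                      cell.rf_center)
        # brute force: per trial, filter the raw spike array directly
        from premotion.geometry import bar_alignment_time
        t = spikes["t_s"].to_numpy()
        w0, w1 = windows.pre_window
        for di, d in enumerate(DIRECTIONS_DEG):
            g = rec.trials[rec.trials["direction"] == d].sort_values("onset")
            for ri, trial in enumerate(g.itertuples(index=False)):
                t0 = bar_alignment_time(trial.onset, trial.p0, trial.speed,
                                        trial.direction, cell.rf_center)
                brute = np.sum((t >= t0 + w0) & (t < t0 + w1))
                assert resp.counts[di, ri] == brute

    def test_missing_direction_flagged(self, bar_recording):
        rec = bar_recording
        cell = rec.ground_truth[0]
        windows = build_windows(cell.rf_center, rec.geometry, 900.0, 600.0)
        broken = rec.trials[rec.trials["direction"] != 90.0]
        with pytest.raises(ValueError, match="direction 90"):
            direction_spike_counts(rec.spikes_of(cell.cell_id, 0), broken,
                                   windows, "PRE", cell.rf_center)


class TestPermutationTest:
    def test_identical_counts_give_one(self):
        assert permutation_test(np.full((8, 5), 4.0)) == 1.0

    def test_single_hot_direction_is_significant(self):
        counts = np.zeros((8, 5))
        counts[0] = 10.0  # 50 spikes at one direction, none elsewhere
        p = permutation_test(counts, n_perm=999, seed=0)
        assert p <= 0.002

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        c = rng.poisson(3.0, (8, 5))
        assert permutation_test(c, seed=42) == permutation_test(c, seed=42)

    def test_requires_three_repetitions(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((8, 2)))


def _response(mean_counts, n_rep=5, kind="PRE", jitter=0):
    """Deterministic counts matrix with the requested per-direction means
    (means must be integers unless jitter spreads them)."""
    c = np.tile(np.asarray(mean_counts, float)[:, None], (1, n_rep))
    if jitter:
        rng = np.random.default_rng(jitter)
        c = rng.poisson(np.clip(c, 0.01, None))
    return DirectionalResponse(window_kind=kind, counts=c.astype(int),
                               duration=1.0)


class TestClassification:
    def test_passing_cell(self):
        # strong one-sided tuning: all four criteria met
        resp = _response([5, 1, 1, 1, 1, 1, 1, 1], n_rep=5, jitter=3)
        s = classify_pre(resp, seed=0)
        assert s.is_asymmetric
        assert s.mai > 0.3 and s.nvs > 0.15 and s.p_perm < 0.05

    def test_mai_threshold_is_strict(self):
        # mAI = (9 - 5) / (9 + 5) = 0.286 < 0.3 with everything else strong
        resp = _response([9, 2, 1, 1, 5, 1, 1, 2], n_rep=6)
        s = classify_window(resp, seed=0)
        assert s.mai < 0.3
        assert not s.is_asymmetric

    def test_count_threshold(self):
        # tuned but too few spikes per repetition (mean PD count < 2)
        counts = np.zeros((8, 5), int)
        counts[0] = [1, 1, 1, 1, 1]
        resp = DirectionalResponse("PRE", counts, 1.0)
        s = classify_window(resp, theta_count=2.0, seed=0)
        assert not s.is_asymmetric

    def test_no_spikes_undefined(self):
        s = classify_post(_response(np.zeros(8), kind="POST"), seed=0)
        assert not s.is_asymmetric and not s.defined

    def test_window_kind_checked(self):
        with pytest.raises(ValueError):
            classify_pre(_response(np.ones(8), kind="POST"))


class TestBaselineComparison:
    def test_exact_baseline_is_none(self):
        resp = _response([3, 3, 3, 3, 3, 3, 3, 3])
        s = classify_window(resp, seed=0)
        assert baseline_comparison(resp, s, baseline_rate=3.0) == "none"

    def test_enhanced_pd(self):
        resp = _response([20, 2, 2, 2, 2, 2, 2, 2], jitter=5)
        s = classify_window(resp, seed=0)
        assert baseline_comparison(resp, s, baseline_rate=2.0) == "enhanced"

    def test_suppressed_nd(self):
        resp = _response([10, 10, 10, 10, 1, 10, 10, 10], jitter=6)
        s = classify_window(resp, seed=0)
        label = baseline_comparison(resp, s, baseline_rate=10.0)
        assert label in ("suppressed", "both")


class TestStaticAsymmetryIndex:
    def _trials(self, offsets, axis=0.0, onset0=0.0):
        rows = []
        for i, off in enumerate(offsets):
            rows.append(dict(trial_id=i, onset=onset0 + 3.0 * i,
                             duration=0.5, axis_deg=axis, offset=off))
        return pd.DataFrame(rows)

    def _spikes(self, trials, rates):
        ts = []
        for trial, r in zip(trials.itertuples(index=False), rates):
            ts.extend(np.linspace(trial.onset, trial.onset + 0.499,
                                  int(round(r * 0.5))))
        return pd.DataFrame({"t_s": np.array(ts)})

    def test_equal_sides_zero(self):
        trials = self._trials([-600.0, 600.0])
        spikes = self._spikes(trials, [10.0, 10.0])
        out = static_asymmetry_index(spikes, trials, (0, 0), pd_deg=0.0,
                                     central_radius=350.0)
        assert out["sai"] == pytest.approx(0.0)

    def test_silent_null_side_is_one(self):
        # preferred side = the side PD motion comes from (negative offset
        # along the PD axis)
        trials = self._trials([-600.0, 600.0])
        spikes = self._spikes(trials, [12.0, 0.0])
        out = static_asymmetry_index(spikes, trials, (0, 0), pd_deg=0.0,
                                     central_radius=350.0)
        assert out["sai"] == pytest.approx(1.0)

    def test_missing_side_flagged(self):
        trials = self._trials([-600.0, -500.0])
        spikes = self._spikes(trials, [10.0, 10.0])
        out = static_asymmetry_index(spikes, trials, (0, 0), pd_deg=0.0,
                                     central_radius=350.0)
        assert np.isnan(out["sai"])
        assert out["n_null"] == 0

    def test_nearest_axis_selected(self):
        trials = pd.concat([self._trials([-600.0, 600.0], axis=0.0),
                            self._trials([-600.0, 600.0], axis=90.0,
                                         onset0=100.0)],
                           ignore_index=True)
        spikes = self._spikes(trials, [10.0, 2.0, 5.0, 5.0])
        out = static_asymmetry_index(spikes, trials, (0, 0), pd_deg=10.0,
                                     central_radius=350.0)
        assert out["axis_deg"] == 0.0
        assert out["sai"] == pytest.approx((10.0 - 2.0) / 12.0)


class TestComparePd:
    @pytest.mark.parametrize("a,b,expected", [
        (10.0, 350.0, 20.0),
        (0.0, 180.0, 180.0),
        (350.0, 10.0, -20.0),
        (90.0, 90.0, 0.0),
    ])
    def test_circular_difference(self, a, b, expected):
        assert compare_pd(a, b) == pytest.approx(expected)

    def test_nan_propagates(self):
        assert np.isnan(compare_pd(float("nan"), 10.0))


def test_baseline_estimated_from_blanks(bar_recording):
    rec = bar_recording
    cell = rec.ground_truth[0]
    spikes = rec.spikes_of(cell.cell_id, 0)
    est = estimate_baseline_rate(spikes, rec.trials, window=1.0)
    assert est == pytest.approx(cell.baseline_rate, rel=0.35)


def test_polar_plot_frame_tidy():
    from premotion.asymmetry import polar_plot_frame
    resp = _response([5, 1, 1, 1, 1, 1, 1, 1], n_rep=4)
    df = polar_plot_frame(resp)
    assert len(df) == 32
    assert set(df.columns) == {"direction_deg", "mean_count", "sem",
                               "repetition", "count"}
    assert df[df["direction_deg"] == 0.0]["mean_count"].iloc[0] == 5.0
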