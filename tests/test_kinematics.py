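import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import motorwheel as mw
from motorwheel.kinematics import CenteredTrace

FR = 71.5


def centered(values, fr=FR):
    return CenteredTrace(np.asarray(values, float), 1.0, 0.0, fr)


class TestCenterPaw:
    def test_direct_substitution(self):
        # alpha 0.1, median 200 px, raw 150 px -> 5.0 mm forward
        raw = np.array([200.0, 200.0, 150.0, 250.0, 200.0])
        t = mw.center_paw(raw, alpha=0.1)
        assert t.d_median == 200.0
        assert t.values_mm[2] == pytest.approx(5.0)
        assert t.values_mm[0] == 0.0

    def test_three_point_example(self):
        t = mw.center_paw(np.array([1.0, 2.0, 3.0]), alpha=1.0)
        assert t.values_mm.tolist() == [1.0, 0.0, -1.0]

    def test_constant_series_gives_zeros(self):
        t = mw.center_paw(np.full(10, 7.0), alpha=0.5)
        assert np.all(t.values_mm == 0.0)

    def test_median_of_centered_trace_is_zero(self, rng):
        t = mw.center_paw(rng.normal(300, 20, 1001), alpha=0.1)
        assert np.median(t.values_mm) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            mw.center_paw(np.array([1.0]), alpha=0.0)
        with pytest.raises(ValueError):
            mw.center_paw(np.array([]), alpha=0.1)


class TestSmoothTrace:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.2)
        assert np.allclose(mw.smooth_trace(x, cutoff=0.1), x)

    def test_high_frequency_sinusoid_attenuated(self):
        # 10x above the cutoff: analytic single-pass order-2 gain is
        # 1/sqrt(1 + 10^4) ~ 1%; filtfilt squares it, well under 5%
        n = 4000
        t = np.arange(n)
        cutoff = 0.05  # fraction of Nyquist
        x = np.sin(np.pi * (10 * cutoff) * t)
        y = mw.smooth_trace(x, cutoff=cutoff)
        assert np.abs(y[500:-500]).max() < 0.05 * np.abs(x).max()

    def test_passband_sinusoid_preserved(self):
        n = 4000
        t = np.arange(n)
        x = np.sin(np.pi * 0.005 * t)
        y = mw.smooth_trace(x, cutoff=0.2)
        assert np.abs(y - x).max() < 0.02

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mw.smooth_trace(np.zeros(5), cutoff=0.1)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            mw.smooth_trace(np.zeros(100), cutoff=1.5)


def plant_spike(n=500, start=200, d=20, length=4.0, height=3.0):
    """One stride: linear x rise (then fall) with a half-sine y spike."""
    x = np.zeros(n)
    y = np.zeros(n)
    ramp = np.linspace(0, length, d + 1)
    x[start : start + d + 1] = ramp
    x[start + d : start + 2 * d + 1] = ramp[::-1]
    y[start : start + d + 1] = height * np.sin(np.linspace(0, np.pi, d + 1))
    return x, y


class TestDetectStrides:
    def test_flat_traces_yield_no_strides(self):
        s = mw.detect_strides(centered(np.zeros(300)), centered(np.zeros(300)))
        assert s.n_strides == 0

    def test_single_planted_spike_pair(self):
        x, y = plant_spike(length=4.0)
        s = mw.detect_strides(centered(x), centered(y))
        assert s.n_strides == 1
        assert s.lengths_mm[0] == pytest.approx(4.0)

    def test_planted_counts_and_lengths_recovered_exactly(self, ascending):
        left, right, truth = mw.gen_paw_trajectories(
            ascending, strides_per_block=10, stride_length_mm=4.5, seed=7
        )
        lx = mw.center_paw(left.x_raw, 0.1, FR)
        ly = mw.center_paw(left.y_raw, 0.1, FR)
        s = mw.detect_strides(lx, ly)
        planted = [t for t in truth.stride_times if t[0] == "left"]
        assert s.n_strides == len(planted) == 40
        assert np.allclose(np.sort(s.lengths_mm), [t[3] for t in planted])
        stats = mw.block_stride_stats(s, ascending)
        assert stats["stride_count"].tolist() == [0, 10, 10, 10, 10, 0]

    def test_count_invariant_to_offsets(self):
        x, y = plant_spike()
        base = mw.detect_strides(centered(x), centered(y)).n_strides
        shifted = mw.detect_strides(centered(x + 11.0), centered(y - 4.0))
        assert shifted.n_strides == base
        assert shifted.lengths_mm[0] == pytest.approx(4.0)

    def test_lengths_scale_linearly_with_calibration(self):
        x, y = plant_spike(length=4.0)
        s1 = mw.detect_strides(centered(x), centered(y))
        s2 = mw.detect_strides(centered(2 * x), centered(2 * y))
        assert s2.n_strides == s1.n_strides
        assert s2.lengths_mm[0] == pytest.approx(2 * s1.lengths_mm[0])

    def test_count_robust_to_noise(self, ascending):
        """<= 2% stride-count error at noise up to 10% of spike amplitude."""
        total_err = 0
        total = 0
        for seed in range(20):
            left, _, truth = mw.gen_paw_trajectories(
                ascending,
                strides_per_block=10,
                spike_height_mm=3.0,
                noise_sd_mm=0.3,
                seed=seed,
            )
            lx = mw.center_paw(left.x_raw, 0.1, FR)
            ly = mw.center_paw(left.y_raw, 0.1, FR)
            lx.values_mm = mw.smooth_trace(lx.values_mm, cutoff=0.3)
            ly.values_mm = mw.smooth_trace(ly.values_mm, cutoff=0.3)
            n_planted = sum(1 for t in truth.stride_times if t[0] == "left")
            n_found = mw.detect_strides(lx, ly).n_strides
            total_err += abs(n_found - n_planted)
            total += n_planted
        assert total_err / total <= 0.02


class TestBlockStats:
    def test_reported_group_means_fold_change(self):
        """Stride counts 271.8 (15 mm/s) -> 475.7 (60 mm/s) is a ~75% rise."""
        assert mw.percent_change(271.8, 475.7) == pytest.approx(75.0, abs=0.05)
        assert mw.percent_change(271.8, 475.7) >= 70.0

    def test_equal_counts_zero_change(self):
        assert mw.percent_change(100.0, 100.0) == 0.0

    def test_empty_block_reports_missing_mean_length(self, ascending):
        x, y = plant_spike(n=int(720 * FR), start=130 * int(FR), d=20)
        s = mw.detect_strides(centered(x), centered(y))
        stats = mw.block_stride_stats(s, ascending)
        assert stats.loc[1, "stride_count"] == 1
        assert np.isnan(stats.loc[0, "mean_length_mm"])


class TestCoordinationIndex:
    def test_perfect_alternation(self, rng):
        left = centered(rng.normal(0, 1, 500))
        right = CenteredTrace(-left.values_mm, 1.0, 0.0, FR)
        assert mw.coordination_index(left, right) == pytest.approx(1.0)

    def test_perfect_in_phase(self, rng):
        left = centered(rng.normal(0, 1, 500))
        assert mw.coordination_index(left, left) == pytest.approx(-1.0)

    def test_antisymmetric_under_negation(self, rng):
        left = centered(rng.normal(0, 1, 500))
        right = centered(rng.normal(0, 1, 500))
        ci = mw.coordination_index(left, right)
        neg = CenteredTrace(-right.values_mm, 1.0, 0.0, FR)
        assert mw.coordination_index(left, neg) == pytest.approx(-ci)

    def test_independent_noise_near_zero(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals.append(
                mw.coordination_index(
                    centered(r.normal(0, 1, 2000)), centered(r.normal(0, 1, 2000))
                )
            )
        assert abs(np.mean(vals)) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mw.coordination_index(centered(np.zeros(100)), centered(np.ones(100)))

    @given(st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        ci = mw.coordination_index(
            centered(r.normal(0, 1, 50)), centered(r.normal(0, 1, 50))
        )
        assert -1.0 <= ci <= 1.0

    def test_generated_coordination_matches_parameter(self, ascending):
        """Planted coordination 1 is exact; coordination 0 averages to ~0."""
        left, right, _ = mw.gen_paw_trajectories(ascending, 10, coordination=1.0, seed=0)
        lx = mw.center_paw(left.x_raw, 0.1, FR)
        rx = mw.center_paw(right.x_raw, 0.1, FR)
        blk = ascending.block_slices(FR)[4]
        assert mw.coordination_index(lx, rx, blk) == pytest.approx(1.0, abs=1e-9)

        vals = []
        for seed in range(20):
            left, right, _ = mw.gen_paw_trajectories(
                ascending, 10, coordination=0.0, noise_sd_mm=1.0, seed=seed
            )
            lx = mw.center_paw(left.x_raw, 0.1, FR)
            rx = mw.center_paw(right.x_raw, 0.1, FR)
            vals.append(mw.coordination_index(lx, rx, blk))
        assert abs(np.mean(vals)) < 0.1
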