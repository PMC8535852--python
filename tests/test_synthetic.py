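import numpy as np
import pytest

import motorwheel as mw
from motorwheel.synthetic import coupling_covariance, default_strides_per_block


class TestDeterminism:
    """Every generator is a pure function of its seed."""

    def test_paw_trajectories(self, ascending):
        a = mw.gen_paw_trajectories(ascending, 10, noise_sd_mm=0.5, seed=9)
        b = mw.gen_paw_trajectories(ascending, 10, noise_sd_mm=0.5, seed=9)
        assert np.array_equal(a[0].x_raw, b[0].x_raw)
        assert np.array_equal(a[1].y_raw, b[1].y_raw)

    def test_network_traces(self):
        c = mw.chain_coupling(4, 0.5)
        a, _ = mw.gen_network_traces(4, c, frames=500, noise_sd=0.1, seed=2, mode="markov")
        b, _ = mw.gen_network_traces(4, c, frames=500, noise_sd=0.1, seed=2, mode="markov")
        assert a.dff.tobytes() == b.dff.tobytes()

    def test_transition_responders(self, ascending):
        a, ta = mw.gen_transition_responders(ascending, 20, seed=4)
        b, tb = mw.gen_transition_responders(ascending, 20, seed=4)
        assert a.dff.tobytes() == b.dff.tobytes()
        assert np.array_equal(ta.responder_labels, tb.responder_labels)

    def test_roi_sessions(self):
        a, ta = mw.gen_roi_sessions(50, 3, jitter_px=1.0, dropout=0.3, seed=6)
        b, tb = mw.gen_roi_sessions(50, 3, jitter_px=1.0, dropout=0.3, seed=6)
        assert ta.day_shifts == tb.day_shifts
        for x, y in zip(a, b):
            assert np.array_equal(x.xy, y.xy)


class TestCouplingCovariance:
    def test_markov_chain_closed_form(self):
        sigma = coupling_covariance(mw.chain_coupling(3, 0.8), mode="markov")
        assert sigma[0, 1] == pytest.approx(0.8)
        assert sigma[0, 2] == pytest.approx(0.64)
        # precision supported on the chain only: partial corr(A,C) = 0
        p = np.linalg.inv(sigma)
        assert abs(p[0, 2]) < 1e-12

    def test_markov_rejects_cyclic_graph(self):
        c = mw.chain_coupling(3, 0.5)
        c[0, 2] = c[2, 0] = 0.5
        with pytest.raises(ValueError, match="forest"):
            coupling_covariance(c, mode="markov")

    def test_precision_mode_encodes_partial_correlations(self):
        c = mw.chain_coupling(3, 0.4)
        sigma = coupling_covariance(c, mode="precision")
        p = np.linalg.inv(sigma)
        d = np.sqrt(np.diag(p))
        partial = -p / np.outer(d, d)
        assert partial[0, 1] == pytest.approx(0.4, abs=1e-9)
        assert abs(partial[0, 2]) < 1e-9

    def test_unstable_coupling_rejected_without_conditioning(self):
        c = mw.chain_coupling(3, 0.8)  # spectral radius 0.8*sqrt(2) > 1
        with pytest.raises(ValueError, match="unstable"):
            coupling_covariance(c, mode="precision")
        sigma = coupling_covariance(c, mode="precision", condition=True)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)

    def test_conditioning_preserves_zero_pattern(self):
        c = mw.random_coupling(20, density=0.15, strength=0.4, seed=1)
        sigma = coupling_covariance(c, mode="precision", condition=True)
        p = np.linalg.inv(sigma)
        absent = (c == 0) & ~np.eye(20, dtype=bool)
        assert np.abs(p[absent]).max() < 1e-8


class TestNetworkTraces:
    def test_uncoupled_neurons_uncorrelated(self):
        traces, _ = mw.gen_network_traces(15, np.zeros((15, 15)), frames=4000, seed=0)
        r = np.corrcoef(traces.dff)
        off = np.abs(r[np.triu_indices(15, 1)])
        assert off.mean() < 0.05

    def test_covariance_converges_to_analytic(self):
        """Frobenius error of the sample correlation decreases with frames."""
        c = mw.chain_coupling(5, 0.6)
        sigma = coupling_covariance(c, mode="markov")
        errs = []
        for frames in (500, 2000, 8000):
            per_seed = []
            for seed in range(3):
                traces, _ = mw.gen_network_traces(
                    5, c, frames=frames, seed=seed, mode="markov"
                )
                r = np.corrcoef(traces.dff)
                per_seed.append(np.linalg.norm(r - sigma))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mw.gen_network_traces(4, np.zeros((3, 3)))

    def test_few_frames_warn(self):
        with pytest.warns(UserWarning, match="ill-conditioned"):
            mw.gen_network_traces(10, np.zeros((10, 10)), frames=8, seed=0)


class TestTransitionResponders:
    def test_zero_fraction_all_labels_false(self, ascending):
        _, truth = mw.gen_transition_responders(ascending, 30, responder_fraction=0.0, seed=0)
        assert not truth.responder_labels.any()

    def test_fraction_rounds_to_count(self, ascending):
        _, truth = mw.gen_transition_responders(ascending, 50, responder_fraction=0.2, seed=1)
        assert truth.responder_labels.sum() == 10

    def test_unit_gain_equals_baseline_process(self, ascending):
        """With gain 1 responders and non-responders share one rate."""
        tm, truth = mw.gen_transition_responders(
            ascending, 400, responder_fraction=0.5, effect_rate_gain=1.0,
            baseline_rate_hz=0.2, seed=3,
        )
        ev = truth.event_raster.events
        r_resp = ev[truth.responder_labels].mean()
        r_non = ev[~truth.responder_labels].mean()
        assert r_resp == pytest.approx(r_non, rel=0.05)

    def test_responders_elevated_in_windows(self, ascending):
        tm, truth = mw.gen_transition_responders(
            ascending, 200, responder_fraction=0.5, effect_rate_gain=4.0,
            baseline_rate_hz=0.1, seed=5,
        )
        s = mw.build_transition_vector(ascending, tm.frame_rate)
        inwin = s.values.astype(bool)
        ev = truth.event_raster.events[truth.responder_labels]
        ratio = ev[:, inwin].mean() / ev[:, ~inwin].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_invalid_parameters_rejected(self, ascending):
        with pytest.raises(ValueError):
            mw.gen_transition_responders(ascending, 10, responder_fraction=1.5)
        with pytest.raises(ValueError):
            mw.gen_transition_responders(ascending, 10, effect_rate_gain=0.5)


class TestROISessions:
    def test_no_perturbation_reproduces_day_one(self):
        tabs, truth = mw.gen_roi_sessions(30, 4, max_shift_px=0, jitter_px=0, dropout=0, seed=2)
        for t in tabs[1:]:
            assert np.array_equal(t.xy, tabs[0].xy)
        assert truth.day_shifts == [(0, 0)] * 4

    def test_dropout_expectation(self):
        counts = []
        for seed in range(5):
            tabs, _ = mw.gen_roi_sessions(200, 2, dropout=0.5, seed=seed)
            counts.append(tabs[1].n_neurons)
        assert np.mean(counts) == pytest.approx(100, abs=15)

    def test_identity_map_injective_per_day(self):
        _, truth = mw.gen_roi_sessions(80, 3, dropout=0.3, seed=8)
        for day, m in truth.identity_map.items():
            assert len(set(m.values())) == len(m)

    def test_shifts_bounded_by_search_window(self):
        _, truth = mw.gen_roi_sessions(20, 10, max_shift_px=12, seed=4)
        for dx, dy in truth.day_shifts:
            assert abs(dx) <= 12 and abs(dy) <= 12

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError):
            mw.gen_roi_sessions(100_000, 2, field_px=64, seed=0)


def test_default_stride_counts_match_group_means(ascending):
    counts = default_strides_per_block(ascending)
    assert counts[0] == counts[-1] == 0
    assert counts[1] == pytest.approx(271.8, abs=1.0)  # 15 mm/s
    assert counts[4] == pytest.approx(475.7, abs=1.0)  # 60 mm/s
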