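import numpy as np
import pandas as pd
import pytest

import motorwheel as mw
from motorwheel.connectivity import PairwiseMatrix

FR = 6.43


def tm(x, **kw):
    return mw.TraceMatrix(np.asarray(x, float), FR, **kw)


class TestPearsonMatrix:
    def test_duplicated_traces_fully_correlated(self, rng):
        x = rng.normal(0, 1, 300)
        m = mw.pearson_matrix(tm([x, x, -x]))
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self, rng):
        m = mw.pearson_matrix(tm(rng.normal(0, 1, (20, 4000))))
        off = m.values[np.triu_indices(20, 1)]
        assert np.abs(off).mean() < 0.05

    def test_chain_correlation_is_path_product(self):
        traces, _ = mw.gen_network_traces(
            3, mw.chain_coupling(3, 0.8), frames=4000, seed=4, mode="markov"
        )
        m = mw.pearson_matrix(traces)
        assert m.values[0, 1] == pytest.approx(0.8, abs=0.05)
        assert m.values[0, 2] == pytest.approx(0.64, abs=0.06)

    def test_zero_variance_neurons_excluded(self, rng):
        x = rng.normal(0, 1, (3, 100))
        x[1] = 5.0
        m = mw.pearson_matrix(tm(x))
        assert m.n_neurons == 2
        assert m.neuron_ids.tolist() == [0, 2]

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            mw.pearson_matrix(tm(np.ones((2, 100))))


class TestDCCMatrix:
    def test_diagonal_truth_gives_near_zero_dcc(self, rng):
        traces, _ = mw.gen_network_traces(20, np.zeros((20, 20)), frames=4000, seed=0)
        m = mw.dcc_matrix(traces)
        off = np.abs(m.values[np.triu_indices(20, 1)])
        assert off.mean() < 0.05

    def test_chain_separates_direct_from_indirect(self):
        """Non-adjacent chain pair: Pearson ~ 0.64 but partial correlation ~ 0."""
        traces, _ = mw.gen_network_traces(
            3, mw.chain_coupling(3, 0.8), frames=4000, seed=4, mode="markov"
        )
        r = mw.pearson_matrix(traces)
        d = mw.dcc_matrix(traces, shrinkage=0.0)
        assert r.values[0, 2] == pytest.approx(0.64, abs=0.06)
        assert abs(d.values[0, 2]) < 0.1
        assert d.values[0, 1] > 0.4 and d.values[1, 2] > 0.4

    def test_full_shrinkage_gives_zero_matrix(self, rng):
        m = mw.dcc_matrix(tm(rng.normal(0, 1, (5, 200))), shrinkage=1.0)
        assert np.allclose(m.values, 0.0)

    def test_affine_rescaling_invariance(self, rng):
        x = rng.normal(0, 1, (6, 500))
        a = mw.dcc_matrix(tm(x)).values
        scale = rng.uniform(0.5, 3.0, (6, 1))
        offset = rng.normal(0, 2, (6, 1))
        b = mw.dcc_matrix(tm(x * scale + offset)).values
        assert np.allclose(a, b, atol=1e-10)

    def test_underdetermined_without_shrinkage_fails_instructively(self, rng):
        with pytest.raises(ValueError, match="shrinkage"):
            mw.dcc_matrix(tm(rng.normal(0, 1, (30, 20))), shrinkage=0.0)

    def test_symmetry(self, rng):
        m = mw.dcc_matrix(tm(rng.normal(0, 1, (8, 300))))
        assert np.array_equal(m.values, m.values.T)

    def test_edge_ranking_recovers_random_graph(self):
        """|DCC| ranking separates true from absent couplings (AUC >= 0.9)."""
        from sklearn.metrics import roc_auc_score

        aucs = []
        for seed in range(10):
            coupling = mw.random_coupling(50, density=0.1, strength=0.3, seed=seed)
            traces, truth = mw.gen_network_traces(
                50, coupling, frames=4000, seed=seed + 100, condition=True
            )
            d = mw.dcc_matrix(traces)
            iu = np.triu_indices(50, 1)
            aucs.append(
                roc_auc_score(truth.coupling[iu] != 0, np.abs(d.values[iu]))
            )
        assert np.mean(aucs) >= 0.9


class TestStrongPairs:
    def _matrix(self, values):
        n = values.shape[0]
        return PairwiseMatrix(values, "pearson", np.arange(n))

    def test_all_equal_values_select_nothing(self):
        v = np.full((5, 5), 0.3)
        np.fill_diagonal(v, 1.0)
        assert mw.strong_pairs(self._matrix(v)).sum() == 0

    def test_single_outlier_pair_selected(self):
        # 99 off-diagonal zeros and one 1: threshold ~ 0.209 < 1
        n = 15  # 105 upper-triangle pairs; use the first 100
        v = np.zeros((n, n))
        v[0, 1] = v[1, 0] = 1.0
        m = self._matrix(v)
        strong = mw.strong_pairs(m)
        assert strong[0, 1]
        assert strong.sum() == 1

    def test_gaussian_values_select_two_sigma_tail(self, rng):
        n = 150  # 11175 pairs
        iu = np.triu_indices(n, 1)
        v = np.zeros((n, n))
        v[iu] = rng.normal(0, 0.1, len(iu[0]))
        v = v + v.T
        frac = mw.strong_pairs(self._matrix(v)).sum() / len(iu[0])
        assert frac == pytest.approx(0.0228, abs=0.006)

    def test_scope_masks_partition_pairs(self, rng):
        x = rng.normal(0, 1, (10, 300))
        layers = np.array(["L2/3"] * 6 + ["L5a"] * 4)
        m = mw.pearson_matrix(tm(x, layer=layers))
        w23 = mw.scope_pair_mask(m, "within", "L2/3")
        w5 = mw.scope_pair_mask(m, "within", "L5a")
        cross = mw.scope_pair_mask(m, "cross")
        assert w23.sum() == 15 and w5.sum() == 6 and cross.sum() == 24
        assert (w23 | w5 | cross).sum() == 45


class TestPairTableAndProximity:
    def test_proximity_ratio_arithmetic(self):
        pairs = pd.DataFrame(
            {"dcc": [0.2, 0.2, -0.1, 0.1], "distance_um": [50.0, 80.0, 120.0, 150.0]}
        )
        assert mw.proximity_ratio(pairs) == pytest.approx(2.0)

    def test_equal_dcc_gives_unit_ratio(self):
        pairs = pd.DataFrame({"dcc": [0.1] * 6, "distance_um": [30, 60, 90, 110, 150, 190.0]})
        assert mw.proximity_ratio(pairs) == pytest.approx(1.0)

    def test_empty_bin_reported_with_counts(self):
        pairs = pd.DataFrame({"dcc": [0.1, 0.2], "distance_um": [30.0, 60.0]})
        with pytest.raises(ValueError, match="0 pairs"):
            mw.proximity_ratio(pairs)

    def test_distance_decaying_coupling_biases_ratio(self):
        """Distance-dependent coupling gives ratio > 1; uniform coupling ~ 1."""
        ratios_decay, ratios_flat = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            cent = r.uniform(0, 512, (60, 2))
            decay = mw.distance_decay_coupling(cent, 0.8, strength=0.3, seed=seed)
            flat = mw.random_coupling(60, density=0.08, strength=0.3, seed=seed)
            for coupling, sink in ((decay, ratios_decay), (flat, ratios_flat)):
                traces, _ = mw.gen_network_traces(
                    60, coupling, frames=2000, seed=seed + 50, condition=True,
                    centroids=cent, pixel_size_um=0.8,
                )
                pairs = mw.pair_table(traces)
                sink.append(mw.proximity_ratio(pairs))
        assert np.mean(ratios_decay) > 1.2
        assert np.mean(ratios_flat) == pytest.approx(1.0, abs=0.15)

    def test_pair_table_scopes_and_flags(self, rng):
        x = rng.normal(0, 1, (12, 600))
        layers = np.array(["L2/3"] * 6 + ["L5a"] * 6)
        cent = rng.uniform(0, 512, (12, 2))
        pairs = mw.pair_table(tm(x, layer=layers, centroids=cent, pixel_size_um=0.8))
        assert set(pairs["scope"]) == {"within-L2/3", "within-L5a", "cross-layer"}
        assert len(pairs) == 66
        assert (pairs["distance_um"] >= 0).all()
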