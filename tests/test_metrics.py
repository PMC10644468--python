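"""Centrality and predictability indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symptomnet import (
    centrality_similarity,
    centrality_table,
    expected_influence,
    npn_transform,
    predictability,
    residualize,
    sample_items,
    select_network,
    strength,
)
from symptomnet.ggm import SymptomNetwork
from symptomnet.metrics import two_step_expected_influence


def _network(weights, labels=None):
    p = weights.shape[0]
    labels = labels or [f"V{i+1}" for i in range(p)]
    return SymptomNetwork(labels, np.asarray(weights, float), 0.1, 0.5, 0.0, 100)


class TestExpectedInfluence:
    def test_signed_sum(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[0, 2] = w[2, 0] = -0.1
        ei = expected_influence(_network(w))
        assert ei["V1"] == pytest.approx(0.2)

    def test_empty_network_all_zero(self):
        ei = expected_influence(_network(np.zeros((5, 5))))
        assert (ei == 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_strength_dominates_abs_ei(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(-0.3, 0.3, size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = _network(w)
        assert (strength(net) >= expected_influence(net).abs() - 1e-12).all()

    def test_ei_equals_strength_for_nonnegative_weights(self):
        rng = np.random.default_rng(0)
        w = np.abs(rng.uniform(0, 0.3, size=(5, 5)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = _network(w)
        np.testing.assert_allclose(expected_influence(net), strength(net))

    def test_planted_hubs_get_top_ranks(self, reference_model):
        """The three highest-signed-degree nodes in truth top the estimated EI."""
        true_ei = reference_model.partials_true.sum(axis=1)
        expected_top = set(np.array(reference_model.node_labels)[np.argsort(-true_ei)[:3]])
        items = sample_items(reference_model, 5000, seed=21)
        net, _ = select_network(npn_transform(items))
        est_top = set(expected_influence(net).nlargest(3).index)
        assert est_top == expected_top

    def test_two_step_adds_neighbor_influence(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.2
        net = _network(w)
        ei1 = expected_influence(net)
        ei2 = two_step_expected_influence(net)
        assert ei2["V1"] == pytest.approx(ei1["V1"] + 0.5 * ei1["V2"])


class TestPredictability:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        data = npn_transform(rng.standard_normal((5000, 5)))
        net = _network(np.zeros((5, 5)), labels=list(data.variable_labels))
        r2 = predictability(data, net)
        assert (r2.abs() <= 0.02).all()

    def test_exact_linear_combination_flagged(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((200, 2))
        data = npn_transform(np.column_stack([base, base.sum(axis=1)]))
        # overwrite the third transformed column with an exact combination
        data.values[:, 2] = data.values[:, 0] + data.values[:, 1]
        net = _network(np.zeros((3, 3)), labels=list(data.variable_labels))
        r2 = predictability(data, net)
        assert r2.iloc[2] == pytest.approx(1.0, abs=1e-10)
        assert data.variable_labels[2] in r2.attrs["degenerate"]

    def test_chain_graph_matches_population_r2(self, chain_model):
        """Sample nodewise R^2 vs the closed form 1 - 1/(K_ii Sigma_ii)."""
        items = sample_items(chain_model, 5000, seed=22)
        data = npn_transform(items)
        net, _ = select_network(data)
        r2 = predictability(data, net)
        # population R^2 on the unit-variance latent scale: 1 - 1/diag(inv(R))
        Kc = np.linalg.inv(chain_model.latent_correlation)
        pop = 1 - 1 / np.diag(Kc)
        # discretization attenuates somewhat; the mean stays within 0.05
        assert abs(r2.mean() - pop.mean()) < 0.05

    def test_mismatched_labels_rejected(self):
        rng = np.random.default_rng(3)
        data = npn_transform(rng.standard_normal((100, 3)))
        net = _network(np.zeros((3, 3)), labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="match"):
            predictability(data, net)


class TestCentralitySimilarity:
    def test_identical_vectors(self):
        r = centrality_similarity([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.correlation == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = np.arange(7.0)
        r = centrality_similarity(a, a[::-1])
        assert r.correlation == pytest.approx(-1.0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            centrality_similarity([1, 2], [2, 1])

    def test_stable_under_irrelevant_adjustment(self, reference_model):
        rng = np.random.default_rng(23)
        items = sample_items(reference_model, 5000, seed=23)
        data = npn_transform(items)
        net, _ = select_network(data)
        cov = rng.standard_normal(5000)  # independent of everything
        net_adj, _ = select_network(residualize(data, cov))
        r = centrality_similarity(expected_influence(net), expected_influence(net_adj))
        assert r.correlation >= 0.9


class TestCentralityTable:
    def test_assembles_all_indices(self, chain_model):
        items = sample_items(chain_model, 1000, seed=24)
        data = npn_transform(items)
        net, _ = select_network(data)
        ct = centrality_table(data, net)
        assert set(ct.frame.columns) == {"expected_influence", "strength",
                                         "predictability", "ei_z"}
        assert 0 <= ct.mean_predictability < 1
        assert len(ct.top_nodes(3)) == 3
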