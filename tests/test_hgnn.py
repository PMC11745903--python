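"""Hypergraph convolution, gated residuals, EBI, and over-smoothing behavior."""

import numpy as np
import pytest

from hypersyn.data_io import SynergySample
from hypersyn.hgnn import (HgnnLayerParams, gated_residual_layer,
                           hgnn_convolve, init_gate_bias_ebi, refine)
from hypersyn.hypergraph import Hypergraph, build_hypergraph, build_node_index
import scipy.sparse as sp


def make_hypergraph(n_nodes, memberships, weights=None):
    """Hypergraph from explicit hyperedge membership lists."""
    rows, cols = [], []
    for e, members in enumerate(memberships):
        for v in members:
            rows.append(v)
            cols.append(e)
    H = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(n_nodes, len(memberships)))
    w = np.ones(len(memberships)) if weights is None else np.asarray(weights)
    return Hypergraph(H, w, ["triplet"] * len(memberships))


def convolve_loop_oracle(X, hg, W6):
    """Per-node double loop over incident hyperedges and their members."""
    H = hg.incidence.toarray()
    n, m = H.shape
    out = np.zeros_like(X @ W6)
    for v in range(n):
        if hg.node_degrees[v] == 0:
            continue
        acc = np.zeros(X.shape[1])
        for e in range(m):
            if not H[v, e]:
                continue
            edge_sum = sum(X[u] for u in range(n) if H[u, e])
            acc += hg.edge_weights[e] * edge_sum / hg.edge_degrees[e]
        out[v] = (acc / hg.node_degrees[v]) @ W6
    return out


def random_hypergraph(rng, max_nodes=20, max_edges=10):
    n = int(rng.integers(2, max_nodes + 1))
    m = int(rng.integers(1, max_edges + 1))
    members = []
    for _ in range(m):
        size = int(rng.integers(1, min(n, 4) + 1))
        members.append(list(rng.choice(n, size=size, replace=False)))
    weights = rng.uniform(0.1, 2.0, size=m)
    return make_hypergraph(n, members, weights)


class TestConvolve:
    def test_hand_worked_three_node_example(self):
        hg = make_hypergraph(3, [[0, 1, 2], [0, 1]])
        X = np.array([[1.0], [2.0], [3.0]])
        out = hgnn_convolve(X, hg, np.array([[1.0]]), activation="identity")
        assert np.array_equal(out, [[1.75], [1.75], [2.0]])

    def test_single_node_single_edge_identity(self):
        hg = make_hypergraph(1, [[0]])
        X = np.array([[2.5, -1.0]])
        out = hgnn_convolve(X, hg, np.eye(2), activation="identity")
        assert np.allclose(out, X)

    def test_constant_features_are_fixed_points(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            hg = random_hypergraph(rng)
            c = float(rng.uniform(-3, 3))
            X = np.full((hg.n_nodes, 2), c)
            X[hg.node_degrees == 0] = 0.0  # zero-degree rows stay zero
            out = hgnn_convolve(X, hg, np.eye(2), activation="identity")
            assert np.abs(out - X).max() < 1e-10

    def test_matches_loop_oracle_on_100_random_hypergraphs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            hg = random_hypergraph(rng)
            X = rng.standard_normal((hg.n_nodes, 3))
            W6 = rng.standard_normal((3, 2))
            got = hgnn_convolve(X, hg, W6, activation="identity")
            want = convolve_loop_oracle(X, hg, W6)
            worst = max(worst, np.abs(got - want).max())
        assert worst < 1e-6

    def test_dimension_mismatch_reported(self):
        hg = make_hypergraph(2, [[0, 1]])
        with pytest.raises(ValueError, match="W6"):
            hgnn_convolve(np.ones((2, 3)), hg, np.eye(2))
        with pytest.raises(ValueError, match="nodes"):
            hgnn_convolve(np.ones((5, 3)), hg, np.eye(3))


def random_layer(rng, dim, bias=None, gate_mode="literal"):
    return HgnnLayerParams(
        conv_weight=rng.standard_normal((dim, dim)) / np.sqrt(dim),
        gate_weight=rng.standard_normal((dim, dim)) / np.sqrt(dim),
        gate_bias=np.zeros(dim) if bias is None else np.full(dim, float(bias)),
        gate_mode=gate_mode)


class TestGatedResidual:
    def test_saturated_off_gate_is_identity(self):
        rng = np.random.default_rng(1)
        hg = random_hypergraph(rng, 6, 4)
        X = rng.standard_normal((hg.n_nodes, 3))
        p = random_layer(rng, 3, bias=-50.0)
        p.gate_weight[:] = 0.0
        assert np.abs(gated_residual_layer(X, hg, p) - X).max() < 1e-12

    def test_saturated_on_gate_doubles_input_in_literal_mode(self):
        rng = np.random.default_rng(2)
        hg = random_hypergraph(rng, 6, 4)
        X = rng.standard_normal((hg.n_nodes, 3))
        p = random_layer(rng, 3, bias=50.0)
        p.gate_weight[:] = 0.0
        assert np.abs(gated_residual_layer(X, hg, p) - 2 * X).max() < 1e-12

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        hg = make_hypergraph(4, [[0, 1, 2], [2, 3], [0, 3]],
                             weights=[1.0, 0.5, 2.0])
        X = rng.standard_normal((4, 2))
        p = random_layer(rng, 2)
        C = np.maximum(convolve_loop_oracle(X, hg, p.conv_weight), 0.0)
        gate = 1.0 / (1.0 + np.exp(-(C @ p.gate_weight.T + p.gate_bias)))
        want = X + gate * X
        got = gated_residual_layer(X, hg, p)
        assert np.abs(got - want).max() < 1e-8

    def test_conv_mode_uses_convolved_carrier(self):
        rng = np.random.default_rng(4)
        hg = make_hypergraph(3, [[0, 1, 2]])
        X = rng.standard_normal((3, 2))
        p = random_layer(rng, 2, bias=50.0, gate_mode="conv")
        p.gate_weight[:] = 0.0
        C = np.maximum(convolve_loop_oracle(X, hg, p.conv_weight), 0.0)
        assert np.allclose(gated_residual_layer(X, hg, p), X + C, atol=1e-10)

    def test_gate_monotone_in_bias(self):
        rng = np.random.default_rng(5)
        hg = random_hypergraph(rng, 8, 5)
        X = rng.standard_normal((hg.n_nodes, 3))
        p_lo = random_layer(rng, 3, bias=-1.0)
        p_hi = HgnnLayerParams(p_lo.conv_weight, p_lo.gate_weight,
                               p_lo.gate_bias + 2.0)
        lo = gated_residual_layer(np.abs(X), hg, p_lo) - np.abs(X)
        hi = gated_residual_layer(np.abs(X), hg, p_hi) - np.abs(X)
        # with positive carrier X, larger bias means larger gated increment
        assert (hi - lo).min() > -1e-12


class TestEbi:
    def test_default_bias_value_and_gate_level(self):
        rng = np.random.default_rng(6)
        p = random_layer(rng, 4, bias=0.0)
        p2 = init_gate_bias_ebi(p)
        assert np.all(p2.gate_bias == -5.0)
        assert 1.0 / (1.0 + np.exp(5.0)) == pytest.approx(0.0067, abs=1e-4)

    def test_zero_bias_disables_ebi(self):
        rng = np.random.default_rng(7)
        p = init_gate_bias_ebi(random_layer(rng, 4), b0=0.0)
        assert np.all(p.gate_bias == 0.0)

    def test_layer_is_near_identity_after_init(self):
        rng = np.random.default_rng(8)
        hg = random_hypergraph(rng, 10, 6)
        X = rng.standard_normal((hg.n_nodes, 4))
        p = init_gate_bias_ebi(random_layer(rng, 4))
        out = gated_residual_layer(X, hg, p)
        rel = np.abs(out - X).max() / np.abs(X).max()
        assert rel < 0.01


class TestRefine:
    def test_empty_stack_is_identity(self):
        rng = np.random.default_rng(9)
        hg = random_hypergraph(rng, 5, 3)
        X = rng.standard_normal((hg.n_nodes, 3))
        assert np.array_equal(refine(X, hg, [], mode="gated"), X)

    def test_one_layer_equals_single_layer_call(self):
        rng = np.random.default_rng(10)
        hg = random_hypergraph(rng, 6, 4)
        X = rng.standard_normal((hg.n_nodes, 3))
        p = random_layer(rng, 3, bias=-1.0)
        assert np.array_equal(refine(X, hg, [p], mode="gated"),
                              gated_residual_layer(X, hg, p))

    def test_three_ebi_layers_stay_near_identity(self):
        rng = np.random.default_rng(11)
        hg = random_hypergraph(rng, 10, 6)
        X = rng.standard_normal((hg.n_nodes, 4))
        layers = [init_gate_bias_ebi(random_layer(rng, 4)) for _ in range(3)]
        out = refine(X, hg, layers, mode="gated")
        rel = np.abs(out - X).max() / np.abs(X).max()
        assert rel < 0.03

    def test_zero_interaction_weight_equals_dropping_pairs(self):
        from hypersyn.data_io import IndicationPair
        idx = build_node_index(["d1", "d2", "d3"], ["c1"], ["s1"])
        samples = [SynergySample("d1", "d2", "c1", 40.0, 1),
                   SynergySample("d2", "d3", "c1", 44.0, 1)]
        pairs = [IndicationPair("d1", "s1")]
        hg_zero = build_hypergraph(samples, pairs, idx, interaction_weight=0.0)
        hg_none = build_hypergraph(samples, [], idx, interaction_weight=0.0)
        rng = np.random.default_rng(12)
        X = rng.standard_normal((idx.n_nodes, 3))
        W6 = rng.standard_normal((3, 3))
        a = hgnn_convolve(X, hg_zero, W6, activation="identity")
        b = hgnn_convolve(X, hg_none, W6, activation="identity")
        assert np.abs(a - b).max() < 1e-12

    def test_over_smoothing_contrast(self):
        """Deep no-residual stacks collapse node variance; gated EBI retains it."""
        rng = np.random.default_rng(13)
        # connected toy hypergraph over 8 nodes
        hg = make_hypergraph(8, [[0, 1, 2], [2, 3, 4], [4, 5, 6], [6, 7, 0],
                                 [1, 3, 5], [5, 7, 2]])
        X = rng.standard_normal((8, 4))
        var0 = X.var(axis=0).sum()
        plain = [HgnnLayerParams(np.eye(4), np.zeros((4, 4)), np.zeros(4))
                 for _ in range(8)]
        collapsed = refine(X, hg, plain, mode="no_residual")
        var_plain = collapsed.var(axis=0).sum()
        gated = [init_gate_bias_ebi(random_layer(rng, 4)) for _ in range(8)]
        kept = refine(X, hg, gated, mode="gated")
        var_gated = kept.var(axis=0).sum()
        assert var_plain <= var0 / 10.0
        assert var_gated >= 0.5 * var0
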