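"""Layer forwards against dense-matrix and double-loop oracles."""

import numpy as np
import pytest

from conftest import random_graph
from deepnc.autodiff import Tensor
from deepnc.layers import (AggregationError, GcnLayerParams, GenLayerParams,
                           HypergraphLayerParams, gcn_forward, gen_conv_forward,
                           gen_message, gen_update, global_add_pool,
                           global_max_pool, hypergraph_attention,
                           hypergraph_conv_forward, powermean_aggregate,
                           softmax_aggregate)
from deepnc.mol_graph import HyperIncidence, build_hyperedges, smiles_to_graph


# ----------------------------------------------------------------------
# oracles


def dense_gcn(x, edge_index, theta, self_loops=True):
    n = len(x)
    a = np.zeros((n, n))
    for i, j in edge_index:
        a[j, i] = 1.0  # arc i -> j contributes A_ji
    if self_loops:
        a = a + np.eye(n)
    deg = a.sum(axis=1)
    dinv = np.where(deg > 0, deg, 1.0) ** -0.5 * (deg > 0)
    return np.diag(dinv) @ a @ np.diag(dinv) @ x @ theta


def gen_oracle(x, edge_index, params):
    """Per-node brute-force message passing loop."""
    w1, b1, w2, b2 = (t.data for t in params.mlp_weights)
    s = float(params.s_scale.data)

    def mlp(v):
        return np.maximum(v @ w1 + b1, 0.0) @ w2 + b2

    out = np.zeros((len(x), w2.shape[1]))
    for v in range(len(x)):
        nbrs = [i for i, j in edge_index if j == v]
        if nbrs:
            m = np.maximum(x[nbrs], 0.0) + params.epsilon
            if params.agg_mode == "softmax":
                e = np.exp(params.beta * (m - m.max(axis=0)))
                agg = (e / e.sum(axis=0) * m).sum(axis=0)
            else:
                agg = (np.mean(m ** params.p_power, axis=0)
                       ) ** (1.0 / params.p_power)
        else:
            agg = np.zeros(x.shape[1])
        hn = np.linalg.norm(x[v])
        mn = np.linalg.norm(agg)
        arg = x[v] + (s * hn * agg / mn if mn > 0 else 0.0)
        out[v] = mlp(arg)
    return out


def dense_hypergraph(x, h, w, theta):
    d = h @ w
    b = h.sum(axis=0)
    dinv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    binv = np.where(b > 0, 1.0 / np.where(b > 0, b, 1.0), 0.0)
    return (np.diag(dinv) @ h @ np.diag(w) @ np.diag(binv) @ h.T @ x @ theta)


def make_gen_params(rng, din, dout, **kw):
    w1 = Tensor(rng.normal(size=(din, dout)) * 0.5, requires_grad=True)
    b1 = Tensor(rng.normal(size=dout) * 0.1, requires_grad=True)
    w2 = Tensor(rng.normal(size=(dout, dout)) * 0.5, requires_grad=True)
    b2 = Tensor(rng.normal(size=dout) * 0.1, requires_grad=True)
    return GenLayerParams(mlp_weights=(w1, b1, w2, b2),
                          s_scale=Tensor(np.array(1.0), requires_grad=True),
                          **kw)


# ----------------------------------------------------------------------
# plain graph convolution


def test_gcn_single_node_identity():
    p = GcnLayerParams(theta=Tensor(np.eye(3)))
    x = np.array([[1.0, -2.0, 0.5]])
    out = gcn_forward(Tensor(x), np.zeros((0, 2), dtype=int), p)
    assert np.allclose(out.data, x)


def test_gcn_two_connected_nodes_hand_value():
    p = GcnLayerParams(theta=Tensor(np.array([[1.0]])))
    out = gcn_forward(Tensor([[1.0], [1.0]]),
                      np.array([[0, 1], [1, 0]]), p)
    assert np.allclose(out.data, [[1.0], [1.0]])


def test_gcn_matches_dense_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(2, 13))
        x, edges = random_graph(rng, n)
        theta = rng.normal(size=(5, 4))
        p = GcnLayerParams(theta=Tensor(theta))
        out = gcn_forward(Tensor(x), edges, p)
        assert np.allclose(out.data, dense_gcn(x, edges, theta), atol=1e-6)


def test_gcn_shape_mismatch():
    p = GcnLayerParams(theta=Tensor(np.eye(4)))
    with pytest.raises(ValueError, match="theta"):
        gcn_forward(Tensor(np.ones((2, 3))), np.zeros((0, 2), dtype=int), p)


# ----------------------------------------------------------------------
# generalized aggregation


def test_gen_message_values_and_positivity():
    out = gen_message(Tensor([[-1.0, 2.0]]), epsilon=1e-7)
    assert np.allclose(out.data, [[1e-7, 2.0 + 1e-7]])
    assert np.all(gen_message(Tensor([[0.0, 0.0]])).data > 0)
    out = gen_message(Tensor([[1.0]]), Tensor([[1.0]]), epsilon=1e-7)
    assert np.allclose(out.data, [[2.0 + 1e-7]])


def test_softmax_aggregation_mean_max_limits():
    msgs = Tensor([[1.0], [3.0]])
    assert np.allclose(softmax_aggregate(Tensor([[2.0, 5.0]]), 1.0).data,
                       [2.0, 5.0])  # singleton unchanged
    assert np.allclose(softmax_aggregate(msgs, 0.0).data, [2.0])
    assert np.allclose(softmax_aggregate(msgs, 100.0).data, [3.0], atol=1e-6)


def test_softmax_aggregation_bounded_by_message_range(rng):
    m = rng.normal(size=(6, 4))
    out = softmax_aggregate(Tensor(m), 2.5).data
    assert np.all(out >= m.min(axis=0) - 1e-12)
    assert np.all(out <= m.max(axis=0) + 1e-12)


def test_powermean_aggregation_values():
    msgs = Tensor([[1.0], [3.0]])
    assert np.allclose(powermean_aggregate(msgs, 1.0).data, [2.0])
    assert np.allclose(powermean_aggregate(msgs, 2.0).data, [np.sqrt(5.0)])
    # large p approaches the max: exact value ((1 + 3^64)/2)^(1/64)
    exact = ((1.0 + 3.0 ** 64) / 2.0) ** (1.0 / 64.0)
    assert np.allclose(powermean_aggregate(msgs, 64.0).data, [exact])
    assert abs(exact - 3.0) < 0.05


def test_aggregation_error_cases():
    empty = Tensor(np.zeros((0, 2)))
    with pytest.raises(AggregationError):
        softmax_aggregate(empty, 1.0)
    with pytest.raises(AggregationError):
        powermean_aggregate(empty, 1.0)
    with pytest.raises(AggregationError):
        powermean_aggregate(Tensor([[-1.0]]), 0.5)


def test_gen_update_s_zero_is_plain_mlp(rng):
    p = make_gen_params(rng, 3, 3)
    p.s_scale = Tensor(np.array(0.0))
    h = rng.normal(size=(4, 3))
    m = rng.normal(size=(4, 3))
    w1, b1, w2, b2 = (t.data for t in p.mlp_weights)
    expected = np.maximum(h @ w1 + b1, 0) @ w2 + b2
    assert np.allclose(gen_update(Tensor(h), Tensor(m), p).data, expected)


def test_gen_update_hand_case_identity_mlp():
    eye = Tensor(np.eye(2))
    zero = Tensor(np.zeros(2))
    p = GenLayerParams(mlp_weights=(eye, zero, eye, zero),
                       s_scale=Tensor(np.array(1.0)))
    h = np.array([[3.0, 4.0]])          # norm 5
    m = np.array([[0.0, 2.0]])          # normalized -> [0, 1]
    out = gen_update(Tensor(h), Tensor(m), p)
    assert np.allclose(out.data, [[3.0, 9.0]], atol=1e-6)


def test_gen_update_zero_message_convention(rng):
    p = make_gen_params(rng, 3, 3)
    h = np.abs(rng.normal(size=(2, 3)))
    out = gen_update(Tensor(h), Tensor(np.zeros((2, 3))), p)
    w1, b1, w2, b2 = (t.data for t in p.mlp_weights)
    assert np.allclose(out.data, np.maximum(h @ w1 + b1, 0) @ w2 + b2)


@pytest.mark.parametrize("agg_mode,kw", [
    ("softmax", {"beta": 1.0}),
    ("softmax", {"beta": 7.5}),
    ("powermean", {"p_power": 1.0}),
    ("powermean", {"p_power": 3.0}),
])
def test_gen_conv_matches_double_loop_oracle(agg_mode, kw, rng):
    for _ in range(10):
        n = int(rng.integers(2, 13))
        x, edges = random_graph(rng, n)
        p = make_gen_params(rng, 5, 6, agg_mode=agg_mode, **kw)
        out = gen_conv_forward(Tensor(x), edges, p)
        assert np.allclose(out.data, gen_oracle(x, edges, p), atol=1e-6)


def test_gen_conv_edgeless_graph_is_rowwise_mlp(rng):
    x = rng.normal(size=(3, 4))
    p = make_gen_params(rng, 4, 4)
    out = gen_conv_forward(Tensor(x), np.zeros((0, 2), dtype=int), p)
    w1, b1, w2, b2 = (t.data for t in p.mlp_weights)
    assert np.allclose(out.data, np.maximum(x @ w1 + b1, 0) @ w2 + b2)


def test_gen_conv_permutation_equivariant(rng):
    x, edges = random_graph(rng, 8)
    p = make_gen_params(rng, 5, 5)
    perm = rng.permutation(8)
    out = gen_conv_forward(Tensor(x), edges, p).data
    out_p = gen_conv_forward(Tensor(x[np.argsort(perm)]),
                             perm[edges] if len(edges) else edges, p).data
    assert np.allclose(out_p, out[np.argsort(perm)], atol=1e-10)


# ----------------------------------------------------------------------
# hypergraph convolution


def _att_params(rng, din, dout, datt=4):
    return HypergraphLayerParams(
        p_weight=Tensor(rng.normal(size=(din, dout))), use_attention=True,
        attention_proj=Tensor(rng.normal(size=(din, datt))),
        attention_score=Tensor(rng.normal(size=(2 * datt, 1))))


def test_hypergraph_single_node_identity():
    inc = HyperIncidence(1, 1, np.array([[0, 0]]), np.ones(1))
    p = HypergraphLayerParams(p_weight=Tensor(np.eye(2)))
    x = np.array([[1.5, -0.5]])
    assert np.allclose(hypergraph_conv_forward(Tensor(x), inc, p).data, x)


def test_hypergraph_shared_edge_hand_value():
    inc = HyperIncidence(2, 1, np.array([[0, 0], [1, 0]]), np.ones(1))
    p = HypergraphLayerParams(p_weight=Tensor(np.array([[1.0]])))
    out = hypergraph_conv_forward(Tensor([[1.0], [3.0]]), inc, p)
    assert np.allclose(out.data, [[2.0], [2.0]])


def test_hypergraph_matches_dense_oracle_on_molecules(rng):
    for smiles in ["CCO", "c1ccccc1", "CC(C)Cc1ccc(C)cc1", "NCC(=O)O"]:
        g = smiles_to_graph(smiles)
        inc = build_hyperedges(g, "bond")
        inc.weights = rng.uniform(0.5, 2.0, size=inc.num_hyperedges)
        x = rng.normal(size=(g.num_atoms, 5))
        theta = rng.normal(size=(5, 3))
        p = HypergraphLayerParams(p_weight=Tensor(theta))
        out = hypergraph_conv_forward(Tensor(x), inc, p)
        expected = dense_hypergraph(x, inc.dense(), inc.weights, theta)
        assert np.allclose(out.data, expected, atol=1e-6)


def test_hypergraph_zero_degree_row_is_zero(rng):
    # node 2 belongs to no hyperedge
    inc = HyperIncidence(3, 1, np.array([[0, 0], [1, 0]]), np.ones(1))
    p = HypergraphLayerParams(p_weight=Tensor(rng.normal(size=(2, 2))))
    out = hypergraph_conv_forward(Tensor(rng.normal(size=(3, 2))), inc, p)
    assert np.allclose(out.data[2], 0.0)


def test_attention_rows_sum_to_one_and_uniform_case(rng):
    g = smiles_to_graph("c1ccccc1")
    inc = build_hyperedges(g, "bond")
    p = _att_params(rng, 5, 3)
    x = rng.normal(size=(6, 5))
    vals = hypergraph_attention(Tensor(x), inc, p).data.ravel()
    sums = np.zeros(6)
    np.add.at(sums, inc.incidence[:, 0], vals)
    assert np.allclose(sums, 1.0)
    # equal scores (zero scoring vector) -> 1 / (incident count) each
    p.attention_score = Tensor(np.zeros((8, 1)))
    vals = hypergraph_attention(Tensor(x), inc, p).data.ravel()
    assert np.allclose(vals, 0.5)  # every benzene atom sits in 2 bonds


def test_attention_hand_computed_two_scores(rng):
    # node 0 sits in two 2-node hyperedges; softmax of its two scores
    inc = HyperIncidence(2, 2, np.array([[0, 0], [1, 0], [0, 1], [1, 1]]),
                         np.ones(2))
    p = _att_params(rng, 3, 3, datt=2)
    x = rng.normal(size=(2, 3))
    proj = x @ p.attention_proj.data
    edge_rep = np.stack([proj.mean(axis=0), proj.mean(axis=0)])
    scores = []
    for node, edge in inc.incidence:
        z = np.concatenate([proj[node], edge_rep[edge]]) @ p.attention_score.data.ravel()
        scores.append(z if z > 0 else 0.2 * z)
    scores = np.array(scores)
    expected0 = np.exp(scores[[0, 2]]) / np.exp(scores[[0, 2]]).sum()
    vals = hypergraph_attention(Tensor(x), inc, p).data.ravel()
    assert np.allclose(vals[[0, 2]], expected0, atol=1e-10)


def test_attention_changes_convolution_but_keeps_shape(rng):
    g = smiles_to_graph("CCOC")
    inc = build_hyperedges(g, "bond")
    x = rng.normal(size=(g.num_atoms, 4))
    plain = HypergraphLayerParams(p_weight=Tensor(np.eye(4)))
    att = _att_params(rng, 4, 4)
    att.p_weight = Tensor(np.eye(4))
    a = hypergraph_conv_forward(Tensor(x), inc, plain).data
    b = hypergraph_conv_forward(Tensor(x), inc, att).data
    assert a.shape == b.shape
    assert not np.allclose(a, b)


def test_attention_params_required():
    with pytest.raises(ValueError):
        HypergraphLayerParams(p_weight=Tensor(np.eye(2)), use_attention=True)


# ----------------------------------------------------------------------
# pooling


def test_add_pool_single_graph(rng):
    x = rng.normal(size=(5, 3))
    out = global_add_pool(Tensor(x), np.zeros(5, dtype=int))
    assert np.allclose(out.data, x.sum(axis=0, keepdims=True))


def test_pools_are_batch_independent(rng):
    xa, xb = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
    batch = np.array([0] * 3 + [1] * 5)
    stacked = np.vstack([xa, xb])
    for pool, red in [(global_add_pool, np.sum), (global_max_pool, np.max)]:
        both = pool(Tensor(stacked), batch).data
        assert np.allclose(both[0], red(xa, axis=0))
        assert np.allclose(both[1], red(xb, axis=0))


def test_max_pool_idempotent_under_duplicate_max_row(rng):
    x = rng.normal(size=(4, 3))
    x2 = np.vstack([x, x.max(axis=0)])
    a = global_max_pool(Tensor(x), np.zeros(4, dtype=int)).data
    b = global_max_pool(Tensor(x2), np.zeros(5, dtype=int)).data
    assert np.allclose(a, b)


def test_pooling_permutation_invariant(rng):
    x = rng.normal(size=(6, 3))
    perm = rng.permutation(6)
    for pool in (global_add_pool, global_max_pool):
        a = pool(Tensor(x), np.zeros(6, dtype=int)).data
        b = pool(Tensor(x[perm]), np.zeros(6, dtype=int)).data
        assert np.allclose(a, b)
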