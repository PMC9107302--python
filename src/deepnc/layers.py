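"""Graph layer forwards: plain, generalized-aggregation, and hypergraph
convolutions, plus the two global pooling reductions.

All operators are pure functions of a node-feature :class:`~deepnc.autodiff.Tensor`
and sparse structure arrays, written so that each forward is numerically
equal to its textbook dense-matrix formula:

* ``gcn_forward``       —  D̂^{-1/2} Â D̂^{-1/2} X Θ  with  Â = A + I
* ``gen_conv_forward``  —  per-node message passing
                           MLP(x_i + s·‖x_i‖·AGG/‖AGG‖) with
                           AGG ∈ {SoftMax_β, PowerMean_p} over
                           messages ReLU(x_j) + ε
* ``hypergraph_conv_forward`` — D^{-1} H W B^{-1} Hᵀ X Θ (row-normalized;
                           symmetric D^{-1/2}··D^{-1/2} behind a flag),
                           optionally with an attention-reweighted
                           real-valued incidence H̃

Edges are directed arcs (i, j) = "message flows from i into j"; an
undirected bond contributes both arcs.  Isolated nodes receive a zero
aggregated message, and hypergraph rows with zero degree produce zero
output, so every forward is a total function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_max, segment_softmax, segment_sum

__all__ = [
    "GcnLayerParams", "GenLayerParams", "HypergraphLayerParams",
    "gcn_forward", "gen_message", "softmax_aggregate", "powermean_aggregate",
    "gen_update", "gen_conv_forward", "hypergraph_attention",
    "hypergraph_conv_forward", "global_add_pool", "global_max_pool",
]


class AggregationError(ValueError):
    pass


# ----------------------------------------------------------------------
# parameter containers


@dataclass
class GcnLayerParams:
    theta: Tensor                  # [in_dim, out_dim]
    use_self_loops: bool = True


@dataclass
class GenLayerParams:
    """Parameters of one generalized-aggregation convolution.

    ``mlp_weights`` is the update perceptron (W1, b1, W2, b2); ``beta``
    is the fixed inverse temperature of SoftMax aggregation; ``p_power``
    the PowerMean exponent; ``epsilon`` the positive constant added to
    every message; ``s_scale`` the learnable message-norm scaling,
    initialized to 1.
    """

    mlp_weights: tuple             # (W1, b1, W2, b2) Tensors
    s_scale: Tensor                # scalar Tensor, learnable
    beta: float = 1.0
    p_power: float = 1.0
    epsilon: float = 1e-7
    agg_mode: str = "softmax"      # softmax | powermean


@dataclass
class HypergraphLayerParams:
    p_weight: Tensor               # [in_dim, out_dim]
    use_attention: bool = False
    attention_proj: Tensor | None = None   # [in_dim, att_dim]
    attention_score: Tensor | None = None  # [2*att_dim, 1]
    leaky_slope: float = 0.2
    symmetric: bool = False        # D^{-1/2}..D^{-1/2} instead of D^{-1}

    def __post_init__(self):
        has_att = self.attention_proj is not None and self.attention_score is not None
        if self.use_attention and not has_att:
            raise ValueError("attention weights required when use_attention")


# ----------------------------------------------------------------------
# plain graph convolution


def gcn_forward(X: Tensor, edge_index: np.ndarray,
                params: GcnLayerParams) -> Tensor:
    """Symmetric-normalized graph convolution of Kipf–Welling type.

    Computed sparsely over arcs but numerically equal to the dense
    formula D̂^{-1/2} Â D̂^{-1/2} X Θ.  The caller applies any activation.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    n = X.shape[0]
    if X.shape[1] != params.theta.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != theta rows {params.theta.shape[0]}")
    edge_index = np.asarray(edge_index, dtype=np.intp).reshape(-1, 2)
    deg = np.bincount(edge_index[:, 1], minlength=n).astype(np.float64)
    if params.use_self_loops:
        deg += 1.0
    dinv = np.where(deg > 0, deg, 1.0) ** -0.5 * (deg > 0)
    if len(edge_index):
        src, dst = edge_index[:, 0], edge_index[:, 1]
        coef = dinv[src] * dinv[dst]
        msgs = X.take(src) * Tensor(coef[:, None])
        agg = segment_sum(msgs, dst, n)
    else:
        agg = Tensor(np.zeros_like(X.data))
    if params.use_self_loops:
        agg = agg + X * Tensor((dinv ** 2)[:, None])
    return agg @ params.theta


# ----------------------------------------------------------------------
# generalized aggregation convolution


def gen_message(x_j: Tensor, e_ij: Tensor | None = None,
                epsilon: float = 1e-7) -> Tensor:
    """Message ReLU(x_j + e_ij) + ε; strictly positive by construction."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x_j = x_j if isinstance(x_j, Tensor) else Tensor(x_j)
    arg = x_j + e_ij if e_ij is not None else x_j
    return arg.relu() + epsilon


def softmax_aggregate(messages: Tensor, beta: float = 1.0) -> Tensor:
    """SoftMax aggregation: Σ_u softmax_u(β·m_u) ⊙ m_u per channel.

    β → 0 recovers the mean of the messages and β → ∞ their channel-wise
    maximum (the generalized mean–max family).
    """
    messages = messages if isinstance(messages, Tensor) else Tensor(messages)
    if messages.shape[0] == 0:
        raise AggregationError("softmax aggregation of zero messages")
    if beta == 0:
        return messages.sum(axis=0) / messages.shape[0]  # uniform weights: the mean
    shift = messages.data.max(axis=0, keepdims=True)  # detached, cancels
    z = ((messages - Tensor(shift)) * beta).exp()
    w = z / z.sum(axis=0, keepdims=True)
    return (w * messages).sum(axis=0)


def powermean_aggregate(messages: Tensor, p_power: float = 1.0) -> Tensor:
    """PowerMean aggregation ((1/k) Σ m^p)^{1/p} per channel."""
    messages = messages if isinstance(messages, Tensor) else Tensor(messages)
    if messages.shape[0] == 0:
        raise AggregationError("powermean aggregation of zero messages")
    if p_power == 0:
        raise ValueError("p_power must be non-zero")
    if p_power != int(p_power) and np.any(messages.data <= 0):
        raise AggregationError(
            "non-positive messages with fractional exponent")
    return (messages ** p_power).mean(axis=0) ** (1.0 / p_power)


def _row_normalized(m: Tensor) -> Tensor:
    """m_v / ‖m_v‖₂ row-wise; zero rows stay zero."""
    norm = (m * m).sum(axis=1, keepdims=True) ** 0.5
    nonzero = (norm.data > 0).astype(np.float64)
    safe = norm + Tensor(1.0 - nonzero)
    return m / safe * Tensor(nonzero)


def _mlp(x: Tensor, weights: tuple) -> Tensor:
    w1, b1, w2, b2 = weights
    return (x @ w1 + b1).relu() @ w2 + b2


def gen_update(h_v: Tensor, m_v: Tensor, params: GenLayerParams) -> Tensor:
    """Message-normalized update MLP(h + s·‖h‖₂ · m/‖m‖₂) per node."""
    h_v = h_v if isinstance(h_v, Tensor) else Tensor(h_v)
    m_v = m_v if isinstance(m_v, Tensor) else Tensor(m_v)
    hnorm = (h_v * h_v).sum(axis=1, keepdims=True) ** 0.5
    arg = h_v + params.s_scale * hnorm * _row_normalized(m_v)
    return _mlp(arg, params.mlp_weights)


def gen_conv_forward(X: Tensor, edge_index: np.ndarray,
                     params: GenLayerParams) -> Tensor:
    """Full message → aggregate → update pipeline for every node.

    Messages flow along arcs (source → target); nodes without incoming
    arcs get a zero aggregated message, so a bond-free molecule reduces
    to MLP(X) row-wise.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    n = X.shape[0]
    edge_index = np.asarray(edge_index, dtype=np.intp).reshape(-1, 2)
    if len(edge_index) == 0:
        agg = Tensor(np.zeros_like(X.data))
        return gen_update(X, agg, params)
    src, dst = edge_index[:, 0], edge_index[:, 1]
    m = gen_message(X.take(src), epsilon=params.epsilon)
    if params.agg_mode == "softmax":
        w = segment_softmax(m * params.beta, dst, n)
        agg = segment_sum(w * m, dst, n)
    elif params.agg_mode == "powermean":
        p = params.p_power
        if p == 0:
            raise ValueError("p_power must be non-zero")
        counts = np.bincount(dst, minlength=n).astype(np.float64)
        safe = np.where(counts > 0, counts, 1.0)
        agg = (segment_sum(m ** p, dst, n) / Tensor(safe[:, None])) ** (1.0 / p)
    else:
        raise ValueError(f"unknown agg_mode {params.agg_mode!r}")
    return gen_update(X, agg, params)


# ----------------------------------------------------------------------
# hypergraph convolution


def hypergraph_attention(X: Tensor, inc, params: HypergraphLayerParams) -> Tensor:
    """Attention values of the reweighted incidence H̃.

    Returns one positive value per (node, hyperedge) pair of
    ``inc.incidence``, in pair order.  A hyperedge is represented by the
    mean of its incident nodes' projected features; each pair is scored
    by a LeakyReLU of a learned linear form on the concatenated node and
    hyperedge representations, and scores are softmax-normalized over
    each node's incident hyperedges (so every non-isolated node's row of
    H̃ sums to 1; structural zeros of H stay zero).
    """
    if not params.use_attention:
        raise ValueError("attention requested on a non-attention layer")
    X = X if isinstance(X, Tensor) else Tensor(X)
    node_ids = inc.incidence[:, 0]
    edge_ids = inc.incidence[:, 1]
    proj = X @ params.attention_proj                      # [n, d]
    sizes = np.bincount(edge_ids, minlength=inc.num_hyperedges).astype(np.float64)
    sizes = np.where(sizes > 0, sizes, 1.0)
    edge_rep = segment_sum(proj.take(node_ids), edge_ids,
                           inc.num_hyperedges) / Tensor(sizes[:, None])
    pair_feat = concat([proj.take(node_ids), edge_rep.take(edge_ids)], axis=1)
    scores = (pair_feat @ params.attention_score).leaky_relu(params.leaky_slope)
    return segment_softmax(scores, node_ids, X.shape[0])  # [nnz, 1]


def hypergraph_conv_forward(X: Tensor, inc,
                            params: HypergraphLayerParams) -> Tensor:
    """Hypergraph convolution D^{-1} H W B^{-1} Hᵀ X Θ.

    D_ii = Σ_e W_ee H_ie is the node degree under hyperedge weights and
    B_ee = Σ_i H_ie the hyperedge size.  With attention enabled H is
    replaced by the real-valued H̃ and D, B are recomputed from it.
    Nodes with zero degree (no incident hyperedge) output a zero row.
    The computation runs sparsely over incidence pairs but equals the
    dense matrix product.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    n, m = inc.num_nodes, inc.num_hyperedges
    if X.shape[1] != params.p_weight.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != weight rows {params.p_weight.shape[0]}")
    if m == 0 or len(inc.incidence) == 0:
        return Tensor(np.zeros((n, params.p_weight.shape[1])))
    node_ids = inc.incidence[:, 0]
    edge_ids = inc.incidence[:, 1]
    w_edge = Tensor(np.asarray(inc.weights, dtype=np.float64)[:, None])  # [m,1]

    if params.use_attention:
        h_pair = hypergraph_attention(X, inc, params)     # [nnz, 1]
    else:
        h_pair = Tensor(np.ones((len(node_ids), 1)))

    # degree and hyperedge-size diagonals, recomputed from (possibly
    # attention-valued) incidence entries
    d_node = segment_sum(h_pair * w_edge.take(edge_ids), node_ids, n)  # [n,1]
    b_edge = segment_sum(h_pair, edge_ids, m)                          # [m,1]

    x_in = X
    if params.symmetric:
        d_half = _safe_power(d_node, -0.5)
        x_in = X * d_half
    y_edge = segment_sum(h_pair * x_in.take(node_ids), edge_ids, m)    # Hᵀ X
    y_edge = y_edge * w_edge * _safe_power(b_edge, -1.0)               # W B⁻¹ Hᵀ X
    z = segment_sum(h_pair * y_edge.take(edge_ids), node_ids, n)       # H · ...
    if params.symmetric:
        z = z * d_half
    else:
        z = z * _safe_power(d_node, -1.0)
    return z @ params.p_weight


def _safe_power(t: Tensor, expo: float) -> Tensor:
    """t^expo with 0 mapped to 0 (zero-degree convention)."""
    nonzero = (t.data > 0).astype(np.float64)
    safe = t + Tensor(1.0 - nonzero)
    return safe ** expo * Tensor(nonzero)


# ----------------------------------------------------------------------
# pooling


def _check_batch(batch: np.ndarray, n_rows: int) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.intp)
    if len(batch) != n_rows:
        raise ValueError("batch vector must cover every node row")
    return batch


def global_add_pool(X: Tensor, batch: np.ndarray) -> Tensor:
    """Per-graph sum of node features across the node dimension."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    batch = _check_batch(batch, X.shape[0])
    return segment_sum(X, batch, int(batch.max()) + 1 if len(batch) else 0)


def global_max_pool(X: Tensor, batch: np.ndarray) -> Tensor:
    """Per-graph channel-wise maximum of node features."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    batch = _check_batch(batch, X.shape[0])
    return segment_max(X, batch, int(batch.max()) + 1 if len(batch) else 0)
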