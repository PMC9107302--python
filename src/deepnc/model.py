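"""Assembly of the two affinity-prediction network variants.

Both variants share the same three-block design: (1) featurization —
SMILES to molecular graph, sequence to integer labels; (2) two parallel
representation branches — a graph branch over atoms and a 1-D
convolution branch over residues; (3) a fully-connected regression head
on the concatenated embeddings producing one real affinity per pair.

Variant ``GEN`` stacks three generalized-aggregation convolutions and a
global add pooling; variant ``HGC-GCN`` stacks two hypergraph
convolutions with attention, one plain graph convolution, and a global
max pooling.  ReLU sits between graph layers; dropout acts only in the
head and only during training.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .layers import (GcnLayerParams, GenLayerParams, HypergraphLayerParams,
                     gcn_forward, gen_conv_forward, global_add_pool,
                     global_max_pool, hypergraph_conv_forward)
from .mol_graph import (AtomFeatureSchema, HyperIncidence, MolGraph,
                        build_hyperedges, smiles_to_graph)
from .protein import VOCAB_SIZE, encode_sequence

__all__ = ["ModelConfig", "ConfigurationError", "DeepNCNetwork",
           "batch_graphs", "batch_hypergraphs"]

GEN = "GEN"
HGC_GCN = "HGC-GCN"


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Layer counts follow the published design (three generalized layers
    for GEN; two hypergraph layers plus one plain graph layer for
    HGC-GCN).  Widths, the protein branch shape and dropout are
    configuration choices of this package, defaulting to the customary
    values of the affinity-prediction lineage.
    """

    variant: str = GEN
    atom_feature_dim: int = AtomFeatureSchema().feature_length
    gnn_hidden_dims: list = field(default_factory=lambda: [78, 156, 312])
    graph_embed_dim: int = 128
    protein_vocab_size: int = VOCAB_SIZE
    protein_embed_dim: int = 128
    protein_conv_filters: int = 32
    protein_kernel_size: int = 8
    protein_max_len: int = 1000
    fc_dims: list = field(default_factory=lambda: [1024, 512])
    dropout_rate: float = 0.2
    hyperedge_mode: str = "bond"
    use_attention: bool = True
    attention_dim: int = 16
    beta: float = 1.0
    agg_mode: str = "softmax"
    p_power: float = 1.0
    epsilon: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if self.variant not in (GEN, HGC_GCN):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if len(self.gnn_hidden_dims) != 3:
            raise ConfigurationError(
                "both variants use exactly three graph layers "
                "(GEN: 3 generalized; HGC-GCN: 2 hypergraph + 1 plain)")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.protein_kernel_size > self.protein_max_len:
            raise ConfigurationError("kernel longer than padded sequence")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ----------------------------------------------------------------------
# batching helpers


def batch_graphs(graphs: list) -> tuple:
    """Stack molecular graphs into one disjoint-union graph.

    Returns (node features [N_total, F], arc array with offset indices,
    per-node graph id vector).
    """
    feats, arcs, batch = [], [], []
    offset = 0
    for g, graph in enumerate(graphs):
        feats.append(graph.atom_features)
        if len(graph.edge_index):
            arcs.append(graph.edge_index + offset)
        batch.extend([g] * graph.num_atoms)
        offset += graph.num_atoms
    x = np.concatenate(feats, axis=0)
    edge_index = (np.concatenate(arcs, axis=0) if arcs
                  else np.zeros((0, 2), dtype=np.intp))
    return x, edge_index, np.asarray(batch, dtype=np.intp)


def batch_hypergraphs(incs: list) -> HyperIncidence:
    """Disjoint union of hypergraph incidences (block-diagonal H)."""
    pairs, weights = [], []
    node_off = edge_off = 0
    for inc in incs:
        if len(inc.incidence):
            shifted = inc.incidence + np.array([node_off, edge_off])
            pairs.append(shifted)
        weights.append(inc.weights)
        node_off += inc.num_nodes
        edge_off += inc.num_hyperedges
    incidence = (np.concatenate(pairs, axis=0) if pairs
                 else np.zeros((0, 2), dtype=np.intp))
    return HyperIncidence(node_off, edge_off, incidence,
                          np.concatenate(weights) if weights else np.zeros(0))


# ----------------------------------------------------------------------
# network


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-a, a, size=(fan_in, fan_out)),
                  requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class DeepNCNetwork:
    """Trainable affinity predictor; parameters keyed by layer name.

    Initialization is deterministic given ``config.seed``.
    """

    def __init__(self, config: ModelConfig,
                 schema: AtomFeatureSchema | None = None):
        self.config = config
        self.schema = schema or AtomFeatureSchema()
        if self.schema.feature_length != config.atom_feature_dim:
            raise ConfigurationError(
                "atom_feature_dim does not match the featurization schema")
        self.params: dict[str, Tensor] = {}
        self._graph_cache: dict[str, tuple] = {}
        self._protein_cache: dict[str, np.ndarray] = {}
        self._build(np.random.default_rng(config.seed))

    # -- construction --------------------------------------------------
    def _add(self, name: str, tensor: Tensor) -> Tensor:
        self.params[name] = tensor
        return tensor

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        dims = [cfg.atom_feature_dim] + list(cfg.gnn_hidden_dims)
        if cfg.variant == GEN:
            for layer in range(3):
                din, dout = dims[layer], dims[layer + 1]
                # update MLP consumes the (message-normalized) node state,
                # so its input width is the layer input width
                self._add(f"gen{layer}.w1", _glorot(rng, din, dout))
                self._add(f"gen{layer}.b1", _zeros(dout))
                self._add(f"gen{layer}.w2", _glorot(rng, dout, dout))
                self._add(f"gen{layer}.b2", _zeros(dout))
                self._add(f"gen{layer}.s", Tensor(np.array(1.0),
                                                  requires_grad=True))
        else:
            for layer in range(2):
                din, dout = dims[layer], dims[layer + 1]
                self._add(f"hgc{layer}.p", _glorot(rng, din, dout))
                if cfg.use_attention:
                    self._add(f"hgc{layer}.att_proj",
                              _glorot(rng, din, cfg.attention_dim))
                    self._add(f"hgc{layer}.att_score",
                              _glorot(rng, 2 * cfg.attention_dim, 1))
            self._add("gcn.theta", _glorot(rng, dims[2], dims[3]))
        self._add("graph_proj.w", _glorot(rng, dims[3], cfg.graph_embed_dim))
        self._add("graph_proj.b", _zeros(cfg.graph_embed_dim))

        # protein branch
        self._add("prot.embedding",
                  _glorot(rng, cfg.protein_vocab_size, cfg.protein_embed_dim))
        kd = cfg.protein_kernel_size * cfg.protein_embed_dim
        self._add("prot.conv_w", _glorot(rng, kd, cfg.protein_conv_filters))
        self._add("prot.conv_b", _zeros(cfg.protein_conv_filters))
        self._add("prot.proj_w",
                  _glorot(rng, cfg.protein_conv_filters, cfg.graph_embed_dim))
        self._add("prot.proj_b", _zeros(cfg.graph_embed_dim))

        # fully-connected head
        fc_in = 2 * cfg.graph_embed_dim
        for i, width in enumerate(cfg.fc_dims):
            self._add(f"fc{i}.w", _glorot(rng, fc_in, width))
            self._add(f"fc{i}.b", _zeros(width))
            fc_in = width
        self._add("out.w", _glorot(rng, fc_in, 1))
        self._add("out.b", _zeros(1))

    # -- featurization (cached per string) ------------------------------
    def drug_inputs(self, smiles: str) -> tuple:
        """(MolGraph, HyperIncidence | None) for one compound, cached."""
        hit = self._graph_cache.get(smiles)
        if hit is None:
            g = smiles_to_graph(smiles, self.schema)
            inc = (build_hyperedges(g, self.config.hyperedge_mode)
                   if self.config.variant == HGC_GCN else None)
            hit = self._graph_cache[smiles] = (g, inc)
        return hit

    def protein_inputs(self, seq: str) -> np.ndarray:
        hit = self._protein_cache.get(seq)
        if hit is None:
            enc = encode_sequence(seq, max_len=self.config.protein_max_len)
            hit = self._protein_cache[seq] = enc.labels
        return hit

    # -- branch forwards -----------------------------------------------
    def _gen_layer_params(self, layer: int) -> GenLayerParams:
        cfg = self.config
        return GenLayerParams(
            mlp_weights=(self.params[f"gen{layer}.w1"],
                         self.params[f"gen{layer}.b1"],
                         self.params[f"gen{layer}.w2"],
                         self.params[f"gen{layer}.b2"]),
            s_scale=self.params[f"gen{layer}.s"],
            beta=cfg.beta, p_power=cfg.p_power, epsilon=cfg.epsilon,
            agg_mode=cfg.agg_mode)

    def _hgc_layer_params(self, layer: int) -> HypergraphLayerParams:
        cfg = self.config
        if cfg.use_attention:
            return HypergraphLayerParams(
                p_weight=self.params[f"hgc{layer}.p"], use_attention=True,
                attention_proj=self.params[f"hgc{layer}.att_proj"],
                attention_score=self.params[f"hgc{layer}.att_score"])
        return HypergraphLayerParams(p_weight=self.params[f"hgc{layer}.p"])

    def drug_branch(self, graphs: list, incs: list | None) -> Tensor:
        cfg = self.config
        x_np, edge_index, batch = batch_graphs(graphs)
        x = Tensor(x_np)
        if cfg.variant == GEN:
            for layer in range(3):
                x = gen_conv_forward(x, edge_index, self._gen_layer_params(layer))
                if layer < 2:
                    x = x.relu()
            pooled = global_add_pool(x, batch)
        else:
            inc = batch_hypergraphs(incs)
            for layer in range(2):
                x = hypergraph_conv_forward(
                    x, inc, self._hgc_layer_params(layer)).relu()
            x = gcn_forward(x, edge_index,
                            GcnLayerParams(self.params["gcn.theta"]))
            pooled = global_max_pool(x, batch)
        return (pooled @ self.params["graph_proj.w"]
                + self.params["graph_proj.b"]).relu()

    def protein_branch(self, labels: np.ndarray) -> Tensor:
        """labels [B, L] ints → [B, graph_embed_dim] embeddings."""
        cfg = self.config
        emb = self.params["prot.embedding"].take(labels)        # [B, L, D]
        length = labels.shape[1]
        k = cfg.protein_kernel_size
        n_win = length - k + 1
        widx = (np.arange(n_win)[:, None] + np.arange(k)).ravel()
        windows = emb.take(widx, axis=1)                        # [B, n*k, D]
        windows = windows.reshape(labels.shape[0], n_win,
                                  k * cfg.protein_embed_dim)
        conv = (windows @ self.params["prot.conv_w"]
                + self.params["prot.conv_b"]).relu()            # [B, n, F]
        pooled = conv.max(axis=1)                               # [B, F]
        return (pooled @ self.params["prot.proj_w"]
                + self.params["prot.proj_b"]).relu()

    # -- full forward ----------------------------------------------------
    def forward(self, smiles_list: list, sequences: list,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predicted affinity for each aligned (drug, target) pair."""
        if len(smiles_list) != len(sequences):
            raise ValueError("misaligned drug/protein batch lengths")
        if len(smiles_list) == 0:
            raise ValueError("empty batch")
        pairs = [self.drug_inputs(s) for s in smiles_list]
        graphs = [p[0] for p in pairs]
        incs = [p[1] for p in pairs] if self.config.variant == HGC_GCN else None
        labels = np.stack([self.protein_inputs(s) for s in sequences])
        drug_emb = self.drug_branch(graphs, incs)
        prot_emb = self.protein_branch(labels)
        h = concat([drug_emb, prot_emb], axis=1)
        cfg = self.config
        for i in range(len(cfg.fc_dims)):
            h = (h @ self.params[f"fc{i}.w"] + self.params[f"fc{i}.b"]).relu()
            if training and cfg.dropout_rate > 0:
                h = h.dropout(cfg.dropout_rate, rng)
        out = h @ self.params["out.w"] + self.params["out.b"]
        return out.reshape(-1)

    def predict(self, smiles_list: list, sequences: list) -> np.ndarray:
        """Evaluation-mode forward returning a plain array."""
        return self.forward(smiles_list, sequences, training=False).data

    # -- serialization ---------------------------------------------------
    def state_meta(self) -> dict:
        return {"config": self.config.to_dict(),
                "schema": self.schema.to_dict(),
                "format_version": 1}

    def save(self, path, extra_meta: dict | None = None) -> None:
        """Single-archive checkpoint: parameters + config + schema."""
        meta = self.state_meta()
        if extra_meta:
            meta.update(extra_meta)
        arrays = {name: t.data for name, t in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple["DeepNCNetwork", dict]:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        config = ModelConfig.from_dict(meta["config"])
        schema = AtomFeatureSchema.from_dict(meta["schema"])
        net = cls(config, schema)
        if set(arrays) != set(net.params):
            raise ConfigurationError("checkpoint/architecture mismatch")
        for name, arr in arrays.items():
            net.params[name].data = arr.astype(np.float64)
        return net, meta
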