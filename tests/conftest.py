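import numpy as np
import pytest

from deepnc.model import ModelConfig


def tiny_config(variant="GEN", seed=0, **overrides):
    """Small architecture for fast tests; widths are test choices."""
    base = dict(variant=variant, gnn_hidden_dims=[16, 16, 16],
                graph_embed_dim=16, protein_embed_dim=8,
                protein_conv_filters=8, protein_kernel_size=4,
                protein_max_len=64, fc_dims=[32], dropout_rate=0.0,
                seed=seed)
    base.update(overrides)
    return ModelConfig(**base)


def random_graph(rng, n, n_feat=5, p=0.4):
    """Random undirected graph as (features, directed arc array)."""
    x = rng.normal(size=(n, n_feat))
    arcs = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                arcs.append((i, j))
                arcs.append((j, i))
    edge_index = (np.array(arcs, dtype=np.intp) if arcs
                  else np.zeros((0, 2), dtype=np.intp))
    return x, edge_index


@pytest.fixture
def rng():
    return np.random.default_rng(0)
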