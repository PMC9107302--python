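"""Model/Results surface for affinity regression.

:class:`AffinityModel` is built from a :class:`~deepnc.data_io.DTIDataset`
(or a dataframe) plus an architecture configuration; :meth:`AffinityModel.fit`
runs the training engine and returns an :class:`AffinityResults` holding
the fitted parameters, the per-epoch history, metric evaluation,
prediction, a text ``summary()`` and checkpoint round-tripping.
"""

from __future__ import annotations

import numpy as np

from .data_io import DTIDataset
from .metrics import MetricsReport
from .model import DeepNCNetwork, ModelConfig
from .training import TrainConfig, TrainHistory, evaluate, predict, train

__all__ = ["AffinityModel", "AffinityResults"]


class AffinityModel:
    """Drug–target affinity regression model bound to a dataset."""

    def __init__(self, dataset: DTIDataset,
                 config: ModelConfig | None = None):
        dataset.validate()
        self.dataset = dataset
        self.config = config or ModelConfig()

    @classmethod
    def from_dataframe(cls, df, config: ModelConfig | None = None,
                       smiles_col: str = "smiles",
                       sequence_col: str = "target_sequence",
                       affinity_col: str = "affinity") -> "AffinityModel":
        pairs = [(str(s), str(t), float(a))
                 for s, t, a in zip(df[smiles_col], df[sequence_col],
                                    df[affinity_col])]
        return cls(DTIDataset(pairs), config)

    def fit(self, train_config: TrainConfig | None = None,
            **overrides) -> "AffinityResults":
        """Train and return the fitted results object."""
        if train_config is None:
            train_config = TrainConfig(**overrides)
        elif overrides:
            raise TypeError("pass either a TrainConfig or keyword overrides")
        net, history = train(self.config, train_config, self.dataset)
        return AffinityResults(self, net, history, train_config)


class AffinityResults:
    """Fitted affinity model: parameters, history and diagnostics."""

    def __init__(self, model: AffinityModel, network: DeepNCNetwork,
                 history: TrainHistory, train_config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    # -- inference -----------------------------------------------------
    def predict(self, pairs: list) -> np.ndarray:
        """Affinities for (smiles, sequence) pairs; NaN for bad rows."""
        values, _ = predict(self.network, pairs,
                            self.train_config.batch_size)
        return values

    def predict_with_errors(self, pairs: list):
        return predict(self.network, pairs, self.train_config.batch_size)

    def evaluate(self, dataset: DTIDataset) -> MetricsReport:
        return evaluate(self.network, dataset, self.train_config.batch_size)

    # -- reporting -----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.network.params.values()))

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "Affinity regression results",
            "=" * 46,
            f"{'variant':<28}{cfg.variant}",
            f"{'graph layers':<28}3",
            f"{'trainable parameters':<28}{self.n_parameters}",
            f"{'training pairs':<28}{len(self.model.dataset)}",
            f"{'epochs run':<28}{len(h.train_loss)}",
            f"{'final training MSE':<28}{h.train_loss[-1]:.4f}",
        ]
        if h.val_mse:
            lines.append(f"{'best epoch (val MSE)':<28}{h.best_epoch}")
            lines.append(f"{'best validation MSE':<28}{min(h.val_mse):.4f}")
            ci = h.val_ci[h.best_epoch] if h.best_epoch is not None else None
            if ci is not None:
                lines.append(f"{'validation CI at best':<28}{ci:.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- persistence / plotting ----------------------------------------
    def save(self, path) -> None:
        self.network.save(path, {"train_config": vars(self.train_config)})

    @staticmethod
    def load_network(path) -> DeepNCNetwork:
        net, _ = DeepNCNetwork.load(path)
        return net

    def plot_history(self, ax=None):
        """Training (and validation) MSE curves; needs matplotlib."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.train_loss, label="train MSE")
        if self.history.val_mse:
            ax.plot(self.history.val_mse, label="validation MSE")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE")
        ax.legend()
        return ax
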