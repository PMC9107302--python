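"""Mini-batch Adam training and evaluation of affinity networks.

The loss is the mean squared error of predicted versus measured
affinity.  Optimization follows the published settings (Adam, learning
rate 5e-4, batch size 256, 1000 epochs by default — all configurable;
the scaled-down configurations used in tests are documented choices).
Shuffling, initialization and dropout all derive from one seed, so a
run is reproducible on a single device.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .data_io import DTIDataset, split_dataset
from .metrics import MetricsReport, compute_report
from .model import DeepNCNetwork, ModelConfig

__all__ = ["TrainConfig", "TrainHistory", "TrainingError",
           "train", "evaluate", "predict"]


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 0.0005
    batch_size: int = 256
    epochs: int = 1000
    optimizer: str = "adam"
    seed: int = 0
    validation: float | str | None = None   # fraction in (0,1) or "folds"
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if isinstance(self.validation, float) and not 0 < self.validation < 1:
            raise ValueError("validation fraction must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    val_ci: list = field(default_factory=list)
    best_epoch: int | None = None

    def to_csv(self, path) -> None:
        lines = ["epoch,train_loss,val_mse,val_ci"]
        for e, loss in enumerate(self.train_loss):
            vm = self.val_mse[e] if e < len(self.val_mse) else ""
            vc = self.val_ci[e] if e < len(self.val_ci) else ""
            vc = "" if vc is None else vc
            lines.append(f"{e},{loss},{vm},{vc}")
        Path(path).write_text("\n".join(lines) + "\n")


class _Adam:
    """Adam with standard moment coefficients and bias correction."""

    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _forward_batched(net: DeepNCNetwork, ds: DTIDataset,
                     batch_size: int) -> np.ndarray:
    out = []
    smi, seq = ds.smiles, ds.sequences
    for a in range(0, len(ds), batch_size):
        out.append(net.predict(smi[a:a + batch_size], seq[a:a + batch_size]))
    return np.concatenate(out)


def train(model_config: ModelConfig, train_config: TrainConfig,
          dataset: DTIDataset,
          net: DeepNCNetwork | None = None) -> tuple[DeepNCNetwork, TrainHistory]:
    """Fit a network to a dataset by mini-batch Adam on the MSE loss.

    When validation is configured the best-validation-MSE parameters are
    restored at the end; otherwise the final epoch's parameters are
    kept.  Returns the network and the per-epoch history.
    """
    if len(dataset) == 0:
        raise TrainingError("empty training dataset")
    if net is None:
        net = DeepNCNetwork(model_config)

    val_ds = None
    if train_config.validation == "folds":
        dataset, val_ds = split_dataset(dataset, scheme="folds")
    elif isinstance(train_config.validation, float):
        dataset, val_ds = split_dataset(
            dataset, scheme="random", fraction=1 - train_config.validation,
            seed=train_config.seed)

    rng = np.random.default_rng(train_config.seed)
    opt = _Adam(net.params, train_config.learning_rate)
    history = TrainHistory()
    smiles, seqs, y = dataset.smiles, dataset.sequences, dataset.affinities
    n = len(dataset)
    log_fh = open(train_config.log_path, "a") if train_config.log_path else None
    best_val = np.inf
    best_state = None
    try:
        for epoch in range(train_config.epochs):
            order = rng.permutation(n)
            losses = []
            for a in range(0, n, train_config.batch_size):
                idx = order[a:a + train_config.batch_size]
                pred = net.forward([smiles[i] for i in idx],
                                   [seqs[i] for i in idx],
                                   training=True, rng=rng)
                diff = pred - Tensor(y[idx])
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise TrainingError(
                        f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data) * len(idx))
            epoch_loss = float(np.sum(losses) / n)
            history.train_loss.append(epoch_loss)

            record = {"epoch": epoch, "train_loss": epoch_loss,
                      "time": time.time()}
            if val_ds is not None:
                rep = evaluate(net, val_ds, train_config.batch_size)
                history.val_mse.append(rep.mse)
                history.val_ci.append(rep.ci)
                record.update(val_mse=rep.mse, val_ci=rep.ci)
                if rep.mse < best_val:
                    best_val = rep.mse
                    history.best_epoch = epoch
                    best_state = {k: t.data.copy()
                                  for k, t in net.params.items()}
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if (train_config.checkpoint_every
                    and (epoch + 1) % train_config.checkpoint_every == 0
                    and train_config.checkpoint_dir):
                ckdir = Path(train_config.checkpoint_dir)
                ckdir.mkdir(parents=True, exist_ok=True)
                net.save(ckdir / f"epoch{epoch + 1}.npz",
                         {"epoch": epoch + 1})
    finally:
        if log_fh:
            log_fh.close()

    if best_state is not None:
        for k, arr in best_state.items():
            net.params[k].data = arr
    elif val_ds is None:
        history.best_epoch = train_config.epochs - 1
    return net, history


def evaluate(net: DeepNCNetwork, dataset: DTIDataset,
             batch_size: int = 256) -> MetricsReport:
    """Evaluation-mode metrics over all pairs of a dataset.

    CI (and r²m) are None when undefined on the given labels; MSE is
    always reported.
    """
    if len(dataset) == 0:
        raise TrainingError("empty evaluation dataset")
    preds = _forward_batched(net, dataset, batch_size)
    return compute_report(preds, dataset.affinities)


def predict(net: DeepNCNetwork, pairs: list,
            batch_size: int = 256) -> tuple[np.ndarray, list]:
    """Predict affinity for (smiles, sequence) pairs, order-preserving.

    Rows whose SMILES cannot be featurized yield NaN and an entry in the
    returned error list; all other rows are predicted.
    """
    values = np.full(len(pairs), np.nan)
    errors: list[tuple[int, str]] = []
    good_idx, good_pairs = [], []
    for k, (smi, seq) in enumerate(pairs):
        try:
            net.drug_inputs(smi)
            net.protein_inputs(seq)
        except Exception as exc:  # noqa: BLE001 - reported per row
            errors.append((k, str(exc)))
            continue
        good_idx.append(k)
        good_pairs.append((smi, seq))
    for a in range(0, len(good_pairs), batch_size):
        chunk = good_pairs[a:a + batch_size]
        out = net.predict([p[0] for p in chunk], [p[1] for p in chunk])
        values[good_idx[a:a + batch_size]] = out
    return values, errors
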