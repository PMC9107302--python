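"""Training harness, evaluation and the Model/Results surface."""

import numpy as np
import pytest

from conftest import tiny_config
from deepnc.data_io import DTIDataset
from deepnc.metrics import mse
from deepnc.model import DeepNCNetwork
from deepnc.regression import AffinityModel
from deepnc.synthetic import SyntheticSpec, make_dataset
from deepnc.training import TrainConfig, evaluate, predict, train


def small_dataset(noise=0.0, seed=3, n_drugs=4, n_targets=4):
    return make_dataset(SyntheticSpec(n_drugs=n_drugs, n_targets=n_targets,
                                      noise_sd=noise, seed=seed))


FAST = dict(learning_rate=0.005, batch_size=16, seed=5)


def test_epochs_zero_rejected():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1)


def test_identical_seeds_identical_loss_curves():
    ds = small_dataset()
    mc = tiny_config("GEN", seed=1)
    _, h1 = train(mc, TrainConfig(epochs=5, **FAST), ds)
    _, h2 = train(mc, TrainConfig(epochs=5, **FAST), ds)
    assert np.allclose(h1.train_loss, h2.train_loss, atol=1e-6)


def test_loss_trend_decreases_on_noise_free_data():
    ds = small_dataset(noise=0.0)
    _, hist = train(tiny_config("GEN", seed=2),
                    TrainConfig(epochs=40, **FAST), ds)
    first = np.median(hist.train_loss[:10])
    last = np.median(hist.train_loss[-10:])
    assert last < first


def test_evaluate_is_deterministic_and_consistent_with_metrics():
    ds = small_dataset(noise=0.3)
    net, _ = train(tiny_config("GEN", seed=4), TrainConfig(epochs=3, **FAST), ds)
    r1 = evaluate(net, ds)
    r2 = evaluate(net, ds)
    assert r1 == r2
    preds = net.predict(ds.smiles, ds.sequences)
    assert abs(r1.mse - mse(preds, ds.affinities)) < 1e-12
    assert r1.n_pairs == len(ds)


def test_evaluate_tied_labels_reports_mse_without_ci():
    pairs = [("CCO", "ACDEF", 5.0), ("CCC", "MKLVW", 5.0)]
    ds = DTIDataset(pairs)
    net = DeepNCNetwork(tiny_config("GEN"))
    rep = evaluate(net, ds)
    assert rep.ci is None and rep.mse >= 0


def test_validation_split_tracks_best_epoch():
    ds = small_dataset(noise=0.3, n_drugs=6, n_targets=4)
    cfg = TrainConfig(epochs=8, validation=0.25, **FAST)
    net, hist = train(tiny_config("GEN", seed=6), cfg, ds)
    assert len(hist.val_mse) == 8
    assert hist.best_epoch == int(np.argmin(hist.val_mse))


def test_divergence_raises_naming_epoch():
    ds = small_dataset()
    mc = tiny_config("GEN", seed=0)
    net = DeepNCNetwork(mc)
    net.params["out.b"].data[:] = np.nan  # poisoned state -> non-finite loss
    cfg = TrainConfig(epochs=5, **FAST)
    with pytest.raises(RuntimeError, match="epoch 0"):
        train(mc, cfg, ds, net=net)


def test_predict_order_preserving_and_row_errors():
    net = DeepNCNetwork(tiny_config("GEN"))
    pairs = [("CCO", "ACDEF"), ("X((", "ACDEF"), ("CCC", "MKLVW")]
    values, errors = predict(net, pairs)
    assert len(values) == 3
    assert np.isnan(values[1]) and not np.isnan(values[0])
    assert errors[0][0] == 1 and "X((" in errors[0][1]
    # permuted input -> permuted output
    v2, _ = predict(net, [pairs[2], pairs[0]])
    assert np.allclose(v2, [values[2], values[0]])


def test_checkpoint_round_trip_reproduces_report(tmp_path):
    ds = small_dataset(noise=0.3)
    net, _ = train(tiny_config("HGC-GCN", seed=7),
                   TrainConfig(epochs=3, **FAST), ds)
    before = evaluate(net, ds)
    net.save(tmp_path / "m.npz")
    loaded, _ = DeepNCNetwork.load(tmp_path / "m.npz")
    after = evaluate(loaded, ds)
    assert before == after  # bit-identical report


def test_history_csv_and_log(tmp_path):
    ds = small_dataset()
    log = tmp_path / "log.jsonl"
    cfg = TrainConfig(epochs=3, log_path=str(log), **FAST)
    _, hist = train(tiny_config("GEN", seed=8), cfg, ds)
    hist.to_csv(tmp_path / "h.csv")
    assert (tmp_path / "h.csv").read_text().startswith("epoch,train_loss")
    assert len(log.read_text().strip().splitlines()) == 3


def test_affinity_model_fit_summary_and_predict():
    ds = small_dataset(noise=0.3)
    model = AffinityModel(ds, tiny_config("GEN", seed=9))
    res = model.fit(epochs=4, **FAST)
    text = res.summary()
    assert "GEN" in text and "epochs run" in text
    preds = res.predict([(ds.smiles[0], ds.sequences[0])])
    assert preds.shape == (1,)
    rep = res.evaluate(ds)
    assert rep.n_pairs == len(ds)


def test_affinity_model_from_dataframe():
    import pandas as pd
    df = pd.DataFrame({"smiles": ["CCO", "CCC", "CO"],
                       "target_sequence": ["ACDEF", "MKLVW", "ACDEF"],
                       "affinity": [5.0, 6.0, 7.0]})
    model = AffinityModel.from_dataframe(df, tiny_config("GEN"))
    assert len(model.dataset) == 3
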