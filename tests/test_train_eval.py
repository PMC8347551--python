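"""Training loop, evaluation, ablation harness and prediction, exercised on
tiny synthetic sets (32x32, base width 16) so each run takes seconds."""

import numpy as np
import pytest
from PIL import Image

from facnet import nn
from facnet.backbone import ModelConfig, build_model, load_checkpoint
from facnet.errors import ConfigurationError
from facnet.nn.tensor import Tensor
from facnet.train import TrainConfig, evaluate, predict, run_ablation, train


def tiny_train_config(**kw):
    base = dict(
        model=ModelConfig(use_ffb=True, use_amb=True, base_width=16, reduction=8),
        learning_rate=1e-3, batch_size=8, epochs=2, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class StubModel:
    """Evaluation stub emitting a fixed map for every input."""

    def __init__(self, maps):
        self.maps = maps

    def eval(self):
        return self

    def __call__(self, images):
        return Tensor(np.stack([self.maps[0]] * len(images)))


def test_short_training_reduces_loss_and_logs_history(tiny_synth_set):
    cfg = tiny_train_config()
    model, history = train(cfg, tiny_synth_set[:16], tiny_synth_set[16:24])
    assert len(history) == 2
    assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]
    assert {"val_JA", "val_DC"} <= set(history.columns)


def test_training_is_seed_reproducible(tiny_synth_set):
    cfg = tiny_train_config(epochs=1)
    _, h1 = train(cfg, tiny_synth_set[:8], [])
    _, h2 = train(cfg, tiny_synth_set[:8], [])
    assert h1["train_loss"].iloc[-1] == pytest.approx(h2["train_loss"].iloc[-1],
                                                      rel=1e-7)


def test_zero_epochs_returns_initialisation(tiny_synth_set):
    cfg = tiny_train_config(epochs=0)
    model, history = train(cfg, tiny_synth_set[:8], [])
    assert history.empty
    reference = build_model(cfg.model, seed=cfg.seed)
    for (na, pa), (nb, pb) in zip(model.named_parameters(),
                                  reference.named_parameters()):
        assert na == nb
        np.testing.assert_array_equal(pa.data, pb.data)


def test_empty_training_split_rejected():
    with pytest.raises(ConfigurationError):
        train(tiny_train_config(), [], [])


def test_evaluate_stub_outputs(tiny_synth_set):
    samples = tiny_synth_set[:4]
    # stub that reproduces the GT of every image exactly -> all metrics 1
    for s in samples:
        perfect = StubModel([s.mask.astype(np.float32)])
        mean, _, _ = evaluate(perfect, [s])
        assert mean.JA == pytest.approx(1.0) and mean.ACC == pytest.approx(1.0)
    # all-zero output -> SE=0, SP=1 on images containing both classes
    zero = StubModel([np.zeros_like(samples[0].mask, dtype=np.float32)])
    mean, _, _ = evaluate(zero, samples)
    assert mean.SE == pytest.approx(0.0) and mean.SP == pytest.approx(1.0)


def test_trained_model_beats_untrained(tiny_synth_set):
    cfg = tiny_train_config(epochs=3)
    trained, _ = train(cfg, tiny_synth_set[:24], tiny_synth_set[24:32])
    untrained = build_model(cfg.model, seed=cfg.seed).eval()
    test_set = tiny_synth_set[32:]
    ja_trained = evaluate(trained, test_set)[0].JA
    ja_untrained = evaluate(untrained, test_set)[0].JA
    assert ja_trained > ja_untrained


def test_checkpoint_written_and_reloadable(tiny_synth_set, tmp_path):
    cfg = tiny_train_config(epochs=1)
    path = tmp_path / "ckpt.npz"
    model, _ = train(cfg, tiny_synth_set[:8], tiny_synth_set[8:12],
                     checkpoint_path=path)
    loaded, extra = load_checkpoint(path)
    assert "best_val_ja" in extra
    x = tiny_synth_set[0].image[None]
    with nn.no_grad():
        np.testing.assert_array_equal(model(x).data, loaded(x).data)


def test_ablation_module_grid_shape_and_determinism(tiny_synth_set):
    cfg = tiny_train_config(epochs=1, batch_size=8)
    tr, va, te = tiny_synth_set[:16], tiny_synth_set[16:20], tiny_synth_set[20:28]
    table1, reports1 = run_ablation(cfg, tr, va, te, grid="modules")
    assert table1.shape == (4, 6)
    assert list(table1.index) == ["CE-Net", "CE-Net+FFB", "CE-Net+AMB",
                                  "CE-Net+FFB+AMB"]
    table2, _ = run_ablation(cfg, tr, va, te, grid="modules")
    assert table1.equals(table2)


def test_ablation_unknown_grid_rejected(tiny_synth_set):
    with pytest.raises(ConfigurationError):
        run_ablation(tiny_train_config(), tiny_synth_set[:4], [], [],
                     grid="nonsense")


def test_predict_writes_bilevel_masks_at_original_size(tmp_path, rng):
    img_dir = tmp_path / "in"
    img_dir.mkdir()
    paths = []
    for k, size in enumerate([(100, 80), (64, 64), (90, 120)]):
        p = img_dir / f"img{k}.jpg"
        Image.fromarray(rng.integers(0, 255, (*size, 3), dtype=np.uint8)).save(p)
        paths.append(p)
    model = build_model(ModelConfig(use_ffb=False, use_amb=False, base_width=8),
                        seed=0)
    out1 = predict(model, paths, tmp_path / "out1", size=32)
    out2 = predict(model, paths, tmp_path / "out2", size=32)
    assert len(out1) == 3
    for p, src, (h, w) in zip(out1, paths, [(100, 80), (64, 64), (90, 120)]):
        arr = np.asarray(Image.open(p))
        assert arr.shape == (h, w)
        assert set(np.unique(arr)) <= {0, 255}
    for a, b in zip(out1, out2):  # prediction is deterministic/idempotent
        np.testing.assert_array_equal(np.asarray(Image.open(a)),
                                      np.asarray(Image.open(b)))


def test_train_config_validation():
    with pytest.raises(ConfigurationError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ConfigurationError):
        TrainConfig(batch_size=0)
    cfg = TrainConfig()
    assert cfg.learning_rate == pytest.approx(1e-4)
    assert cfg.batch_size == 12 and cfg.epochs == 200


def test_cli_synth_split_roundtrip(tmp_path):
    from click.testing import CliRunner

    from facnet.cli import main

    runner = CliRunner()
    data_dir = tmp_path / "data"
    res = runner.invoke(main, ["synth", "--out", str(data_dir), "--n", "10",
                               "--size", "64", "--seed", "1"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["split", "--data", str(data_dir),
                               "--out", str(tmp_path / "split.tsv")])
    assert res.exit_code == 0, res.output
    assert "train=7" in res.output and "test=2" in res.output
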