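"""Dynamic-weight fusion, the prediction head, and the training harness."""

import dataclasses

import numpy as np
import pytest

from casguide.fusion_model import (ActivityScaler, CasActivityModel,
                                   DynamicWeightFusion, GridSpace,
                                   TrainingConfig, TrainingDivergedError,
                                   fuse, grid_search, train)
from casguide.nn import cosine_annealing_lr
from casguide.sgrna_encoder import encode_batch


def test_training_config_defaults():
    cfg = TrainingConfig()
    assert cfg.learning_rate == 0.0001
    assert cfg.batch_size == 256
    assert cfg.epochs == 100
    assert cfg.optimizer == "adam"
    assert cfg.loss == "mse"
    assert cfg.scheduler == "cosine_annealing"
    assert cfg.scheduler_cycle == 5


def test_grid_space_enumerates_full_product():
    assert len(GridSpace().configs()) == 4 * 4 * 3 == 48


def test_fusion_weight_bounded_and_convex():
    rng = np.random.default_rng(0)
    gate = DynamicWeightFusion(width=16, rng=rng)
    a = rng.standard_normal((20, 16)).astype(np.float32)
    b = rng.standard_normal((20, 16)).astype(np.float32)
    fused, w = fuse(a, b, gate)
    assert np.all(w > 0) and np.all(w < 1)
    # coordinatewise convex combination: recompute directly and bound-check
    np.testing.assert_allclose(fused, w * a + (1 - w) * b, rtol=1e-6)
    assert np.all(fused >= np.minimum(a, b) - 1e-6)
    assert np.all(fused <= np.maximum(a, b) + 1e-6)


def test_fusion_equal_vectors_passthrough():
    rng = np.random.default_rng(1)
    gate = DynamicWeightFusion(width=8, rng=rng)
    a = rng.standard_normal((5, 8)).astype(np.float32)
    fused, _ = fuse(a, a.copy(), gate)
    np.testing.assert_allclose(fused, a, rtol=1e-6)


def test_fusion_zero_weight_net_gives_half():
    rng = np.random.default_rng(2)
    gate = DynamicWeightFusion(width=8, rng=rng)
    for p in gate.params():
        p.value[...] = 0
    a = rng.standard_normal((4, 8)).astype(np.float32)
    b = rng.standard_normal((4, 8)).astype(np.float32)
    fused, w = fuse(a, b, gate)
    np.testing.assert_allclose(w, 0.5)
    np.testing.assert_allclose(fused, (a + b) / 2, rtol=1e-5)


def test_fusion_width_mismatch():
    gate = DynamicWeightFusion(width=8, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="mismatch"):
        gate.forward(np.zeros((2, 8), dtype=np.float32),
                     np.zeros((2, 7), dtype=np.float32))


def test_predict_in_open_unit_interval(tiny_model, tiny_dataset):
    records, _ = tiny_dataset
    preds = tiny_model.predict_scaled(records[:16])
    assert preds.shape == (16,)
    assert np.all(preds > 0) and np.all(preds < 1)


def test_batch_equals_per_record_prediction(tiny_model, tiny_dataset):
    records, _ = tiny_dataset
    batch = tiny_model.predict_scaled(records[:8])
    singles = np.concatenate(
        [tiny_model.predict_scaled(records[i:i + 1]) for i in range(8)])
    np.testing.assert_allclose(batch, singles, rtol=1e-5, atol=1e-7)


def test_unknown_variant_label_raises(tiny_model, tiny_dataset):
    records, _ = tiny_dataset
    bad = dataclasses.replace(records[0], variant_name="no-such-variant")
    with pytest.raises(KeyError, match="no-such-variant"):
        tiny_model.predict_scaled([bad])


def test_forward_reproducible_under_seed(small_proteins, tiny_dataset):
    records, _ = tiny_dataset
    x = encode_batch(records[:4])
    names = [r.variant_name for r in records[:4]]
    outs = []
    for _ in range(2):
        m = CasActivityModel(embedding_width=64, seed=11)
        m.set_variant_embeddings(small_proteins)
        outs.append(m.forward(x, names)[0])
    np.testing.assert_array_equal(outs[0], outs[1])


def test_zero_learning_rate_freezes_parameters(small_proteins, tiny_dataset):
    records, _ = tiny_dataset
    cfg = TrainingConfig(learning_rate=0.0, epochs=1, batch_size=32, seed=0)
    model = CasActivityModel(embedding_width=64, seed=0)
    before = [p.value.copy() for p in model.params()]
    model, _ = train(records[:32], small_proteins, cfg, model=model)
    for b, p in zip(before, model.params()):
        np.testing.assert_array_equal(b, p.value)


def test_loss_nonincreasing_on_constant_targets(small_proteins, tiny_dataset):
    """On a constant-target dataset MSE decreases monotonically (to the
    sigmoid head this is a pure bias-fitting problem)."""
    records, _ = tiny_dataset
    const = [dataclasses.replace(r, activity=0.7) for r in records[:40]]
    cfg = TrainingConfig(learning_rate=0.001, epochs=8, batch_size=40, seed=0)
    _, history = train(const, small_proteins, cfg)
    losses = history["train_loss"]
    assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


def test_training_history_and_best_checkpoint(small_proteins, tiny_dataset):
    records, truth = tiny_dataset
    cfg = TrainingConfig(learning_rate=0.002, epochs=6, batch_size=32, seed=1)
    model, history = train(records[:90], small_proteins, cfg,
                           val_records=records[90:])
    assert len(history["train_loss"]) == 6
    assert len(history["val_spearman"]) == 6
    assert history["best_val_spearman"] == max(history["val_spearman"])


def test_cosine_annealing_restarts_at_cycle_start():
    lr_max, cycle = 0.01, 5
    values = [cosine_annealing_lr(e, lr_max, cycle) for e in range(15)]
    for start in (0, 5, 10):
        assert values[start] == pytest.approx(lr_max)
    # strictly decreasing within a cycle
    for start in (0, 5, 10):
        cyc = values[start:start + 5]
        assert all(a > b for a, b in zip(cyc, cyc[1:]))


def test_grid_search_singleton_returns_element(small_proteins, tiny_dataset):
    records, _ = tiny_dataset
    space = GridSpace(learning_rates=(0.001,), batch_sizes=(32,),
                      epoch_counts=(2,))
    best, board = grid_search(space, records[:80], records[80:], small_proteins)
    assert (best.learning_rate, best.batch_size, best.epochs) == (0.001, 32, 2)
    assert len(board) == 1


def test_grid_search_prefers_trainable_lr(small_proteins, tiny_dataset):
    """A grid with one sane and one absurd learning rate selects the sane
    one; the diverging config lands at the bottom of the leaderboard."""
    records, _ = tiny_dataset
    space = GridSpace(learning_rates=(0.002, 500.0), batch_sizes=(32,),
                      epoch_counts=(3,))
    best, board = grid_search(space, records[:80], records[80:], small_proteins)
    assert best.learning_rate == 0.002
    assert board[-1]["val_spearman"] <= board[0]["val_spearman"]


def test_nonfinite_loss_aborts_with_diagnostic(small_proteins, tiny_dataset):
    records, _ = tiny_dataset
    model = CasActivityModel(embedding_width=64, seed=0)
    model.params()[0].value[...] = np.nan  # poison one tensor
    cfg = TrainingConfig(learning_rate=0.001, epochs=1, batch_size=32, seed=0)
    with pytest.raises(TrainingDivergedError, match="non-finite"):
        train(records[:32], small_proteins, cfg, model=model)


def test_scaler_roundtrip():
    values = np.array([3.0, 7.0, 5.0])
    scaler = ActivityScaler.fit(values)
    scaled = scaler.transform(values)
    assert scaled.min() == 0.0 and scaled.max() == 1.0
    np.testing.assert_allclose(scaler.inverse(scaled), values, rtol=1e-6)


def test_checkpoint_roundtrip(tmp_path, small_proteins, tiny_dataset):
    records, _ = tiny_dataset
    cfg = TrainingConfig(learning_rate=0.002, epochs=2, batch_size=32, seed=3)
    model, _ = train(records[:60], small_proteins, cfg)
    preds = model.predict(records[60:80])
    model.save(tmp_path / "ckpt")
    loaded = CasActivityModel.load(tmp_path / "ckpt")
    np.testing.assert_allclose(loaded.predict(records[60:80]), preds,
                               rtol=1e-6)
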