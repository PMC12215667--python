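"""Training protocols: transfer bit-equality, exact freezing, early stopping,
determinism, and the sweep's selection rule."""

import numpy as np
import pytest

from ltadetect.ecgnet import ArchitectureSpec, build_model
from ltadetect.experiments import prepare_pt_data
from ltadetect.synth import generate_pt_cohort
from ltadetect.trainer import (
    TrainConfig,
    TransferConfig,
    finetune,
    freezing_sweep,
    load_checkpoint,
    pretrain,
    save_checkpoint,
    select_best_k,
    transfer_weights,
)


def _cfg(**kw) -> TrainConfig:
    base = dict(max_epochs=2, early_stop_patience=1, batch_size=16, seed=0, n_repeats=1)
    base.update(kw)
    return TrainConfig(**base)


def test_transfer_copies_backbone_bit_exactly(toy_spec):
    v0 = build_model(ArchitectureSpec(8, 4, 4, 8, head="v0", n_classes=10), seed=1)
    source = v0.state_dict()
    v1 = build_model(toy_spec, seed=2)
    head_before = v1.head.w.value.copy()
    transfer_weights(source, v1)
    for p in v1.params():
        if p.name.startswith("head."):
            continue
        assert np.array_equal(p.value, source[p.name]), p.name
    # head keeps its fresh initialization, differing from the source head
    assert np.array_equal(v1.head.w.value, head_before)
    assert v1.head.w.value.shape != v0.head.w.value.shape


def test_transfer_shape_mismatch_names_offenders(toy_spec):
    wide = build_model(ArchitectureSpec(8, 8, 4, 8, head="v1"), seed=0)
    narrow = build_model(toy_spec, seed=0)
    with pytest.raises(ValueError, match="stem.conv.w"):
        transfer_weights(wide.state_dict(), narrow)


@pytest.mark.parametrize("k", [0, 3, 7])
def test_finetune_freezing_contract(toy_spec, tiny_ft, tiny_ft_val, k):
    """First k blocks bit-identical after training; unfrozen blocks changed."""
    source = build_model(toy_spec, seed=9).state_dict()
    model = build_model(toy_spec, seed=4)
    state, _ = finetune(model, TransferConfig(source, k), tiny_ft, tiny_ft_val, _cfg())
    for i, block in enumerate(model.blocks):
        names = [p.name for p in block.params()]
        bn_stat_names = [f"block{i:02d}.bn1.run_mean", f"block{i:02d}.bn2.run_var"]
        if i < k:
            assert all(np.array_equal(state[n], source[n]) for n in names), i
            assert all(np.array_equal(state[n], source[n]) for n in bn_stat_names), i
        else:
            assert any(not np.array_equal(state[n], source[n]) for n in names), i
    assert any(not np.array_equal(state[p.name], source[p.name])
               for p in model.head.params() + model.final_bn.params())


def test_freezing_all_blocks_rejected(toy_spec):
    model = build_model(toy_spec, seed=0)
    with pytest.raises(ValueError, match=r"\[0, 7\]"):
        model.freeze_blocks(8)


def test_early_stopping_on_stagnant_validation_loss(
    toy_spec, tiny_ft, tiny_ft_val, monkeypatch
):
    """A validation loss that never improves stops training after exactly
    1 + patience epochs, and the best checkpoint is the first epoch's."""
    import ltadetect.trainer as trainer_mod

    monkeypatch.setattr(trainer_mod, "_epoch_loss_v1", lambda *a, **k: 1.0)
    model = build_model(toy_spec, seed=0)
    cfg = _cfg(max_epochs=10, early_stop_patience=2)
    state, hist = finetune(model, None, tiny_ft, tiny_ft_val, cfg)
    assert len(hist["val_loss"]) == 3
    assert hist["best_epoch"] == 0


def test_finetune_is_deterministic_under_seed(toy_spec, tiny_ft, tiny_ft_val):
    runs = []
    for _ in range(2):
        model = build_model(toy_spec, seed=3)
        state, hist = finetune(model, None, tiny_ft, tiny_ft_val, _cfg(seed=3))
        runs.append((state, hist))
    assert runs[0][1]["train_loss"] == runs[1][1]["train_loss"]
    assert all(np.array_equal(runs[0][0][k], runs[1][0][k]) for k in runs[0][0])


def test_pretrain_loss_decreases_on_synthetic_pt(toy_spec):
    """Smoke criterion: multi-label pre-training makes progress within the
    first three epochs on a separable synthetic cohort."""
    pt, _ = prepare_pt_data(generate_pt_cohort(60, seed=2), seed=0)
    spec = ArchitectureSpec(8, 4, 4, 8, head="v0", n_classes=pt["train"].y.shape[1])
    model = build_model(spec, seed=0)
    cfg = _cfg(max_epochs=3, early_stop_patience=2, loss="multilabel_bce")
    state, hist = pretrain(model, pt["train"], pt["validation"], cfg)
    tl = hist["train_loss"]
    assert len(tl) == 3 and tl[0] > tl[1] > tl[2]
    assert "manifest" in hist and hist["manifest"]["config_hash"]


def test_pretrain_requires_v0_head(toy_model, tiny_ft, tiny_ft_val):
    with pytest.raises(ValueError, match="v0"):
        pretrain(toy_model, None, None, _cfg())


def test_select_best_k_argmax_and_tie_rule():
    assert select_best_k({0: [0.90], 1: [0.95], 2: [0.93]}) == 1
    assert select_best_k({1: [0.95, 0.95], 3: [0.95, 0.95]}) == 1  # tie -> smaller k
    assert select_best_k({0: [0.5, 0.7], 2: [0.65, 0.55]}) == 0


def test_freezing_sweep_smoke(toy_spec, tiny_ft, tiny_ft_val):
    source = build_model(toy_spec, seed=9).state_dict()
    cfg = _cfg(seed=1)
    res = freezing_sweep(source, toy_spec, tiny_ft, tiny_ft_val, (0, 4), cfg)
    assert set(res.mean_mf1) == {0, 4}
    assert all(np.isfinite(v) for v in res.mean_mf1.values())
    assert res.selected_k in (0, 4)
    with pytest.raises(ValueError, match="empty"):
        freezing_sweep(source, toy_spec, tiny_ft, tiny_ft_val, (), cfg)


def test_checkpoint_round_trip(tmp_path, toy_model):
    state = toy_model.state_dict()
    save_checkpoint(state, tmp_path / "ck.npz")
    back = load_checkpoint(tmp_path / "ck.npz")
    assert set(back) == set(state)
    assert all(np.array_equal(state[k], back[k]) for k in state)
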