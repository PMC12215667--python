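"""Architecture reconstruction: parameter accounting, temporal contract,
head behavior, and an end-to-end analytic-vs-numeric gradient check."""

import numpy as np
import pytest

from ltadetect.ecgnet import (
    ArchitectureSpec,
    build_model,
    count_parameters,
    predict_segments,
)


@pytest.mark.parametrize("size,millions", [("L", 10.5), ("M", 7.7), ("S", 4.9)])
def test_parameter_counts_match_published_sizes(size, millions):
    spec = ArchitectureSpec.for_size(size, head="v1")
    assert round(count_parameters(spec) / 1e6, 1) == millions


def test_structural_count_equals_built_model_count(toy_spec):
    model = build_model(toy_spec, seed=0)
    assert model.count_parameters() == count_parameters(toy_spec)
    spec_s = ArchitectureSpec.for_size("S", head="v1")
    assert build_model(spec_s, seed=0).count_parameters() == count_parameters(spec_s)


def test_toy_spec_hand_counted_total(toy_spec):
    """Layer-by-layer closed-form count for the 8-block/4-filter/kernel-8 toy."""
    stem = 1 * 8 * 4 + 4 + 2 * 4  # conv W+b, BN gamma+beta
    b_same4 = (2 * 4) + (4 * 8 * 4 + 4) + (2 * 4) + (4 * 8 * 4 + 4)  # 4->4 block
    b_trans = (2 * 4) + (4 * 8 * 8 + 8) + (2 * 8) + (8 * 8 * 8 + 8)  # 4->8 block
    b_same8 = (2 * 8) + (8 * 8 * 8 + 8) + (2 * 8) + (8 * 8 * 8 + 8)  # 8->8 block
    final = 2 * 8 + (8 * 2 + 2)  # final BN + head
    expected = stem + 4 * b_same4 + b_trans + 3 * b_same8 + final
    assert count_parameters(toy_spec) == expected


@pytest.mark.parametrize("n_segments", [7, 14])
def test_one_output_step_per_256_samples(toy_model, n_segments):
    x = np.random.default_rng(0).normal(size=n_segments * 256).astype(np.float32)
    assert predict_segments(toy_model, x).step_scores.shape == (n_segments, 2)


def test_input_length_and_nan_guards(toy_model):
    with pytest.raises(ValueError, match="multiple of 256"):
        toy_model.forward(np.zeros(1000, dtype=np.float32))
    bad = np.zeros(1792, dtype=np.float32)
    bad[5] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        toy_model.forward(bad)


def test_same_seed_same_initial_weights(toy_spec):
    a = build_model(toy_spec, seed=7)
    b = build_model(toy_spec, seed=7)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)
    c = build_model(toy_spec, seed=8)
    assert any(not np.array_equal(pa.value, pc.value)
               for pa, pc in zip(a.params(), c.params()))


def test_inference_is_deterministic(toy_model):
    x = np.random.default_rng(1).normal(size=1792).astype(np.float32)
    p1 = predict_segments(toy_model, x).step_scores
    p2 = predict_segments(toy_model, x).step_scores
    assert np.array_equal(p1, p2)


def test_v1_step_scores_are_a_distribution(toy_model):
    x = np.random.default_rng(2).normal(size=1792).astype(np.float32)
    scores = predict_segments(toy_model, x).step_scores
    assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(scores >= 0)


def test_v0_pooled_score_is_max_over_steps():
    spec = ArchitectureSpec(8, 4, 4, 8, head="v0", n_classes=5)
    model = build_model(spec, seed=0)
    x = np.random.default_rng(3).normal(size=3584).astype(np.float32)
    pred = predict_segments(model, x)
    assert np.allclose(pred.pooled_scores, pred.step_scores.max(axis=0))


def test_v0_v1_backbones_share_all_shapes(toy_spec):
    v1 = build_model(toy_spec, seed=0)
    v0 = build_model(
        ArchitectureSpec(8, 4, 4, 8, head="v0", n_classes=10), seed=0
    )
    p1 = {p.name: p.value.shape for p in v1.params() if not p.name.startswith("head.")}
    p0 = {p.name: p.value.shape for p in v0.params() if not p.name.startswith("head.")}
    assert p0 == p1
    assert v0.head.w.value.shape != v1.head.w.value.shape


def test_output_depends_on_matching_segment(toy_model):
    """Changing one segment's content changes that segment's score."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=1792).astype(np.float32)
    base = toy_model.forward(x)[0]
    x2 = x.copy()
    x2[3 * 256 : 4 * 256] += 3.0
    changed = toy_model.forward(x2)[0]
    assert not np.allclose(base[3], changed[3])  # untrained logits must move


def test_full_model_gradients_match_finite_differences():
    """End-to-end analytic backprop vs central differences on a dropout-free
    toy network (covers conv, batch-norm batch statistics, pooling, residual
    shortcuts and the softmax head)."""
    spec = ArchitectureSpec(8, 4, 4, 8, dropout_p=0.0, head="v1")
    model = build_model(spec, seed=11)
    rng = np.random.default_rng(5)
    x = rng.normal(size=(2, 1792)).astype(np.float32)
    labels = rng.integers(0, 2, size=(2, 7))

    def loss_value():
        logits = model.forward(x, training=True)
        return model.loss_v1(logits, labels)[0]

    logits = model.forward(x, training=True)
    loss, dl = model.loss_v1(logits, labels)
    for p in model.params():
        p.zero_grad()
    model.backward(dl)

    checked = 0
    eps = 1e-3  # early layers sit in a high-curvature region; keep steps small
    for p in model.params():
        if p.name not in ("stem.conv.w", "block04.conv1.w", "head.fc.w", "final.bn.gamma"):
            continue
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        idx = int(np.argmax(np.abs(gflat)))  # check the most sensitive entry
        orig = flat[idx]
        flat[idx] = orig + eps
        lp = loss_value()
        flat[idx] = orig - eps
        lm = loss_value()
        flat[idx] = orig
        num = (lp - lm) / (2 * eps)
        assert num == pytest.approx(gflat[idx], rel=0.08, abs=1e-4), p.name
        checked += 1
    assert checked == 4
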