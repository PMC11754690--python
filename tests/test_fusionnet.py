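import numpy as np
import pandas as pd
import pytest

from holoflow import (
    BackboneConfig,
    FusionModel,
    SplitSpec,
    TrainConfig,
    evaluate,
    initialize_from_single_view,
    make_splits,
    paired_one_sided_pvalue,
    train,
)

TINY = BackboneConfig(
    input_size=16, stem_channels=4, stem_pool=1,
    block_channels=(8,), block_strides=(2,), latent_dim=8,
)


def tiny_data(n=48, k=1, side=16, seed=0, separation=2.0):
    """Two linearly separable blob classes of (n, k, 1, side, side) images."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    x = rng.normal(size=(n, k, 1, side, side)).astype(np.float32)
    x[y == 1, :, :, 4:10, 4:10] += separation
    return x, y.astype(np.int64)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_make_splits_disjoint_and_stratified():
    labels = np.repeat([0, 1, 2], 50)
    split = make_splits(labels, fold=0)
    idx = np.concatenate([split.train, split.val, split.test])
    assert sorted(idx.tolist()) == list(range(150))  # partition, no leakage
    assert len(split.train) == 120 and len(split.val) == 15 and len(split.test) == 15
    for part in (split.train, split.val, split.test):
        counts = np.bincount(labels[part], minlength=3)
        assert np.all(counts == counts[0])  # stratified


def test_make_splits_folds_cycle_disjoint():
    labels = np.repeat([0, 1, 2], 50)
    held = [set(np.concatenate([make_splits(labels, fold=f).val,
                                make_splits(labels, fold=f).test]).tolist())
            for f in range(5)]
    for i in range(5):
        for j in range(i + 1, 5):
            assert not held[i] & held[j]
    assert set().union(*held) == set(range(150))


def test_make_splits_deterministic_and_validated():
    labels = np.repeat([0, 1], 40)
    a, b = make_splits(labels, fold=2), make_splits(labels, fold=2)
    assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)
    with pytest.raises(ValueError, match="fold"):
        make_splits(labels, fold=5)


def test_splitspec_rejects_overlap():
    with pytest.raises(ValueError, match="overlap"):
        SplitSpec(train=np.array([0, 1]), val=np.array([1]), test=np.array([2]))


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

def test_forward_shape_and_validation():
    model = FusionModel(2, TINY, seed=0)
    x, _ = tiny_data(n=6, k=2)
    logits = model.forward(x)
    assert logits.shape == (6, 3)
    with pytest.raises(ValueError, match="expected input"):
        model.forward(x[:, :1])
    with pytest.raises(ValueError, match="n_views"):
        FusionModel(0, TINY)


def test_parameter_count_linear_in_k():
    counts = [FusionModel(k, TINY, seed=0).n_parameters for k in (1, 2, 3)]
    assert counts[2] - counts[1] == counts[1] - counts[0]
    assert counts[1] > counts[0]


def test_share_weights_reduces_parameters():
    independent = FusionModel(3, TINY, seed=0)
    shared = FusionModel(3, TINY, seed=0, share_weights=True)
    assert len(shared.backbones) == 1
    assert shared.n_parameters < independent.n_parameters
    x, _ = tiny_data(n=4, k=3)
    assert shared.forward(x).shape == (4, 3)
    # shared-backbone output is permutation-covariant in a concrete sense:
    # feeding identical views gives identical per-view latent contributions
    same = np.repeat(x[:, :1], 3, axis=1)
    p = shared.predict_proba(same)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_initialize_from_single_view():
    source = FusionModel(1, TINY, seed=1)
    model = FusionModel(3, TINY, seed=2)
    initialize_from_single_view(model, source)
    for b in model.backbones:
        for d, s in zip(b.parameters(), source.backbones[0].parameters()):
            assert np.array_equal(d.value, s.value)
    with pytest.raises(ValueError, match="single-view"):
        initialize_from_single_view(model, FusionModel(2, TINY, seed=0))


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def test_training_learns_separable_problem():
    x, y = tiny_data(n=48)
    model = FusionModel(1, TINY, n_classes=2, seed=0)
    cfg = TrainConfig(batch_size=8, learning_rate=5e-3, epochs=25, seed=0)
    history = train(model, x, y, cfg)
    assert list(history.columns) == ["epoch", "train_loss", "train_accuracy"]
    assert len(history) == 25
    assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]
    assert history["train_accuracy"].iloc[-1] >= 0.9


def test_training_bitwise_deterministic():
    x, y = tiny_data(n=32)
    cfg = TrainConfig(batch_size=8, epochs=4, seed=3)
    runs = []
    for _ in range(2):
        model = FusionModel(1, TINY, n_classes=2, seed=3)
        runs.append((train(model, x, y, cfg), model.get_weights()))
    pd.testing.assert_frame_equal(runs[0][0], runs[1][0])
    for a, b in zip(runs[0][1], runs[1][1]):
        assert np.array_equal(a, b)


def test_validation_history_and_best_restore():
    x, y = tiny_data(n=48)
    model = FusionModel(1, TINY, n_classes=2, seed=0)
    cfg = TrainConfig(batch_size=8, epochs=6, seed=0)
    history = train(model, x[:32], y[:32], cfg, x_val=x[32:], y_val=y[32:])
    assert {"val_loss", "val_accuracy"} <= set(history.columns)
    best = history["val_accuracy"].max()
    result = evaluate(model, x[32:], y[32:])
    assert result["accuracy"] == pytest.approx(best)  # best weights restored


def test_evaluate_confusion_consistency():
    x, y = tiny_data(n=30)
    model = FusionModel(1, TINY, n_classes=2, seed=0)
    result = evaluate(model, x, y)
    conf = result["confusion"]
    assert conf.shape == (2, 2)
    assert conf.sum() == result["n"] == 30
    assert np.trace(conf) / conf.sum() == pytest.approx(result["accuracy"])
    assert np.all(conf.sum(axis=1) == np.bincount(y))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_paired_pvalue_behavior():
    a = np.array([0.9, 0.92, 0.95, 0.91, 0.93])
    b = a - 0.1
    assert paired_one_sided_pvalue(a, b) < 0.01
    assert paired_one_sided_pvalue(b, a) > 0.95
    assert paired_one_sided_pvalue(a, a) == 1.0
    with pytest.raises(ValueError):
        paired_one_sided_pvalue(a, b[:3])
    with pytest.raises(ValueError):
        paired_one_sided_pvalue([1.0], [0.5])
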