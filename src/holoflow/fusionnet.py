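"""Multi-head late-fusion classifier over K projections of one cell.

Each of the K views is encoded by its *own* lightweight convolutional
backbone (MobileNetV2-style: a strided stem convolution followed by
inverted-residual bottleneck blocks, global average pooling and a dense
latent layer).  The K latent vectors are concatenated and a single dense
softmax head produces the class probabilities, so fusion happens late, at
the feature level, and the parameter count grows linearly with K.

The module also provides deterministic per-class train/val/test splits,
a plain minibatch training loop with per-epoch history and best-validation
weight selection, evaluation (accuracy, confusion matrix, per-class
recall), and ``projection_sweep`` — the accuracy-versus-K experiment over
several seeds that quantifies the value of additional projections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .datasets import ProjectionDataset

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "PAPER_TRAINING_STAGES",
    "SplitSpec",
    "FusionModel",
    "initialize_from_single_view",
    "make_splits",
    "train",
    "evaluate",
    "projection_sweep",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of one per-view backbone.

    ``block_channels``/``block_strides`` describe the inverted-residual
    stack after the stem; blocks with stride 1 and unchanged width carry an
    identity shortcut.  The default is a deliberately small desk-scale
    network (a width-reduced MobileNetV2) that trains in seconds on a CPU.
    """

    input_size: int = 134
    in_channels: int = 1
    stem_channels: int = 8
    stem_pool: int = 2
    block_channels: tuple[int, ...] = (16, 24, 24)
    block_strides: tuple[int, ...] = (2, 2, 1)
    expansion: int = 2
    latent_dim: int = 16
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if len(self.block_channels) != len(self.block_strides):
            raise ValueError("block_channels and block_strides must have equal length")
        if self.stem_pool < 1:
            raise ValueError("stem_pool must be >= 1")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")

    def scaled(self, channels: int) -> int:
        """Channel count after the width multiplier (floor of 4)."""
        return max(4, int(round(channels * self.width_multiplier)))


@dataclass(frozen=True)
class TrainConfig:
    """One training stage: plain Adam with a constant learning rate.

    The defaults are the desk-scale recipe (small batches give enough
    optimizer steps on a few hundred cells); ``PAPER_TRAINING_STAGES`` holds
    the full-scale schedule.
    """

    batch_size: int = 16
    learning_rate: float = 2e-3
    epochs: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


#: The three-stage schedule used for full-scale training runs (batch size,
#: learning rate, epochs per stage).
PAPER_TRAINING_STAGES: tuple[TrainConfig, ...] = (
    TrainConfig(batch_size=64, learning_rate=5e-4, epochs=10),
    TrainConfig(batch_size=64, learning_rate=1e-4, epochs=20),
    TrainConfig(batch_size=64, learning_rate=1e-6, epochs=30),
)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint cell-level train/validation/test index sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.train.tolist()), set(self.val.tolist()), set(self.test.tolist())]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test index sets overlap")


def _build_backbone(cfg: BackboneConfig, rng: np.random.Generator) -> nn.Sequential:
    stem = cfg.scaled(cfg.stem_channels)
    layers: list[nn.Layer] = [
        nn.Conv2d(cfg.in_channels, stem, 3, stride=2, rng=rng),
        nn.ReLU6(),
    ]
    if cfg.stem_pool > 1:
        layers.append(nn.AvgPool2d(cfg.stem_pool))
    c = stem
    for width, stride in zip(cfg.block_channels, cfg.block_strides):
        width = cfg.scaled(width)
        layers.append(nn.InvertedResidual(c, width, stride=stride, expansion=cfg.expansion, rng=rng))
        c = width
    layers += [nn.ReLU6(), nn.GlobalAvgPool(), nn.Dense(c, cfg.latent_dim, rng=rng), nn.ReLU6()]
    return nn.Sequential(*layers)


class FusionModel:
    """K independent backbones -> concatenated latents -> softmax head."""

    def __init__(
        self,
        n_views: int,
        backbone: BackboneConfig = BackboneConfig(),
        n_classes: int = 3,
        seed: int | np.random.Generator = 0,
        share_weights: bool = False,
    ) -> None:
        if n_views < 1:
            raise ValueError("n_views must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.n_views = n_views
        self.n_classes = n_classes
        self.backbone_config = backbone
        self.share_weights = share_weights
        n_distinct = 1 if share_weights else n_views
        self.backbones = [_build_backbone(backbone, rng) for _ in range(n_distinct)]
        self.head = nn.Dense(backbone.latent_dim * n_views, n_classes, rng=rng)

    def parameters(self) -> list[nn.Parameter]:
        params = [p for b in self.backbones for p in b.parameters()]
        return params + self.head.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, K, 1, H, W) -> logits (N, n_classes)."""
        if x.ndim != 5 or x.shape[1] != self.n_views:
            raise ValueError(
                f"expected input of shape (N, {self.n_views}, 1, H, W), got {x.shape}"
            )
        if self.share_weights:
            # One batched pass through the single backbone keeps its layer
            # caches valid for the backward pass.
            n, k = x.shape[:2]
            flat = x.reshape((n * k,) + x.shape[2:])
            lat = self.backbones[0].forward(flat)
            self._latent_dim = lat.shape[1]
            return self.head.forward(lat.reshape(n, k * lat.shape[1]))
        latents = [b.forward(x[:, v]) for v, b in enumerate(self.backbones)]
        self._latent_dim = latents[0].shape[1]
        return self.head.forward(np.concatenate(latents, axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dcat = self.head.backward(dlogits)
        d = self._latent_dim
        if self.share_weights:
            n = dcat.shape[0]
            self.backbones[0].backward(dcat.reshape(n * self.n_views, d))
            return
        for v, b in enumerate(self.backbones):
            b.backward(dcat[:, v * d : (v + 1) * d])

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            out.append(nn.softmax(self.forward(x[start : start + batch_size])))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value[...] = w


def initialize_from_single_view(model: FusionModel, source: FusionModel) -> None:
    """Copy a (pre)trained single-view backbone's weights into every head of
    ``model``.  The fusion head keeps its fresh initialization (its width
    depends on K).  Both models must use the same backbone architecture."""
    if source.n_views != 1:
        raise ValueError("source must be a single-view model")
    src = source.backbones[0].parameters()
    for b in model.backbones:
        dst = b.parameters()
        if len(dst) != len(src) or any(d.value.shape != s.value.shape for d, s in zip(dst, src)):
            raise ValueError("backbone architectures differ")
        for d, s in zip(dst, src):
            d.value[...] = s.value


def make_splits(
    labels: np.ndarray,
    fold: int = 0,
    n_folds: int = 5,
    seed: int = 0,
) -> SplitSpec:
    """Deterministic stratified split.

    Cells of each class are shuffled once (by ``seed``) and partitioned into
    ``n_folds`` disjoint folds.  Fold ``fold`` is held out and divided into
    equal validation and test halves; the remaining folds form the training
    set.  With the default 5 folds this yields an 80/10/10 split, and
    varying ``fold`` cycles through 5 non-overlapping held-out sets.
    """
    labels = np.asarray(labels)
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold must lie in [0, {n_folds}), got {fold}")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        parts = np.array_split(idx, n_folds)
        held = parts[fold]
        train.extend(np.concatenate([p for f, p in enumerate(parts) if f != fold]))
        val.extend(held[: held.size // 2])
        test.extend(held[held.size // 2 :])
    return SplitSpec(
        train=np.sort(np.array(train)), val=np.sort(np.array(val)), test=np.sort(np.array(test))
    )


def train(
    model: FusionModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig = TrainConfig(),
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    restore_best: bool = True,
) -> pd.DataFrame:
    """Minibatch Adam training; returns the per-epoch history.

    The history has columns epoch, train_loss, train_accuracy and — when a
    validation set is given — val_loss, val_accuracy.  With ``restore_best``
    the weights from the epoch with the highest validation accuracy are
    restored at the end.  Fully deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    n = x_train.shape[0]
    rows = []
    best_acc, best_weights = -1.0, None
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            logits = model.forward(xb)
            loss, dlogits, probs = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(batch))
            hits += int((probs.argmax(axis=1) == yb).sum())
        row = {
            "epoch": epoch,
            "train_loss": float(np.sum(losses) / n),
            "train_accuracy": hits / n,
        }
        if x_val is not None and y_val is not None:
            probs = model.predict_proba(x_val, config.batch_size)
            val_loss = float(-np.log(probs[np.arange(len(y_val)), y_val] + 1e-12).mean())
            val_acc = float((probs.argmax(axis=1) == y_val).mean())
            row.update(val_loss=val_loss, val_accuracy=val_acc)
            if restore_best and val_acc > best_acc:
                best_acc, best_weights = val_acc, model.get_weights()
        rows.append(row)
    if best_weights is not None:
        model.set_weights(best_weights)
    return pd.DataFrame(rows)


def evaluate(model: FusionModel, x: np.ndarray, y: np.ndarray) -> dict:
    """Accuracy, confusion matrix (rows: true class) and per-class recall."""
    pred = model.predict(x)
    y = np.asarray(y)
    k = model.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    with np.errstate(invalid="ignore"):
        recall = np.where(
            confusion.sum(axis=1) > 0,
            np.diag(confusion) / np.maximum(confusion.sum(axis=1), 1),
            np.nan,
        )
    return {
        "accuracy": float((pred == y).mean()),
        "confusion": confusion,
        "per_class_recall": recall,
        "n": int(y.size),
    }


def paired_one_sided_pvalue(a, b) -> float:
    """P-value of the one-sided paired t-test for mean(a - b) > 0.

    Used for the accuracy-versus-K and hologram-versus-OPD comparisons,
    pairing runs by seed.  Degenerate case: if every pair is identical the
    test is uninformative and p = 1 is returned.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples with at least 2 pairs")
    if np.allclose(a, b):
        return 1.0
    return float(stats.ttest_rel(a, b, alternative="greater").pvalue)


def projection_sweep(
    dataset: ProjectionDataset,
    k_values: tuple[int, ...] = (1, 3, 5),
    domain: str = "hologram",
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    train_config: TrainConfig = TrainConfig(),
    backbone: BackboneConfig = BackboneConfig(),
    n_folds: int = 5,
    center_crop: int | None = None,
) -> pd.DataFrame:
    """Accuracy versus number of fused projections K.

    For every (K, seed) pair a fresh K-head model is trained from scratch;
    the seed selects the held-out fold (``seed % n_folds``), the weight
    initialization and the batch order, so repeated seeds probe both data
    and training variability.  Returns one row per run with the held-out
    test accuracy.
    """
    rows = []
    for k in k_values:
        x_all = dataset.views(domain, k, center_crop)
        for seed in seeds:
            split = make_splits(dataset.labels, fold=seed % n_folds)
            model = FusionModel(k, backbone, seed=seed)
            cfg = replace(train_config, seed=seed)
            history = train(
                model,
                x_all[split.train],
                dataset.labels[split.train],
                cfg,
                x_val=x_all[split.val],
                y_val=dataset.labels[split.val],
            )
            result = evaluate(model, x_all[split.test], dataset.labels[split.test])
            rows.append(
                {
                    "domain": domain,
                    "rolling": dataset.config.rolling,
                    "k": k,
                    "seed": seed,
                    "test_accuracy": result["accuracy"],
                    "n_test": result["n"],
                    "final_train_accuracy": float(history["train_accuracy"].iloc[-1]),
                    "n_parameters": model.n_parameters,
                }
            )
    return pd.DataFrame(rows)
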