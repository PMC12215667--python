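"""The ECGnet residual CNN family for per-segment rhythm classification.

The backbone is a 1-D residual network over single-lead ECG at 200 Hz: an
initial convolution, then ``n`` pre-activation residual blocks (BN - ReLU -
conv, twice, the second convolution preceded by dropout 0.2), a final
BN - ReLU, and a time-distributed fully connected head applied to every
temporal slice with shared weights.  Convolution kernels are 16 samples;
filters start at 32 and double periodically; 2x temporal subsampling is
applied at selected blocks' inputs (shared by the residual and shortcut
paths, the shortcut additionally zero-padding channels at doubling blocks)
so that 1792 input samples map to exactly 7 output steps — one prediction
per 256-sample (1.28 s) segment.  Any input whose length is a multiple of
256 is accepted and yields one output step per segment.

Three sizes trade parameters for accuracy:

========  ========  ===============  ==============
size      blocks    doubling period  subsampled at
========  ========  ===============  ==============
L         16        4                every 2nd block
M         12        3                2 of every 3
S         8         2                every block
========  ========  ===============  ==============

Each size performs eight 2x subsamplings (256x total).  Two heads exist:
``v1`` emits a per-step 2-class softmax (LTA vs Other); ``v0`` emits
per-step sigmoid probabilities for ``n_classes`` rhythm labels and pools
them with a global max over time for whole-recording multi-label targets.
v0 and v1 share the entire backbone (all layers except the last two), which
is what makes pre-train -> transfer possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm1d, Conv1d, Dropout, MaxPool1d, Param, ReLU, TimeDistributedDense

__all__ = [
    "ArchitectureSpec",
    "SegmentPrediction",
    "ResidualBlock",
    "ECGNet",
    "build_model",
    "count_parameters",
    "predict_segments",
]

SEGMENT_LEN = 256
TOTAL_SUBSAMPLING = 256  # 2^8


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural description of one ECGnet variant."""

    n_blocks: int = 16
    initial_filters: int = 32
    doubling_period: int = 4
    kernel: int = 16
    dropout_p: float = 0.2
    head: str = "v1"  # "v0" (multi-label sigmoid + global max pool) or "v1" (binary softmax)
    n_classes: int = 2
    subsample_blocks: tuple[int, ...] = None  # block indices with 2x input subsampling

    def __post_init__(self) -> None:
        if self.head not in ("v0", "v1"):
            raise ValueError("head must be 'v0' or 'v1'")
        if self.head == "v1" and self.n_classes != 2:
            raise ValueError("v1 head is binary (n_classes = 2)")
        if self.subsample_blocks is None:
            object.__setattr__(self, "subsample_blocks", self._default_subsampling())
        if 2 ** len(self.subsample_blocks) != TOTAL_SUBSAMPLING:
            raise ValueError(
                f"{len(self.subsample_blocks)} subsamplings cannot map 1792 samples to 7 steps"
            )
        if any(not 0 <= b < self.n_blocks for b in self.subsample_blocks):
            raise ValueError("subsample block index out of range")

    def _default_subsampling(self) -> tuple[int, ...]:
        n_sub = 8
        if self.n_blocks == 2 * n_sub:  # L: every alternate block
            return tuple(range(0, self.n_blocks, 2))
        if self.n_blocks == n_sub:  # S: every block
            return tuple(range(self.n_blocks))
        # M and friends: skip the first block of each doubling stage
        cand = [i for i in range(self.n_blocks) if i % self.doubling_period != 0]
        if len(cand) == n_sub:
            return tuple(cand)
        raise ValueError(
            f"no default subsampling pattern for {self.n_blocks} blocks; pass subsample_blocks"
        )

    def filters_at(self, block: int) -> int:
        return self.initial_filters * 2 ** (block // self.doubling_period)

    @property
    def final_filters(self) -> int:
        return self.filters_at(self.n_blocks - 1)

    @classmethod
    def for_size(cls, size: str, head: str = "v1", n_classes: int = 2,
                 kernel: int = 16, dropout_p: float = 0.2) -> "ArchitectureSpec":
        table = {"L": (16, 4), "M": (12, 3), "S": (8, 2)}
        if size not in table:
            raise ValueError("size must be 'L', 'M' or 'S'")
        n_blocks, period = table[size]
        return cls(n_blocks, 32, period, kernel, dropout_p, head, n_classes)


@dataclass
class SegmentPrediction:
    """Per-segment class scores, plus the pooled scores for v0 models."""

    step_scores: np.ndarray  # (T, n_classes); v1 rows sum to 1
    pooled_scores: np.ndarray | None = None  # (n_classes,) = max over steps (v0)

    @property
    def labels(self) -> np.ndarray:
        """v1 convenience: per-step argmax (1 = LTA)."""
        return np.argmax(self.step_scores, axis=-1)


class ResidualBlock:
    """Pre-activation residual block, optional 2x input subsampling.

    Subsampling pools both the residual and the shortcut path; channel
    doubling zero-pads the shortcut.  Freezing the block stops parameter
    updates and pins its batch-norm layers to their running statistics.
    """

    def __init__(self, cin: int, cout: int, spec: ArchitectureSpec,
                 subsample: bool, rng: np.random.Generator, drop_rng: np.random.Generator,
                 name: str):
        self.cin, self.cout, self.subsample = cin, cout, subsample
        self.pool = MaxPool1d() if subsample else None
        self.bn1 = BatchNorm1d(cin, f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv1d(cin, cout, spec.kernel, rng, f"{name}.conv1")
        self.bn2 = BatchNorm1d(cout, f"{name}.bn2")
        self.relu2 = ReLU()
        self.drop = Dropout(spec.dropout_p, drop_rng)
        self.conv2 = Conv1d(cout, cout, spec.kernel, rng, f"{name}.conv2")
        self.name = name

    @property
    def layers(self) -> list:
        return [self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.drop, self.conv2]

    def params(self) -> list[Param]:
        return [p for lay in self.layers for p in lay.params()]

    def set_frozen(self, frozen: bool) -> None:
        for p in self.params():
            p.trainable = not frozen
        self.bn1.frozen = frozen
        self.bn2.frozen = frozen

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.pool is not None:
            x = self.pool.forward(x, training)
        h = x
        for lay in self.layers:
            h = lay.forward(h, training)
        if self.cout > self.cin:
            pad = np.zeros(x.shape[:2] + (self.cout - self.cin,), dtype=x.dtype)
            sc = np.concatenate([x, pad], axis=2)
        else:
            sc = x
        return h + sc

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = dy
        for lay in reversed(self.layers):
            dh = lay.backward(dh)
        dx = dh + (dy[:, :, : self.cin] if self.cout > self.cin else dy)
        if self.pool is not None:
            dx = self.pool.backward(dx)
        return dx


class ECGNet:
    """A built ECGnet model (backbone + head) with training machinery."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        ss = np.random.SeedSequence(entropy=(int(seed), 0x5EC6))
        init_rng, self.drop_rng = (np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(2))
        self.input_conv = Conv1d(1, spec.initial_filters, spec.kernel, init_rng, "stem.conv")
        self.input_bn = BatchNorm1d(spec.initial_filters, "stem.bn")
        self.input_relu = ReLU()
        self.blocks: list[ResidualBlock] = []
        cin = spec.initial_filters
        for i in range(spec.n_blocks):
            cout = spec.filters_at(i)
            self.blocks.append(
                ResidualBlock(cin, cout, spec, i in spec.subsample_blocks,
                              init_rng, self.drop_rng, f"block{i:02d}")
            )
            cin = cout
        self.final_bn = BatchNorm1d(cin, "final.bn")
        self.final_relu = ReLU()
        self.head = TimeDistributedDense(cin, spec.n_classes, init_rng, "head.fc")
        self.n_frozen_blocks = 0

    # -- parameter plumbing -------------------------------------------------

    def backbone_layers(self) -> list:
        out = [self.input_conv, self.input_bn]
        for b in self.blocks:
            out += [b.bn1, b.conv1, b.bn2, b.conv2]
        out.append(self.final_bn)
        return out

    def params(self) -> list[Param]:
        out = self.input_conv.params() + self.input_bn.params()
        for b in self.blocks:
            out += b.params()
        return out + self.final_bn.params() + self.head.params()

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def freeze_blocks(self, k: int) -> None:
        """Freeze the first ``k`` residual blocks (weights + BN statistics)."""
        if not 0 <= k <= self.spec.n_blocks - 1:
            raise ValueError(f"k must be in [0, {self.spec.n_blocks - 1}]")
        for i, b in enumerate(self.blocks):
            b.set_frozen(i < k)
        self.n_frozen_blocks = k

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value.copy() for p in self.params()}
        for lay in self.backbone_layers():
            if isinstance(lay, BatchNorm1d):
                for k, v in lay.state().items():
                    out[f"{lay.gamma.name.rsplit('.', 1)[0]}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        byname = {p.name: p for p in self.params()}
        for name, val in state.items():
            if name.endswith(("run_mean", "run_var")):
                prefix, stat = name.rsplit(".", 1)
                for lay in self.backbone_layers():
                    if isinstance(lay, BatchNorm1d) and lay.gamma.name.startswith(prefix + "."):
                        setattr(lay, stat, val.copy().astype(np.float32))
            elif name in byname:
                p = byname[name]
                if p.value.shape != val.shape:
                    raise ValueError(f"shape mismatch for {name}: {p.value.shape} vs {val.shape}")
                p.value[...] = val

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :, None]
        elif x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] % SEGMENT_LEN != 0:
            raise ValueError(f"input length {x.shape[1]} is not a multiple of {SEGMENT_LEN}")
        if not np.isfinite(x).all():
            raise ValueError("input contains NaN or infinite samples")
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-step head logits, shape (N, L/256, n_classes)."""
        h = self._check_input(x)
        h = self.input_conv.forward(h, training)
        h = self.input_bn.forward(h, training)
        h = self.input_relu.forward(h, training)
        for b in self.blocks:
            h = b.forward(h, training)
        h = self.final_bn.forward(h, training)
        h = self.final_relu.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.final_relu.backward(g)
        g = self.final_bn.backward(g)
        for b in reversed(self.blocks):
            g = b.backward(g)
        g = self.input_relu.backward(g)
        g = self.input_bn.backward(g)
        self.input_conv.backward(g)

    # -- losses -------------------------------------------------------------

    def loss_v1(self, logits: np.ndarray, labels: np.ndarray,
                mask: np.ndarray | None = None,
                class_weights: tuple[float, float] | None = None
                ) -> tuple[float, np.ndarray]:
        """Masked per-step 2-class cross-entropy; returns (loss, dlogits)."""
        n, T, c = logits.shape
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=-1, keepdims=True)
        m = np.ones((n, T), dtype=bool) if mask is None else mask.astype(bool)
        w = np.where(m, 1.0, 0.0)
        if class_weights is not None:
            cw = np.asarray(class_weights, dtype=np.float64)
            w = w * cw[labels]
        tot = w.sum()
        if tot == 0:
            raise ValueError("no valid segments in batch")
        idx = np.eye(c, dtype=np.float64)[labels]
        ll = -np.log(np.clip((p * idx).sum(-1), 1e-12, None))
        loss = float((ll * w).sum() / tot)
        dlogits = ((p - idx) * w[..., None] / tot).astype(np.float32)
        return loss, dlogits

    def loss_v0(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        """Multi-label BCE on globally max-pooled per-step probabilities.

        Pooling is on logits (sigmoid is monotone, so the pooled probability
        equals the max over per-step probabilities); gradients flow to the
        argmax step of each class.
        """
        n, T, c = logits.shape
        arg = logits.argmax(axis=1)  # (N, C)
        pooled = np.take_along_axis(logits, arg[:, None, :], axis=1)[:, 0, :]
        p = 1.0 / (1.0 + np.exp(-np.clip(pooled, -60.0, 60.0)))
        y = targets.astype(np.float64)
        loss = float(-np.mean(y * np.log(np.clip(p, 1e-12, None))
                              + (1 - y) * np.log(np.clip(1 - p, 1e-12, None))))
        dpooled = (p - y) / (n * c)
        dlogits = np.zeros_like(logits)
        np.put_along_axis(dlogits, arg[:, None, :], dpooled[:, None, :].astype(np.float32), axis=1)
        return loss, dlogits

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)


# ---------------------------------------------------------------------------
# module-level operations


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ECGNet:
    """Construct an ECGnet with deterministic initialization under ``seed``."""
    return ECGNet(spec, seed)


def _structural_params(spec: ArchitectureSpec) -> int:
    k = spec.kernel
    total = 1 * k * spec.initial_filters + spec.initial_filters  # stem conv
    total += 2 * spec.initial_filters  # stem BN
    cin = spec.initial_filters
    for i in range(spec.n_blocks):
        cout = spec.filters_at(i)
        total += 2 * cin  # bn1
        total += cin * k * cout + cout  # conv1
        total += 2 * cout  # bn2
        total += cout * k * cout + cout  # conv2
        cin = cout
    total += 2 * cin  # final BN
    total += cin * spec.n_classes + spec.n_classes  # head
    return total


def count_parameters(spec: ArchitectureSpec) -> int:
    """Trainable parameter count (convolutions, batch norm, head)."""
    return _structural_params(spec)


def predict_segments(model: ECGNet, waveform: np.ndarray) -> SegmentPrediction:
    """Deterministic inference: per-segment scores for one standardized waveform."""
    logits = model.forward(waveform, training=False)[0]
    if model.spec.head == "v1":
        z = logits - logits.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return SegmentPrediction(ez / ez.sum(axis=-1, keepdims=True))
    p = 1.0 / (1.0 + np.exp(-logits))
    return SegmentPrediction(p, pooled_scores=p.max(axis=0))
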