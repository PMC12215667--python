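"""Training protocols: scratch, pre-train, transfer, partially-frozen fine-tune.

The transfer protocol mirrors the two-stage recipe the package is built
around: a v0 model is pre-trained on a large multi-label rhythm corpus
(binary cross-entropy on globally max-pooled per-step probabilities), its
backbone weights — everything except the last two layers — are copied into
a fresh v1 binary detector, and the v1 model is fine-tuned on the scarce
LTA-annotated set with the first ``k`` residual blocks frozen.  Freezing is
exact: frozen blocks neither receive optimizer updates nor update their
batch-norm running statistics, so their tensors are bit-identical before
and after fine-tuning.  The optimal ``k`` is selected by a sweep over
freezing configurations, scored by mean validation macro-F1 over repeated
runs (ties resolve to the smaller ``k``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ecgnet import ArchitectureSpec, ECGNet, build_model
from .evalstats import compute_metrics
from .segment import BatchPlan, SequenceSample, plan_balanced_batches

__all__ = [
    "TrainConfig",
    "TransferConfig",
    "SweepResult",
    "FtArrays",
    "PtArrays",
    "sequences_to_ft_arrays",
    "sequences_to_pt_arrays",
    "pretrain",
    "transfer_weights",
    "finetune",
    "freezing_sweep",
    "select_best_k",
    "predict_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


def save_checkpoint(state: dict[str, np.ndarray], path: str | Path) -> Path:
    """Write a state dict as a framework-neutral compressed array archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **state)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


@dataclass
class TrainConfig:
    """Hyperparameters shared by all training entry points.

    Full-scale defaults follow the protocol the architecture was tuned
    with (early stopping on validation loss, patience 30, cap 500 epochs,
    Adam at 1e-3, batch 512 for pre-training); desk-scale experiment
    configs override ``max_epochs``/``batch_size`` downward.
    """

    max_epochs: int = 500
    early_stop_patience: int = 30
    batch_size: int = 512
    lr: float = 1e-3
    loss: str = "cross_entropy_binary"  # or multilabel_bce / weighted_ce
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class TransferConfig:
    """Source checkpoint + freezing depth for fine-tuning."""

    source_state: dict[str, np.ndarray]
    n_frozen_blocks: int = 0


@dataclass
class SweepResult:
    """Per-k validation metrics of the freezing sweep."""

    k_grid: tuple[int, ...]
    mean_mf1: dict[int, float]
    sd_mf1: dict[int, float]
    mean_se: dict[int, float]
    mean_sp: dict[int, float]
    selected_k: int


@dataclass
class FtArrays:
    """FT-style sequences as training arrays."""

    x: np.ndarray  # (N, 1792) float32, standardized
    labels: np.ndarray  # (N, 7) int, 1 = LTA
    mask: np.ndarray  # (N, 7) bool

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class PtArrays:
    """PT-style sequences as multi-label training arrays."""

    x: np.ndarray  # (N, 1792) float32, standardized
    y: np.ndarray  # (N, n_classes) {0,1}
    label_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.x)


def sequences_to_ft_arrays(seqs: list[SequenceSample]) -> FtArrays:
    x = np.stack([s.waveform for s in seqs]).astype(np.float32)
    labels = np.stack([s.segment_labels for s in seqs])
    mask = np.stack([s.segment_mask for s in seqs])
    return FtArrays(x, labels, mask)


def sequences_to_pt_arrays(
    seqs: list[SequenceSample], label_names: list[str] | None = None
) -> PtArrays:
    if label_names is None:
        label_names = sorted({lab for s in seqs for lab in (s.label_set or ())})
    x = np.stack([s.waveform for s in seqs]).astype(np.float32)
    y = np.zeros((len(seqs), len(label_names)), dtype=np.float32)
    index = {lab: j for j, lab in enumerate(label_names)}
    for i, s in enumerate(seqs):
        for lab in s.label_set or ():
            if lab in index:
                y[i, index[lab]] = 1.0
    return PtArrays(x, y, tuple(label_names))


def _manifest(cfg: TrainConfig, extra: dict, *arrays: np.ndarray) -> dict:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return {
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "data_hash": h.hexdigest()[:16],
        **extra,
    }


def _epoch_loss_v0(model: ECGNet, data: PtArrays, batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.x[i : i + batch_size], training=False)
        loss, _ = model.loss_v0(logits, data.y[i : i + batch_size])
        losses.append(loss)
        weights.append(len(logits))
    return float(np.average(losses, weights=weights))


def _epoch_loss_v1(model: ECGNet, data: FtArrays, batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.x[i : i + batch_size], training=False)
        loss, _ = model.loss_v1(
            logits, data.labels[i : i + batch_size], data.mask[i : i + batch_size]
        )
        losses.append(loss)
        weights.append(len(logits))
    return float(np.average(losses, weights=weights))


def _early_stop_loop(run_epoch, val_loss_fn, model: ECGNet, cfg: TrainConfig):
    """Shared epoch loop: best-validation-loss checkpointing + patience."""
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_state, best_epoch, stale = np.inf, model.state_dict(), -1, 0
    for epoch in range(cfg.max_epochs):
        tr = run_epoch(epoch)
        vl = val_loss_fn()
        if not np.isfinite(vl):
            raise RuntimeError(
                f"validation loss became {vl} at epoch {epoch}; "
                f"train loss {tr}; aborting"
            )
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        if vl < best_loss:
            best_loss, best_state, best_epoch, stale = vl, model.state_dict(), epoch, 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_loss)
    return best_state, history


def pretrain(
    model: ECGNet,
    train: PtArrays,
    val: PtArrays,
    cfg: TrainConfig,
) -> tuple[dict[str, np.ndarray], dict]:
    """Pre-train a v0 model on the multi-label rhythm task.

    Returns the best-validation-loss checkpoint (state dict) and history.
    """
    if model.spec.head != "v0":
        raise ValueError("pretraining expects a v0 (multi-label) model")
    opt = model.make_optimizer(cfg.lr)
    order_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((cfg.seed, 0xDA7A))))

    def run_epoch(epoch: int) -> float:
        idx = order_rng.permutation(len(train))
        losses = []
        for i in range(0, len(idx), cfg.batch_size):
            b = idx[i : i + cfg.batch_size]
            logits = model.forward(train.x[b], training=True)
            loss, dl = model.loss_v0(logits, train.y[b])
            opt.zero_grad()
            model.backward(dl)
            opt.step()
            losses.append(loss)
        return float(np.mean(losses))

    state, history = _early_stop_loop(
        run_epoch, lambda: _epoch_loss_v0(model, val, cfg.batch_size), model, cfg
    )
    history["manifest"] = _manifest(cfg, {"stage": "pretrain"}, train.x, train.y)
    return state, history


def transfer_weights(source_state: dict[str, np.ndarray], target: ECGNet) -> ECGNet:
    """Copy the shared backbone (all layers except the last two) into ``target``.

    Every transferred tensor ends bit-equal to the source; the head keeps
    its fresh initialization.  Shape mismatches raise, listing offenders.
    """
    target_names = {p.name: p.value.shape for p in target.params()}
    mismatches = []
    for name, val in source_state.items():
        if name.startswith("head."):
            continue
        base = name.replace(".run_mean", "").replace(".run_var", "")
        if base != name:
            continue  # BN statistics handled below
        if name in target_names and target_names[name] != val.shape:
            mismatches.append(f"{name}: source {val.shape} vs target {target_names[name]}")
    if mismatches:
        raise ValueError("transfer shape mismatch:\n  " + "\n  ".join(mismatches))
    backbone = {k: v for k, v in source_state.items() if not k.startswith("head.")}
    target.load_state_dict(backbone)
    return target


def finetune(
    model: ECGNet,
    transfer_cfg: TransferConfig | None,
    train: FtArrays,
    val: FtArrays,
    cfg: TrainConfig,
    plan: BatchPlan | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Fine-tune (or train from scratch) a v1 model on FT-style arrays.

    With a :class:`TransferConfig`, the model is first initialized from the
    source checkpoint and its first ``n_frozen_blocks`` residual blocks are
    frozen bit-exactly for the whole run.
    """
    if model.spec.head != "v1":
        raise ValueError("fine-tuning expects a v1 (binary) model")
    k = 0
    if transfer_cfg is not None:
        transfer_weights(transfer_cfg.source_state, model)
        k = transfer_cfg.n_frozen_blocks
    model.freeze_blocks(k)
    if plan is None:
        seqs = [
            SequenceSample(
                train.x[i], "", "", 0,
                segment_labels=train.labels[i], segment_mask=train.mask[i],
            )
            for i in range(len(train))
        ]
        mode = "weighted_loss" if cfg.loss == "weighted_ce" else "oversample_3x_undersample"
        plan = plan_balanced_batches(seqs, cfg.batch_size, mode, seed=cfg.seed)
    weights = plan.class_weights if cfg.loss == "weighted_ce" else None
    opt = model.make_optimizer(cfg.lr)

    def run_epoch(epoch: int) -> float:
        losses = []
        for b in plan.epoch_batches(epoch):
            logits = model.forward(train.x[b], training=True)
            loss, dl = model.loss_v1(logits, train.labels[b], train.mask[b], weights)
            opt.zero_grad()
            model.backward(dl)
            opt.step()
            losses.append(loss)
        return float(np.mean(losses))

    state, history = _early_stop_loop(
        run_epoch, lambda: _epoch_loss_v1(model, val, cfg.batch_size), model, cfg
    )
    history["manifest"] = _manifest(
        cfg, {"stage": "finetune", "n_frozen_blocks": k}, train.x, train.labels
    )
    return state, history


def predict_dataset(model: ECGNet, data: FtArrays, batch_size: int = 256) -> np.ndarray:
    """Per-segment predicted labels (N, 7), deterministic inference mode."""
    out = []
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.x[i : i + batch_size], training=False)
        out.append(np.argmax(logits, axis=-1))
    return np.concatenate(out)


def select_best_k(mf1_by_k: dict[int, list[float]]) -> int:
    """argmax of mean validation MF1; ties resolve to the smaller k."""
    means = {k: float(np.mean(v)) for k, v in mf1_by_k.items()}
    best = max(means.values())
    # tolerance guards against float summation order breaking exact ties
    return min(k for k, m in means.items() if m >= best - 1e-9)


def freezing_sweep(
    source_state: dict[str, np.ndarray],
    spec: ArchitectureSpec,
    train: FtArrays,
    val: FtArrays,
    k_grid: tuple[int, ...],
    cfg: TrainConfig,
) -> SweepResult:
    """Fine-tune repeatedly over a grid of freezing depths.

    For each ``k`` the fine-tuning is repeated ``cfg.n_repeats`` times with
    different weight-initialization/data-order seeds (splits fixed);
    ``selected_k`` maximizes mean validation macro-F1.
    """
    if not k_grid:
        raise ValueError("empty freezing grid")
    if any(not 0 <= k <= spec.n_blocks - 1 for k in k_grid):
        raise ValueError(f"k_grid must lie in [0, {spec.n_blocks - 1}]")
    mf1: dict[int, list[float]] = {k: [] for k in k_grid}
    se: dict[int, list[float]] = {k: [] for k in k_grid}
    sp: dict[int, list[float]] = {k: [] for k in k_grid}
    for k in k_grid:
        for rep in range(cfg.n_repeats):
            rep_seed = int(
                np.random.SeedSequence((cfg.seed, k, rep)).generate_state(1, np.uint32)[0]
            ) % (2**31)
            model = build_model(spec, seed=rep_seed)
            rep_cfg = TrainConfig(
                cfg.max_epochs, cfg.early_stop_patience, cfg.batch_size,
                cfg.lr, cfg.loss, rep_seed, 1,
            )
            state, _ = finetune(
                model, TransferConfig(source_state, k), train, val, rep_cfg
            )
            model.load_state_dict(state)
            pred = predict_dataset(model, val)
            rep_metrics = compute_metrics(
                val.labels.ravel(), pred.ravel(), mask=val.mask.ravel()
            )
            mf1[k].append(rep_metrics.mf1)
            se[k].append(rep_metrics.se)
            sp[k].append(rep_metrics.sp)
    return SweepResult(
        tuple(k_grid),
        {k: float(np.mean(v)) for k, v in mf1.items()},
        {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in mf1.items()},
        {k: float(np.mean(v)) for k, v in se.items()},
        {k: float(np.mean(v)) for k, v in sp.items()},
        select_best_k(mf1),
    )
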