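"""End-to-end experiment orchestration at configurable (desk) scale.

Four experiments mirror the package's evaluation protocol:

* ``scratch_vs_tl`` — train the binary detector from scratch and via
  pre-train + transfer, repeatedly; compare per-metric samples with the
  one-sided Mann-Whitney test.
* ``freezing_sweep`` — fine-tune with increasing numbers of frozen
  residual blocks; select the depth maximizing mean validation macro-F1.
* ``lightening`` — train the reduced backbones and report metrics next to
  parameter counts.
* ``confidence_analysis`` — sliding-window vote confidence distributions
  per confusion quadrant, plus stationary/transitory phase metrics.

Everything runs from synthetic cohorts by default (no downloads); the same
orchestration accepts directories of WFDB records for full-scale runs.
Desk-scale defaults (S backbone, 200 PT + 30 FT recordings, 5 seeds, short
epoch caps) are sized for minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import confidence as conf
from .ecg_io import EcgRecord, RhythmAnnotationTrack
from .ecgnet import ArchitectureSpec, build_model, count_parameters
from .evalstats import (
    METRIC_DIRECTIONS,
    compare_models,
    compute_metrics,
    partition_phases,
    summarize_runs,
)
from .preprocess import amann_filter, apply_standardizer, fit_standardizer, pt_filter, resample_to_200hz
from .rhythms import LTA_CODES, RhythmCode
from .segment import (
    SEQUENCE_LEN,
    RecordExcluded,
    segment_recording,
    split_subjects,
    truncate_pt_recording,
)
from .synth import AnnotatedRecording, generate_ft_cohort, generate_pt_cohort
from .trainer import (
    FtArrays,
    TrainConfig,
    TransferConfig,
    finetune,
    freezing_sweep,
    predict_dataset,
    pretrain,
    sequences_to_ft_arrays,
    sequences_to_pt_arrays,
    transfer_weights,
)

__all__ = [
    "ExperimentConfig",
    "ProcessedFtRecording",
    "prepare_ft_data",
    "prepare_pt_data",
    "run_experiment",
    "oracle_confidence_analysis",
]


@dataclass
class ExperimentConfig:
    """Reproducible description of one experiment run."""

    experiment: str  # scratch_vs_tl | freezing_sweep | lightening | confidence_analysis
    size: str = "S"
    n_pt: int = 200
    n_ft: int = 30
    n_seeds: int = 5
    seed: int = 0
    sweep_grid: tuple[int, ...] = (0, 2, 4)
    sweep_repeats: int = 2
    max_epochs: int = 5
    patience: int = 2
    batch_size: int = 64
    pretrain_max_epochs: int = 8
    lightening_sizes: tuple[str, ...] = ("S",)
    n_frozen_blocks: int | None = None  # None -> take the sweep's choice


# ---------------------------------------------------------------------------
# synthetic data preparation (the pipeline: resample -> filter -> segment ->
# split -> standardize)


@dataclass
class ProcessedFtRecording:
    """A 200 Hz filtered recording with per-segment ground truth."""

    subject_id: str
    signal: np.ndarray  # truncated to a whole number of sequences
    segment_labels: np.ndarray  # (n_seq * 7,)
    segment_mask: np.ndarray
    split: str = ""

    def standardized(self, stats) -> "ProcessedFtRecording":
        return ProcessedFtRecording(
            self.subject_id, apply_standardizer(stats, self.signal),
            self.segment_labels, self.segment_mask, self.split,
        )


def _resampled_track(track_entries, fs_in: int) -> RhythmAnnotationTrack:
    entries = []
    for onset, code in track_entries:
        t = int(round(onset * 200 / fs_in))
        if entries and entries[-1][0] == t:
            entries[-1] = (t, code)
        else:
            entries.append((t, code))
    return RhythmAnnotationTrack(entries)


def prepare_ft_data(
    recordings: list[AnnotatedRecording], seed: int = 0
) -> tuple[dict[str, FtArrays], dict[str, list[ProcessedFtRecording]], object]:
    """FT pipeline on annotated recordings -> standardized split arrays.

    Returns per-split sequence arrays, per-split processed recordings (for
    sliding-window/phase analysis), and the fitted normalization stats.
    """
    processed: list[ProcessedFtRecording] = []
    subject_strata: dict[str, frozenset[str]] = {}
    for rec in recordings:
        r200 = resample_to_200hz(EcgRecord(rec.subject_id, rec.signal, rec.fs))
        y = amann_filter(r200.signal)
        track = _resampled_track(rec.annotations, rec.fs)
        seqs = segment_recording(EcgRecord(rec.subject_id, y, 200), track)
        if not seqs:
            continue
        labels = np.concatenate([s.segment_labels for s in seqs])
        mask = np.concatenate([s.segment_mask for s in seqs])
        processed.append(
            ProcessedFtRecording(rec.subject_id, y[: len(seqs) * SEQUENCE_LEN], labels, mask)
        )
        strata = set()
        if labels[mask].max(initial=0) == 1:
            strata.add("lta")
        if not mask.all():
            strata.add("noise")
        subject_strata[rec.subject_id] = frozenset(strata)
    assignment = split_subjects(subject_strata, seed=seed)
    for p in processed:
        p.split = assignment[p.subject_id]
    train_pool = [p.signal for p in processed if p.split == "train"]
    stats = fit_standardizer(train_pool)
    by_split: dict[str, list[ProcessedFtRecording]] = {"train": [], "validation": [], "test": []}
    for p in processed:
        by_split[p.split].append(p.standardized(stats))
    arrays = {}
    for split, recs in by_split.items():
        x = np.concatenate(
            [r.signal.reshape(-1, SEQUENCE_LEN) for r in recs]
        ).astype(np.float32)
        labels = np.concatenate([r.segment_labels.reshape(-1, 7) for r in recs])
        mask = np.concatenate([r.segment_mask.reshape(-1, 7) for r in recs])
        arrays[split] = FtArrays(x, labels, mask)
    return arrays, by_split, stats


def prepare_pt_data(
    recordings: list[AnnotatedRecording], seed: int = 0
) -> tuple[dict[str, object], object]:
    """PT pipeline: resample -> band-pass -> truncate -> split -> standardize."""
    seqs, strata = [], {}
    for rec in recordings:
        r200 = resample_to_200hz(EcgRecord(rec.subject_id, rec.signal, rec.fs))
        y = pt_filter(r200.signal)
        try:
            s = truncate_pt_recording(
                EcgRecord(rec.subject_id, y, 200), rec.label_set or frozenset()
            )
        except RecordExcluded:
            continue
        seqs.append(s)
        strata[rec.subject_id] = rec.label_set
    assignment = split_subjects(strata, seed=seed)
    label_names = sorted({lab for s in seqs for lab in s.label_set})
    by_split = {"train": [], "validation": [], "test": []}
    for s in seqs:
        by_split[assignment[s.subject_id]].append(s)
    stats = fit_standardizer([s.waveform for s in by_split["train"]])
    arrays = {}
    for split, ss in by_split.items():
        arr = sequences_to_pt_arrays(ss, label_names)
        arr.x = apply_standardizer(stats, arr.x).astype(np.float32)
        arrays[split] = arr
    return arrays, stats


# ---------------------------------------------------------------------------
# experiment bodies


def _pretrain_checkpoint(cfg: ExperimentConfig, n_classes: int, pt_arrays) -> dict:
    spec = ArchitectureSpec.for_size(cfg.size, head="v0", n_classes=n_classes)
    model = build_model(spec, seed=cfg.seed)
    tc = TrainConfig(cfg.pretrain_max_epochs, cfg.patience, cfg.batch_size,
                     loss="multilabel_bce", seed=cfg.seed, n_repeats=1)
    state, history = pretrain(model, pt_arrays["train"], pt_arrays["validation"], tc)
    return {"state": state, "history": history, "spec": spec}


def _test_metrics(model, arrays: FtArrays):
    pred = predict_dataset(model, arrays)
    return compute_metrics(arrays.labels.ravel(), pred.ravel(), mask=arrays.mask.ravel())


def _finetune_once(spec, source_state, k, ft, cfg: ExperimentConfig, rep_seed: int):
    model = build_model(spec, seed=rep_seed)
    tc = TrainConfig(cfg.max_epochs, cfg.patience, cfg.batch_size, seed=rep_seed, n_repeats=1)
    transfer = TransferConfig(source_state, k) if source_state is not None else None
    state, history = finetune(model, transfer, ft["train"], ft["validation"], tc)
    model.load_state_dict(state)
    return model, history


def _rep_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence((base, *key)).generate_state(1, np.uint32)[0]) % (2**31)


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    _data_cache: dict | None = None,
) -> dict:
    """Run one experiment end-to-end on synthetic cohorts; return the bundle."""
    cache = _data_cache if _data_cache is not None else {}
    if "ft" not in cache:
        ft_recs = generate_ft_cohort(config.n_ft, seed=config.seed)
        cache["ft"], cache["ft_recs"], cache["ft_stats"] = prepare_ft_data(ft_recs, seed=config.seed)
    ft, ft_recs = cache["ft"], cache["ft_recs"]
    bundle: dict = {"config": asdict(config)}

    needs_pt = config.experiment in ("scratch_vs_tl", "freezing_sweep", "lightening",
                                     "confidence_analysis")
    if needs_pt and "pt" not in cache:
        pt_cohort = generate_pt_cohort(config.n_pt, seed=config.seed + 1)
        cache["pt"], cache["pt_stats"] = prepare_pt_data(pt_cohort, seed=config.seed)
    pt = cache.get("pt")

    spec_v1 = ArchitectureSpec.for_size(config.size, head="v1")

    if config.experiment == "scratch_vs_tl":
        ck = _pretrain_checkpoint(config, pt["train"].y.shape[1], pt)
        scratch_reports, tl_reports = [], []
        for rep in range(config.n_seeds):
            m_s, _ = _finetune_once(spec_v1, None, 0, ft, config, _rep_seed(config.seed, 0, rep))
            scratch_reports.append(_test_metrics(m_s, ft["test"]))
            m_t, _ = _finetune_once(spec_v1, ck["state"], config.n_frozen_blocks or 0,
                                    ft, config, _rep_seed(config.seed, 1, rep))
            tl_reports.append(_test_metrics(m_t, ft["test"]))
        comparisons = {}
        for metric, direction in METRIC_DIRECTIONS.items():
            a = [getattr(r, metric) for r in tl_reports]
            b = [getattr(r, metric) for r in scratch_reports]
            if any(np.isnan(a)) or any(np.isnan(b)):
                continue
            c = compare_models(a, b, direction, metric=metric)
            comparisons[metric] = {"u": c.u, "p": c.p, "r": c.r,
                                   "direction": c.direction, "significant": c.significant}
        bundle.update(
            scratch={k: v[2] for k, v in summarize_runs(scratch_reports).items()},
            transfer={k: v[2] for k, v in summarize_runs(tl_reports).items()},
            comparisons=comparisons,
        )
        bundle["_reports"] = {"scratch": scratch_reports, "transfer": tl_reports}

    elif config.experiment == "freezing_sweep":
        ck = _pretrain_checkpoint(config, pt["train"].y.shape[1], pt)
        tc = TrainConfig(config.max_epochs, config.patience, config.batch_size,
                         seed=config.seed, n_repeats=config.sweep_repeats)
        sweep = freezing_sweep(ck["state"], spec_v1, ft["train"], ft["validation"],
                               config.sweep_grid, tc)
        bundle["sweep"] = {
            "k_grid": list(sweep.k_grid),
            "mean_mf1": sweep.mean_mf1, "sd_mf1": sweep.sd_mf1,
            "mean_se": sweep.mean_se, "mean_sp": sweep.mean_sp,
            "selected_k": sweep.selected_k,
        }

    elif config.experiment == "lightening":
        bundle["parameter_counts"] = {
            s: count_parameters(ArchitectureSpec.for_size(s, head="v1")) for s in "LMS"
        }
        per_size = {}
        for size in config.lightening_sizes:
            spec = ArchitectureSpec.for_size(size, head="v1")
            spec_v0 = ArchitectureSpec.for_size(size, head="v0", n_classes=pt["train"].y.shape[1])
            model0 = build_model(spec_v0, seed=config.seed)
            tc0 = TrainConfig(config.pretrain_max_epochs, config.patience, config.batch_size,
                              loss="multilabel_bce", seed=config.seed, n_repeats=1)
            state0, _ = pretrain(model0, pt["train"], pt["validation"], tc0)
            m, _ = _finetune_once(spec, state0, config.n_frozen_blocks or 0, ft, config,
                                  _rep_seed(config.seed, 2, 0))
            per_size[size] = _test_metrics(m, ft["test"]).as_dict()
        bundle["metrics_by_size"] = per_size

    elif config.experiment == "confidence_analysis":
        ck = _pretrain_checkpoint(config, pt["train"].y.shape[1], pt)
        model, _ = _finetune_once(spec_v1, ck["state"], config.n_frozen_blocks or 0,
                                  ft, config, _rep_seed(config.seed, 3, 0))
        bundle.update(confidence_analysis(model, ft_recs["test"]))
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in bundle.items() if not k.startswith("_")}
        (out_dir / f"{config.experiment}.json").write_text(json.dumps(serializable, indent=2))
    return bundle


def confidence_analysis(model, recordings: list[ProcessedFtRecording]) -> dict:
    """Sliding-vote predictions over whole recordings: quadrant confidence
    distributions and stationary/transitory phase metrics."""

    def predict_fn(signal):
        preds = [conf.vote(t) for t in conf.sliding_votes(model, signal)]
        return (np.array([p.label for p in preds]),
                np.array([p.confidence for p in preds]))

    return _confidence_analysis(recordings, predict_fn)


def oracle_confidence_analysis(recordings: list[ProcessedFtRecording]) -> dict:
    """Upper-bound variant: ground truth injected as a perfect predictor."""
    return _confidence_analysis(
        recordings, lambda sig, _labels=None: (None, None), oracle=True
    )


def _confidence_analysis(recordings, predict_fn, oracle: bool = False) -> dict:
    all_true, all_pred, all_conf, all_mask, all_phase = [], [], [], [], []
    for rec in recordings:
        if oracle:
            labels, confs = rec.segment_labels.copy(), np.ones(len(rec.segment_labels))
        else:
            labels, confs = predict_fn(rec.signal)
        n = min(len(labels), len(rec.segment_labels))
        all_true.append(rec.segment_labels[:n])
        all_pred.append(labels[:n])
        all_conf.append(confs[:n])
        all_mask.append(rec.segment_mask[:n])
        all_phase.append(partition_phases([rec.segment_labels[:n]])[0])
    t = np.concatenate(all_true)
    p = np.concatenate(all_pred)
    c = np.concatenate(all_conf)
    m = np.concatenate(all_mask)
    ph = np.concatenate(all_phase)
    quadrants = {
        "tp": c[(t == 1) & (p == 1) & m],
        "tn": c[(t == 0) & (p == 0) & m],
        "fp": c[(t == 0) & (p == 1) & m],
        "fn": c[(t == 1) & (p == 0) & m],
    }
    out = {
        "quadrant_confidence": {
            k: {"n": int(len(v)), "mean": float(v.mean()) if len(v) else float("nan")}
            for k, v in quadrants.items()
        },
        "phase_metrics": {},
        "phase_confidence": {},
        "_raw": {"true": t, "pred": p, "conf": c, "mask": m, "phase": ph},
    }
    for name, sel in (("stationary", ~ph), ("transitory", ph)):
        keep = sel & m
        if keep.sum() == 0:
            continue
        rep = compute_metrics(t[keep], p[keep])
        out["phase_metrics"][name] = rep.as_dict()
        out["phase_confidence"][name] = {
            "mean": float(c[keep].mean()), "sd": float(c[keep].std())
        }
    return out
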