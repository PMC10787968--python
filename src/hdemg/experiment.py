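"""End-to-end experiment runner: simulate -> preprocess -> shift -> train -> evaluate.

An experiment emulates one subject-session: several recording blocks are
simulated (or loaded), features are extracted, cue labels are aligned
(none / static / dynamic), a decoder is trained on the chronologically
earlier blocks and evaluated on the held-out final blocks — training data
never postdate test data. Every stochastic stage derives its seed from the
master seed, and a manifest captures everything needed to regenerate the
report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .align import dynamic_shift, static_shift, summarize
from .decoder import DecoderResults, MovementDecoder
from .metrics import EvalReport, SubsetSpec, bin_accuracy, build_subset, chance_level, confusion, success_rate
from .preprocess import (
    FeatureTensor,
    FilterSpec,
    apply_normalizer,
    bandpass_notch,
    extract_center_windows,
    fit_normalizer,
    rms_bins,
    stack_history,
)
from .simulate import (
    CLASSES,
    MOVEMENTS,
    REST,
    CueSchedule,
    EMGRecording,
    LatencyModel,
    SimulationParams,
    make_cue_schedule,
    make_sleeve_layout,
)

_CENTER_WIDTH = {"stroke": 2.5, "able": 1.5}


class ExperimentConfig(BaseModel):
    """Schema-validated configuration for one decoding experiment."""

    size_class: Literal["small", "medium", "large"] = "small"
    movements: list[str] | Literal["all"] = "all"
    reps_per_movement: int = Field(2, ge=1)
    profile: Literal["stroke", "able"] = "able"
    n_blocks: int = Field(3, ge=2)
    n_test_blocks: int = Field(1, ge=1)
    train_block_indices: Optional[list[int]] = None
    test_block_indices: Optional[list[int]] = None

    impairment: float = Field(0.0, ge=0.0, le=1.0)
    snr_db: float = 15.0
    latency_low_s: float = Field(0.0, ge=0.0, le=2.0)
    latency_high_s: float = Field(0.0, ge=0.0, le=2.0)
    line_noise_amp: float = 2.0

    shift_mode: Literal["none", "static", "dynamic"] = "none"
    static_shift_s: float = 0.8
    max_shift_s: float = 2.0

    model_kind: Literal["lr", "svm", "mlp"] = "lr"
    mlp_epochs: int = Field(50, ge=1)
    center_width_s: Optional[float] = None
    subset_mode: Optional[Literal["binary_rest_move", "fixed_three", "top_k"]] = None
    subset_k: int = Field(2, ge=1)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if self.n_test_blocks >= self.n_blocks:
            raise ValueError("need at least one training block")
        if self.latency_high_s < self.latency_low_s:
            raise ValueError("latency_high_s must be >= latency_low_s")
        if self.movements != "all":
            for m in self.movements:
                if m not in MOVEMENTS:
                    raise ValueError(f"unknown movement {m!r}")
        if (self.train_block_indices is None) != (self.test_block_indices is None):
            raise ValueError("give both explicit block index lists or neither")
        if self.train_block_indices is not None:
            # chronological split discipline: training must precede testing
            if max(self.train_block_indices) >= min(self.test_block_indices):
                raise ValueError(
                    "chronology violated: every training block must precede "
                    "every test block"
                )
        return self

    def split(self) -> tuple[list[int], list[int]]:
        if self.train_block_indices is not None:
            return list(self.train_block_indices), list(self.test_block_indices)
        n_train = self.n_blocks - self.n_test_blocks
        return list(range(n_train)), list(range(n_train, self.n_blocks))

    @property
    def movement_list(self) -> list[str]:
        return list(MOVEMENTS) if self.movements == "all" else list(self.movements)

    @property
    def width_s(self) -> float:
        return self.center_width_s or _CENTER_WIDTH[self.profile]


@dataclass
class BlockData:
    recording: EMGRecording
    features: FeatureTensor  # normalized + stacked
    schedule_used: CueSchedule  # after any shifting
    shift_info: dict = field(default_factory=dict)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: EvalReport
    decoder: DecoderResults
    norm_stats: object
    blocks: list[BlockData]
    train_indices: list[int]
    test_indices: list[int]
    manifest: dict


def _block_seed(master: int, i: int) -> int:
    h = hashlib.sha256(f"{master}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def simulate_blocks(config: ExperimentConfig) -> list[EMGRecording]:
    layout = make_sleeve_layout(config.size_class)
    lat = LatencyModel(config.latency_low_s, config.latency_high_s)
    recs = []
    for i in range(config.n_blocks):
        s = _block_seed(config.seed, i)
        sched = make_cue_schedule(
            config.movement_list, config.reps_per_movement, config.profile, seed=s
        )
        params = SimulationParams(
            pattern_spread=1.0,
            impairment=config.impairment,
            snr_db=config.snr_db,
            latency_model=lat,
            line_noise_amp=config.line_noise_amp,
            seed=s,
        )
        recs.append(simulate_with_params(sched, layout, params))
    return recs


def simulate_with_params(schedule, layout, params):
    from .simulate import simulate_emg

    return simulate_emg(schedule, layout, params)


def run_experiment(
    config: ExperimentConfig,
    recordings: list[EMGRecording] | None = None,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Execute the full offline workflow for one configuration.

    Stage failures raise with the stage named; when ``out_dir`` is given,
    artifacts produced before the failure are preserved there.
    """
    stage = "simulate"
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    try:
        if recordings is None:
            recordings = simulate_blocks(config)
        train_idx, test_idx = config.split()
        if max(train_idx + test_idx) >= len(recordings):
            raise ValueError("block index exceeds available recordings")

        stage = "preprocess"
        raw_fts = []
        for rec in recordings:
            ft = rms_bins(bandpass_notch(rec, FilterSpec()))
            raw_fts.append(ft)
        norm_stats = fit_normalizer(
            np.concatenate([raw_fts[i].rms for i in train_idx])
        )
        blocks: list[BlockData] = []
        for rec, ft in zip(recordings, raw_fts):
            ft.rms = apply_normalizer(ft.rms, norm_stats)
            ft.norm_stats = norm_stats
            ft = stack_history(ft)
            blocks.append(BlockData(recording=rec, features=ft, schedule_used=rec.schedule))

        stage = "shift"
        for b in blocks:
            if config.shift_mode == "static":
                b.schedule_used = static_shift(b.recording.schedule, config.static_shift_s)
                b.shift_info = {"mode": "static", "delta_s": config.static_shift_s}
            elif config.shift_mode == "dynamic":
                res = dynamic_shift(
                    summarize(b.features), b.recording.schedule, config.max_shift_s
                )
                b.schedule_used = res.shifted_schedule
                b.shift_info = {
                    "mode": "dynamic",
                    "per_boundary_shift_s": res.per_boundary_shift_s.tolist(),
                    "total_ssr": res.total_ssr,
                }
            b.features.labels = b.schedule_used.labels_for_bins(
                b.features.n_bins, b.features.bin_width_s
            )

        stage = "dataset"
        def _dataset(idxs):
            parts = [
                extract_center_windows(blocks[i].features, blocks[i].schedule_used, config.width_s)
                for i in idxs
            ]
            X = np.concatenate([p.X for p in parts])
            y = np.concatenate([p.y for p in parts])
            return X, y, parts

        X_train, y_train, train_parts = _dataset(train_idx)
        X_test, y_test, test_parts = _dataset(test_idx)

        classes = None
        if config.subset_mode:
            spec = SubsetSpec(mode=config.subset_mode, k=config.subset_k)
            pca_acc = None
            if config.subset_mode == "top_k":
                pca_acc = _cv_per_class_accuracy(X_train, y_train, config.seed)
            new_train, classes = _subset_blocks(train_idx, blocks, config, spec, pca_acc)
            X_train, y_train = new_train
            new_test, _ = _subset_blocks(test_idx, blocks, config, spec, pca_acc)
            X_test, y_test = new_test

        stage = "train"
        from ._mlp import MLPSpec

        model = MovementDecoder(
            X_train, y_train, kind=config.model_kind,
            mlp_spec=MLPSpec(epochs=config.mlp_epochs),
        )
        results = model.fit(seed=config.seed)

        stage = "evaluate"
        pred = results.predict(X_test)
        cls_idx = np.unique(np.concatenate([results.class_indices, np.unique(y_test)]))
        cm = confusion(pred, y_test, cls_idx)
        per_class = {}
        for i, c in enumerate(cls_idx):
            n = cm[i].sum()
            name = CLASSES[c] if c < len(CLASSES) else "Move"
            per_class[name] = float(cm[i, i] / n) if n else float("nan")
        # success rate on the continuous test streams (per block, aggregated)
        n_succ = n_att = 0
        sa: dict = {}
        if not config.subset_mode:
            for i in test_idx:
                stream = results.predict(blocks[i].features.stacked)
                stream[~blocks[i].features.valid_mask] = results.class_indices[0]
                _, per = success_rate(stream, blocks[i].schedule_used)
                for k, (s, a) in per.items():
                    s0, a0 = sa.get(k, (0, 0))
                    sa[k] = (s0 + s, a0 + a)
                    n_succ += s
                    n_att += a
        report = EvalReport(
            bin_accuracy=bin_accuracy(pred, y_test),
            chance_level=chance_level(y_test),
            confusion_matrix=cm,
            class_labels=tuple(
                CLASSES[c] if c < len(CLASSES) else "Move" for c in cls_idx
            ),
            per_class_accuracy=per_class,
            success_rate=(n_succ / n_att) if n_att else None,
            successes_attempts=sa,
        )

        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "config": json.loads(config.model_dump_json()),
            "train_blocks": train_idx,
            "test_blocks": test_idx,
            "block_seeds": [_block_seed(config.seed, i) for i in range(config.n_blocks)],
            "n_train_samples": int(X_train.shape[0]),
            "n_test_samples": int(X_test.shape[0]),
        }
        if out:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            from .io import write_report

            write_report(report, out / "report.json")
        return ExperimentResult(
            config=config, report=report, decoder=results, norm_stats=norm_stats,
            blocks=blocks, train_indices=train_idx, test_indices=test_idx,
            manifest=manifest,
        )
    except Exception as e:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {e}") from e


def _subset_blocks(idxs, blocks, config, spec, per_class_acc):
    Xs, ys, classes = [], [], None
    for i in idxs:
        ds = extract_center_windows(
            blocks[i].features, blocks[i].schedule_used, config.width_s
        )
        sub, classes = build_subset(ds, blocks[i].schedule_used, spec, per_class_acc)
        Xs.append(sub.X)
        ys.append(sub.y)
    return (np.concatenate(Xs), np.concatenate(ys)), classes


def _cv_per_class_accuracy(X, y, seed) -> dict:
    """Per-class accuracy from cross-validated training predictions (LR)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_predict

    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    pred = cross_val_predict(
        LogisticRegression(max_iter=1000, random_state=seed), X, y, cv=cv
    )
    out = {}
    for c in np.unique(y):
        mask = y == c
        out[CLASSES[c]] = float(np.mean(pred[mask] == c))
    return out
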