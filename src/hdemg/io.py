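"""Reading and writing recordings, schedules, features and reports.

HDF5 is the native container for recordings and features; schedules,
normalization statistics and evaluation reports are JSON; confusion
tables export to CSV. Schedules are schema-validated on read and
violations are reported with a JSON-pointer-style path.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .metrics import EvalReport
from .preprocess import FeatureTensor, NormStats
from .simulate import (
    CLASSES,
    CueSchedule,
    EMGRecording,
    SleeveLayout,
    make_sleeve_layout,
)


def write_recording(recording: EMGRecording, path) -> None:
    """HDF5 layout: /emg float32 channels x time; /meta JSON attrs string."""
    meta = {
        "sampling_rate": recording.sampling_rate,
        "size_class": recording.layout.size_class,
        "schedule": recording.schedule.to_dict(),
    }
    if recording.ground_truth is not None:
        gt = recording.ground_truth
        meta["ground_truth"] = {
            "true_segments": gt.true_segments.to_dict(),
            "patterns": {k: v.tolist() for k, v in gt.patterns.items()},
            "observed_movement_score": gt.observed_movement_score,
            "boundary_latencies_s": gt.boundary_latencies_s.tolist(),
        }
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=recording.samples.astype(np.float32))
        f.create_dataset("meta", data=json.dumps(meta))


def read_recording(path) -> EMGRecording:
    from .simulate import GroundTruth

    with h5py.File(path, "r") as f:
        samples = f["emg"][...]
        meta = json.loads(f["meta"][()].decode())
    schedule = schedule_from_dict(meta["schedule"])
    gt = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        gt = GroundTruth(
            true_segments=schedule_from_dict(g["true_segments"]),
            patterns={k: np.asarray(v) for k, v in g["patterns"].items()},
            observed_movement_score=g["observed_movement_score"],
            boundary_latencies_s=np.asarray(g["boundary_latencies_s"]),
        )
    return EMGRecording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate"]),
        layout=make_sleeve_layout(meta["size_class"]),
        schedule=schedule,
        ground_truth=gt,
    )


def schedule_from_dict(d: dict) -> CueSchedule:
    """Validate and build a schedule; errors carry JSON-pointer paths."""
    if "segments" not in d or not d["segments"]:
        raise ValueError("/segments: missing or empty")
    prev_off = None
    for i, s in enumerate(d["segments"]):
        for key in ("label", "onset_s", "offset_s"):
            if key not in s:
                raise ValueError(f"/segments/{i}/{key}: missing")
        if s["label"] not in CLASSES:
            raise ValueError(f"/segments/{i}/label: unknown class {s['label']!r}")
        if s["offset_s"] <= s["onset_s"]:
            raise ValueError(f"/segments/{i}: non-positive duration")
        if prev_off is not None and abs(s["onset_s"] - prev_off) > 1e-9:
            kind = "overlaps" if s["onset_s"] < prev_off else "leaves a gap after"
            raise ValueError(f"/segments/{i}: {kind} previous segment")
        prev_off = s["offset_s"]
    return CueSchedule.from_dict(d)


def write_schedule(schedule: CueSchedule, path, provenance: dict | None = None) -> None:
    d = schedule.to_dict()
    if provenance:
        d["provenance"] = provenance
    Path(path).write_text(json.dumps(d, indent=2))


def read_schedule(path) -> CueSchedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))


def write_features(ft: FeatureTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rms", data=ft.rms)
        f.attrs["bin_width_s"] = ft.bin_width_s
        if ft.stacked is not None:
            f.create_dataset("stacked", data=ft.stacked)
            f.create_dataset("valid_mask", data=ft.valid_mask)
        if ft.labels is not None:
            f.create_dataset("labels", data=ft.labels)
        if ft.norm_stats is not None:
            f.attrs["norm_stats"] = json.dumps(ft.norm_stats.to_dict())


def read_features(path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        ft = FeatureTensor(
            rms=f["rms"][...],
            bin_width_s=float(f.attrs["bin_width_s"]),
            stacked=f["stacked"][...] if "stacked" in f else None,
            valid_mask=f["valid_mask"][...] if "valid_mask" in f else None,
            labels=f["labels"][...] if "labels" in f else None,
        )
        if "norm_stats" in f.attrs:
            ft.norm_stats = NormStats.from_dict(json.loads(f.attrs["norm_stats"]))
    return ft


def features_to_csv(ft: FeatureTensor, path) -> None:
    """Tabular export: bin_index, label, ch0..chN-1 RMS columns."""
    df = pd.DataFrame(ft.rms, columns=[f"ch{i}" for i in range(ft.n_channels)])
    df.insert(0, "label", ft.labels if ft.labels is not None else -1)
    df.insert(0, "bin_index", np.arange(ft.n_bins))
    df.to_csv(path, index=False)


def write_report(report: EvalReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def confusion_to_csv(report: EvalReport, path) -> None:
    pd.DataFrame(
        report.confusion_matrix,
        index=list(report.class_labels),
        columns=list(report.class_labels),
    ).to_csv(path)
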