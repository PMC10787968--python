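"""Decoding performance metrics and movement-subset analyses.

Accuracy is the fraction of 100 ms bins whose predicted class equals the
ground-truth label; chance level is the majority-class label fraction (the
accuracy of a naive always-Rest decoder). Success rate scores each cue as
a binary outcome: a cue succeeds when at least 1 s (10 consecutive bins)
strictly inside it is decoded as the cued movement.

Subset analyses rebuild the dataset for reduced problems — Rest-vs-Move,
a fixed {Rest, Hand Close, Hand Open} set, or Rest plus the top-k
movements by per-class accuracy — while subsampling rest bins from the
rest cues directly preceding each retained movement so that rest stays at
50% of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .preprocess import BIN_WIDTH_S, CenterWindowDataset
from .simulate import CLASS_INDEX, CLASSES, REST, CueSchedule

MOVE_CLASS = "Move"  # collapsed label for the binary Rest/Move problem


def bin_accuracy(pred_labels, true_labels) -> float:
    """Fraction of bins where prediction equals ground truth."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0:
        raise ValueError("empty label streams")
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return float(np.mean(pred == true))


def chance_level(true_labels) -> float:
    """Majority-class fraction: the accuracy of a naive constant decoder."""
    true = np.asarray(true_labels)
    if true.size == 0:
        raise ValueError("empty label stream")
    _, counts = np.unique(true, return_counts=True)
    return float(counts.max() / true.size)


def confusion(pred_labels, true_labels, classes) -> np.ndarray:
    """Counts, true class x predicted class, in the order of ``classes``."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    labels = list(classes)
    for v in np.unique(np.concatenate([pred, true])):
        if v not in labels:
            raise ValueError(f"label {v!r} not in the declared class set")
    return _sk_confusion(true, pred, labels=labels)


def _runs_of_true(mask: np.ndarray):
    """Lengths of maximal runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return (ends - starts).tolist()


def success_rate(
    pred_labels,
    schedule: CueSchedule,
    bin_width_s: float = BIN_WIDTH_S,
    min_run_s: float = 1.0,
    include_rest: bool = False,
) -> tuple[float, dict]:
    """Fraction of cues with >= 1 s continuously correct decoding.

    A cue counts as successful when some run of at least
    ``min_run_s / bin_width_s`` consecutive bins strictly inside the cue is
    decoded as the cued class. Rest periods are excluded from the
    denominator unless ``include_rest`` is set.
    """
    pred = np.asarray(pred_labels)
    n_bins = int(np.floor(schedule.duration_s / bin_width_s))
    if pred.size < n_bins:
        raise ValueError(
            f"predictions ({pred.size} bins) do not cover the schedule ({n_bins} bins)"
        )
    need = int(round(min_run_s / bin_width_s))
    per_class: dict[str, list] = {}
    n_success = n_attempt = 0
    for seg in schedule.segments:
        if seg.label == REST and not include_rest:
            continue
        b0 = int(np.ceil(seg.onset_s / bin_width_s - 1e-9))
        b1 = int(np.floor(seg.offset_s / bin_width_s + 1e-9))
        inside = pred[b0:b1] == CLASS_INDEX[seg.label]
        ok = any(r >= need for r in _runs_of_true(inside))
        s, a = per_class.get(seg.label, (0, 0))
        per_class[seg.label] = (s + int(ok), a + 1)
        n_success += int(ok)
        n_attempt += 1
    if n_attempt == 0:
        raise ValueError("schedule contains no scoreable cues")
    return n_success / n_attempt, per_class


@dataclass
class EvalReport:
    """The metric bundle for one evaluated prediction stream."""

    bin_accuracy: float
    chance_level: float
    confusion_matrix: np.ndarray
    class_labels: tuple
    per_class_accuracy: dict
    success_rate: float | None = None
    successes_attempts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bin_accuracy": self.bin_accuracy,
            "chance_level": self.chance_level,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_labels": list(self.class_labels),
            "per_class_accuracy": dict(self.per_class_accuracy),
            "success_rate": self.success_rate,
            "successes_attempts": {k: list(v) for k, v in self.successes_attempts.items()},
        }


def evaluate_predictions(
    pred_labels,
    true_labels,
    schedule: CueSchedule | None = None,
    class_indices=None,
    include_rest: bool = False,
) -> EvalReport:
    """Full metric bundle; success rate only when a schedule is given."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if class_indices is None:
        class_indices = np.unique(np.concatenate([pred, true]))
    cm = confusion(pred, true, class_indices)
    per_class = {}
    for i, c in enumerate(class_indices):
        n = cm[i].sum()
        per_class[CLASSES[c] if c < len(CLASSES) else str(c)] = (
            float(cm[i, i] / n) if n else float("nan")
        )
    sr, sa = (None, {})
    if schedule is not None:
        sr, sa = success_rate(pred, schedule, include_rest=include_rest)
    return EvalReport(
        bin_accuracy=bin_accuracy(pred, true),
        chance_level=chance_level(true),
        confusion_matrix=cm,
        class_labels=tuple(
            CLASSES[c] if c < len(CLASSES) else str(c) for c in class_indices
        ),
        per_class_accuracy=per_class,
        success_rate=sr,
        successes_attempts=sa,
    )


@dataclass(frozen=True)
class SubsetSpec:
    """Reduced-problem definition with rest held at 50% of samples."""

    mode: str  # binary_rest_move | fixed_three | top_k
    k: int = 2
    rest_fraction_target: float = 0.5

    def __post_init__(self):
        if self.mode not in ("binary_rest_move", "fixed_three", "top_k"):
            raise ValueError(f"unknown subset mode {self.mode!r}")


def build_subset(
    dataset: CenterWindowDataset,
    schedule: CueSchedule,
    spec: SubsetSpec,
    per_class_accuracy: dict | None = None,
) -> tuple[CenterWindowDataset, tuple]:
    """Reduced dataset plus its class-label tuple.

    Movement samples of the retained classes are kept (relabelled to a
    single Move class in binary mode); rest samples are then drawn from the
    rest cues immediately preceding each retained movement cue, in temporal
    order, until rest makes up half the dataset (within one sample).
    """
    seg_labels = [s.label for s in schedule.segments]
    if spec.mode == "binary_rest_move":
        keep = set(l for l in seg_labels if l != REST)
    elif spec.mode == "fixed_three":
        keep = {"Hand Close", "Hand Open"}
    else:
        if per_class_accuracy is None:
            raise ValueError("top_k mode needs a per-class accuracy table")
        movers = {k: v for k, v in per_class_accuracy.items() if k != REST}
        if spec.k > len(movers):
            raise ValueError(f"k={spec.k} exceeds the {len(movers)} available movements")
        keep = set(sorted(movers, key=lambda m: -movers[m])[: spec.k])

    rest_idx = CLASS_INDEX[REST]
    move_mask = np.isin(
        dataset.y, [CLASS_INDEX[m] for m in keep]
    )
    move_rows = np.flatnonzero(move_mask)
    n_move = move_rows.size
    if n_move == 0:
        raise ValueError("no samples of the retained movements in the dataset")

    # rest bins from the rest cue directly before each retained movement cue
    rest_rows: list[int] = []
    for si, seg in enumerate(schedule.segments):
        if seg.label in keep and si > 0 and seg_labels[si - 1] == REST:
            prev = np.flatnonzero(dataset.segment_ids == si - 1)
            rest_rows.extend(prev.tolist())
    n_rest_needed = n_move  # 50% rest
    if len(rest_rows) < n_rest_needed - 1:
        raise ValueError(
            f"only {len(rest_rows)} rest samples available from preceding rest "
            f"cues; need {n_rest_needed} for a 50% rest fraction"
        )
    rest_rows = np.asarray(rest_rows[:n_rest_needed])

    sel = np.sort(np.concatenate([move_rows, rest_rows]))
    y = dataset.y[sel].copy()
    if spec.mode == "binary_rest_move":
        move_index = len(CLASSES)  # synthetic index for the collapsed class
        y[y != rest_idx] = move_index
        classes = (REST, MOVE_CLASS)
    else:
        kept_sorted = [m for m in CLASSES if m in keep]
        classes = (REST, *kept_sorted)
    out = replace(
        dataset,
        X=dataset.X[sel],
        y=y,
        bin_indices=dataset.bin_indices[sel],
        segment_ids=dataset.segment_ids[sel],
    )
    return out, classes
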