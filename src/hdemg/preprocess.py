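"""Filtering, RMS binning, history stacking, normalization, center windows.

The feature pipeline: causal 20-400 Hz Butterworth band-pass (10th-order
transfer function, applied as second-order sections) plus a 60 Hz notch;
root-mean-square amplitude over consecutive non-overlapping 100 ms bins;
per-channel standardization with statistics fitted on training data only;
and prediction samples built by concatenating the current bin with its
three predecessors (400 ms of temporal context).

For offline model comparison the middle W seconds of every cue and rest
segment are extracted (W = 2.5 s stroke, 1.5 s able-bodied), dropping the
first three bins of each window whose stacked history reaches outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _signal

from .simulate import CLASS_INDEX, CueSchedule, EMGRecording

logger = logging.getLogger(__name__)

BIN_WIDTH_S = 0.1
HISTORY_BINS = 4


@dataclass(frozen=True)
class FilterSpec:
    """20-400 Hz band-pass (10th-order Butterworth) + 60 Hz notch (Q=30)."""

    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    order: int = 10
    notch_freq_hz: float = 60.0
    notch_q: float = 30.0

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low < band_high")
        if self.order % 2:
            raise ValueError("band-pass order must be even (transfer-function order)")


def design_bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """SOS array for the band-pass alone (scipy doubles N for band-pass)."""
    if fs <= 2 * spec.band_high_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {spec.band_high_hz} Hz band edge"
        )
    return _signal.butter(
        spec.order // 2,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def design_filter_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Cascaded band-pass + notch as second-order sections."""
    sos_bp = design_bandpass_sos(spec, fs)
    b, a = _signal.iirnotch(spec.notch_freq_hz, spec.notch_q, fs=fs)
    sos_notch = _signal.tf2sos(b, a)
    return np.vstack([sos_bp, sos_notch])


def bandpass_notch(recording: EMGRecording, spec: FilterSpec | None = None) -> EMGRecording:
    """Causal (forward-only) per-channel filtering; shape preserved."""
    spec = spec or FilterSpec()
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("recording contains non-finite samples")
    sos = design_filter_sos(spec, recording.sampling_rate)
    filtered = _signal.sosfilt(sos, recording.samples.astype(np.float64), axis=1)
    return replace(
        recording, samples=filtered.astype(recording.samples.dtype)
    )


@dataclass
class FeatureTensor:
    """Binned RMS features with optional stacked history and labels.

    ``rms`` is bins x channels; ``stacked`` row t concatenates rms rows
    t-3..t (oldest first); ``valid_mask`` flags bins with complete history.
    """

    rms: np.ndarray
    bin_width_s: float = BIN_WIDTH_S
    stacked: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    labels: np.ndarray | None = None
    norm_stats: "NormStats | None" = None

    @property
    def n_bins(self) -> int:
        return self.rms.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rms.shape[1]


def rms_bins(recording: EMGRecording, bin_width_s: float = BIN_WIDTH_S) -> FeatureTensor:
    """RMS per consecutive non-overlapping bin; trailing partial bin discarded."""
    n_per = int(round(bin_width_s * recording.sampling_rate))
    n_t = recording.samples.shape[1]
    if n_t < n_per:
        raise ValueError("recording shorter than one bin")
    n_bins = n_t // n_per
    x = recording.samples[:, : n_bins * n_per].astype(np.float64)
    x = x.reshape(recording.n_channels, n_bins, n_per)
    rms = np.sqrt(np.mean(x**2, axis=2)).T  # bins x channels
    labels = recording.schedule.labels_for_bins(n_bins, bin_width_s)
    return FeatureTensor(rms=rms, bin_width_s=bin_width_s, labels=labels)


def stack_history(ft: FeatureTensor, k: int = HISTORY_BINS) -> FeatureTensor:
    """Concatenate each bin with its k-1 predecessors (oldest first).

    Bins with fewer than k-1 preceding bins in the record are marked
    invalid; their rows are built by repeating the earliest available bin
    so shapes stay rectangular, but downstream selection must honour
    ``valid_mask``.
    """
    if k < 1:
        raise ValueError("history length k must be >= 1")
    n_bins, n_ch = ft.rms.shape
    idx = np.arange(n_bins)[:, None] - np.arange(k - 1, -1, -1)[None, :]
    valid = idx[:, 0] >= 0
    idx = np.clip(idx, 0, None)
    stacked = ft.rms[idx].reshape(n_bins, k * n_ch)
    return replace(ft, stacked=stacked, valid_mask=valid)


@dataclass(frozen=True)
class NormStats:
    """Per-feature mean/variance fitted on training data; variance floored."""

    mean: np.ndarray
    var: np.ndarray
    eps: float = 1e-12

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "var": self.var.tolist(), "eps": self.eps}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.asarray(d["mean"]), np.asarray(d["var"]), float(d.get("eps", 1e-12)))


def fit_normalizer(train_features: np.ndarray, eps: float = 1e-12) -> NormStats:
    x = np.asarray(train_features, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    return NormStats(mean=x.mean(axis=0), var=np.maximum(x.var(axis=0), eps), eps=eps)


def apply_normalizer(features: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(features, dtype=np.float64) - stats.mean) / np.sqrt(stats.var)


def normalize_features(ft: FeatureTensor, stats: NormStats) -> FeatureTensor:
    """Standardize the per-channel RMS bins (before history stacking)."""
    out = replace(ft, rms=apply_normalizer(ft.rms, stats), norm_stats=stats)
    if ft.stacked is not None:
        out = stack_history(out, k=ft.stacked.shape[1] // ft.n_channels)
    return out


@dataclass
class CenterWindowDataset:
    """Stacked samples drawn from the middle W seconds of each segment.

    Per retained segment the count is round(W / 0.1) - 3: the window's bins
    minus the first three, whose 400 ms context reaches outside the window.
    """

    X: np.ndarray  # samples x (channels*4)
    y: np.ndarray  # class indices
    bin_indices: np.ndarray  # bin index into the source FeatureTensor
    segment_ids: np.ndarray  # index of the source segment in the schedule
    width_s: float


def extract_center_windows(
    ft: FeatureTensor, schedule: CueSchedule, width_s: float
) -> CenterWindowDataset:
    """Take the centred ``width_s`` window of every segment long enough.

    Segments shorter than the window are skipped with a warning. The first
    three bins of each extracted window are dropped.
    """
    if ft.stacked is None:
        ft = stack_history(ft)
    n_target = int(round(width_s / ft.bin_width_s))
    if n_target <= 3:
        raise ValueError("window too short: no bins remain after dropping the first 3")
    rows, labels, bins_, segs_ = [], [], [], []
    for si, seg in enumerate(schedule.segments):
        if seg.duration_s < width_s - 1e-9:
            logger.warning(
                "segment %d (%s, %.2f s) shorter than %.2f s window; skipped",
                si, seg.label, seg.duration_s, width_s,
            )
            continue
        mid = 0.5 * (seg.onset_s + seg.offset_s)
        start_bin = int(round((mid - width_s / 2) / ft.bin_width_s))
        start_bin = max(start_bin, 0)
        stop_bin = min(start_bin + n_target, ft.n_bins)
        sel = np.arange(start_bin + 3, stop_bin)
        rows.append(ft.stacked[sel])
        labels.append(np.full(sel.size, CLASS_INDEX[seg.label]))
        bins_.append(sel)
        segs_.append(np.full(sel.size, si))
    if not rows:
        raise ValueError("no segment is long enough for the requested window")
    return CenterWindowDataset(
        X=np.concatenate(rows),
        y=np.concatenate(labels),
        bin_indices=np.concatenate(bins_),
        segment_ids=np.concatenate(segs_),
        width_s=width_s,
    )


def preprocess_recording(
    recording: EMGRecording,
    spec: FilterSpec | None = None,
    norm_stats: NormStats | None = None,
):
    """Filter -> RMS bins -> (fit or apply) normalizer -> stacked history.

    Returns ``(FeatureTensor, NormStats)``. When ``norm_stats`` is None the
    statistics are fitted on this recording's bins (training role);
    otherwise the supplied training statistics are applied (testing role).
    """
    filtered = bandpass_notch(recording, spec)
    ft = rms_bins(filtered)
    if norm_stats is None:
        norm_stats = fit_normalizer(ft.rms)
    ft = replace(ft, rms=apply_normalizer(ft.rms, norm_stats), norm_stats=norm_stats)
    ft = stack_history(ft)
    return ft, norm_stats
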