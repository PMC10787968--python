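"""Streaming decoder with probability-threshold and stability debouncing.

The raw per-bin argmax flips too easily between classes to drive an
assistive device, so the online decoder changes state only when (a) the
candidate class's probability exceeds 0.6 on every bin of a pending run
and (b) the same candidate repeats for two consecutive bins. A replay
harness drives the full causal pipeline — streaming filter state, per-bin
RMS, 4-bin history, training-statistics normalization, model inference,
policy step — over 100 ms frames, and matches the batch pipeline exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy import signal as _signal

from .decoder import DecoderResults, hard_labels
from .preprocess import (
    BIN_WIDTH_S,
    HISTORY_BINS,
    FilterSpec,
    NormStats,
    design_filter_sos,
)
from .simulate import CLASS_INDEX, REST, EMGRecording


@dataclass(frozen=True)
class OnlinePolicy:
    """Debounce policy: probability threshold + consecutive-bin stability."""

    prob_threshold: float = 0.6
    stability_count: int = 2
    initial_state: int = CLASS_INDEX[REST]

    def __post_init__(self):
        if not (0.0 < self.prob_threshold):
            raise ValueError("prob_threshold must be positive")
        if self.stability_count < 1:
            raise ValueError("stability_count must be >= 1")


@dataclass(frozen=True)
class DecoderState:
    """Fully serializable debouncer state."""

    current_class: int
    pending_class: int = -1
    pending_run_length: int = 0
    bins_processed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "DecoderState":
        return cls(**json.loads(s))


def initial_state(policy: OnlinePolicy) -> DecoderState:
    return DecoderState(current_class=policy.initial_state)


def step(
    state: DecoderState, prob_vector: np.ndarray, policy: OnlinePolicy
) -> tuple[DecoderState, int]:
    """One debouncer update; returns (new state, emitted class).

    The argmax candidate (ties toward the lowest index) joins the pending
    run only if its probability exceeds the threshold and it differs from
    the current class; a bin that breaks the run — different candidate or
    sub-threshold — resets it. When the run reaches ``stability_count``
    the decoder state switches.
    """
    p = np.asarray(prob_vector, dtype=np.float64)
    if p.ndim != 1 or p.size == 0 or np.any(p < -1e-9):
        raise ValueError("probability vector must be 1-D and non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"probabilities must sum to 1 (got {p.sum():.6f})")

    cand = int(np.argmax(p))
    cur, pend, run = state.current_class, state.pending_class, state.pending_run_length
    if cand != cur and p[cand] > policy.prob_threshold:
        run = run + 1 if cand == pend else 1
        pend = cand
        if run >= policy.stability_count:
            cur, pend, run = cand, -1, 0
    else:
        pend, run = -1, 0
    new = DecoderState(
        current_class=cur,
        pending_class=pend,
        pending_run_length=run,
        bins_processed=state.bins_processed + 1,
    )
    return new, cur


def apply_policy(
    probs: np.ndarray, policy: OnlinePolicy, class_indices=None
) -> np.ndarray:
    """Run the debouncer over a batch of per-bin probability rows.

    ``class_indices`` maps probability columns to global class indices
    (identity when omitted). The returned stream is in global indices.
    """
    state = initial_state(policy)
    out = np.empty(probs.shape[0], dtype=np.int64)
    if class_indices is None:
        for i, row in enumerate(probs):
            state, out[i] = step(state, row, policy)
        return out
    class_indices = np.asarray(class_indices)
    # run the policy in local column space, then map to global indices
    local_init = int(np.argmax(class_indices == policy.initial_state)) if (
        policy.initial_state in class_indices
    ) else 0
    state = DecoderState(current_class=local_init)
    for i, row in enumerate(probs):
        state, emitted = step(state, row, policy)
        out[i] = class_indices[emitted]
    return out


class StreamingDecoder:
    """Causal per-frame pipeline around a fitted decoder.

    Carries the band-pass/notch filter state across frames so that
    streaming filtering equals batch causal filtering exactly. Bins whose
    4-bin history is incomplete emit the current (initial) state without
    consulting the model.
    """

    def __init__(
        self,
        results: DecoderResults,
        norm_stats: NormStats,
        sampling_rate: float,
        n_channels: int,
        policy: OnlinePolicy | None = None,
        filter_spec: FilterSpec | None = None,
    ):
        self.results = results
        self.norm_stats = norm_stats
        self.policy = policy or OnlinePolicy()
        self.fs = sampling_rate
        self.n_channels = n_channels
        self.sos = design_filter_sos(filter_spec or FilterSpec(), sampling_rate)
        self.zi = np.zeros((self.sos.shape[0], n_channels, 2))
        self.history: list[np.ndarray] = []
        cls_idx = results.class_indices
        local = int(np.argmax(cls_idx == self.policy.initial_state)) if (
            self.policy.initial_state in cls_idx
        ) else 0
        self.state = DecoderState(current_class=local)
        self.frame_len = int(round(BIN_WIDTH_S * sampling_rate))

    def push_frame(self, frame: np.ndarray):
        """Process one 100 ms frame; returns (global class, prob row or None)."""
        if frame.shape != (self.n_channels, self.frame_len):
            raise ValueError(
                f"expected frame of shape ({self.n_channels}, {self.frame_len}), "
                f"got {frame.shape}"
            )
        filt, self.zi = _signal.sosfilt(
            self.sos, frame.astype(np.float64), axis=1, zi=self.zi
        )
        rms = np.sqrt(np.mean(filt**2, axis=1))
        rms = (rms - self.norm_stats.mean) / np.sqrt(self.norm_stats.var)
        self.history.append(rms)
        if len(self.history) > HISTORY_BINS:
            self.history.pop(0)
        if len(self.history) < HISTORY_BINS:
            self.state = replace(
                self.state, bins_processed=self.state.bins_processed + 1
            )
            return int(self.results.class_indices[self.state.current_class]), None
        x = np.concatenate(self.history)[None, :]
        probs = self.results.predict_proba(x)[0]
        self.state, emitted = step(self.state, probs, self.policy)
        return int(self.results.class_indices[emitted]), probs


def replay(
    recording: EMGRecording,
    results: DecoderResults,
    norm_stats: NormStats,
    policy: OnlinePolicy | None = None,
    static_shift_s: float = 0.3,
):
    """Replay a recording through the streaming pipeline frame by frame.

    Returns ``(decoded, probs, shifted_schedule)``: one global class index
    per 100 ms bin, the per-bin probability rows (NaN while history is
    filling), and the cue schedule shifted by the online reaction-time
    convention for scoring.
    """
    from .align import static_shift as _static_shift

    dec = StreamingDecoder(
        results, norm_stats, recording.sampling_rate, recording.n_channels,
        policy=policy,
    )
    n_bins = recording.samples.shape[1] // dec.frame_len
    decoded = np.empty(n_bins, dtype=np.int64)
    n_classes = len(results.classes)
    probs = np.full((n_bins, n_classes), np.nan)
    for b in range(n_bins):
        frame = recording.samples[:, b * dec.frame_len : (b + 1) * dec.frame_len]
        decoded[b], row = dec.push_frame(frame)
        if row is not None:
            probs[b] = row
    shifted = (
        _static_shift(recording.schedule, static_shift_s)
        if static_shift_s
        else recording.schedule
    )
    return decoded, probs, shifted
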