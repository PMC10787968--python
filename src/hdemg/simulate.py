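"""Synthetic high-density sleeve EMG with known ground truth.

Emulates the structure of a cued movement-recording session: a forearm
sleeve of bipolar channels laid out in rings (elbow to wrist) and angular
sectors (flexor/extensor sides), blocks that open with an 8 s lead-in rest
followed by alternating movement cues and rests, movement-specific spatial
activation patterns, per-cue reaction latency between cue onset and actual
EMG onset, 60 Hz line interference, and band-limited baseline noise.

Amplitude during a movement is controlled by an observed-movement score in
{0,1,2,3} (0 = no visible movement, 3 = normal), and spatial localization
degrades with an impairment level in [0, 1].
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

REST = "Rest"

#: The 12 cued movements, in the canonical order; Rest is class index 0.
MOVEMENTS = (
    "Hand Close",
    "Hand Open",
    "Index Extension",
    "Thumb Flexion",
    "Thumb Extension",
    "Thumb Abduction",
    "Forearm Supination",
    "Forearm Pronation",
    "Wrist Flexion",
    "Wrist Extension",
    "Two Point Pinch",
    "Key Pinch",
)

#: All 13 classes: Rest first, then the cued movements.
CLASSES = (REST,) + MOVEMENTS

CLASS_INDEX = {label: i for i, label in enumerate(CLASSES)}

_SLEEVE_CHANNELS = {"small": 64, "medium": 71, "large": 75}
_N_SECTORS = 8

# Movements whose prime movers sit on the flexor (volar) vs extensor
# (dorsal) aspect of the forearm; used to place activation blobs on the
# anatomically plausible side of the sleeve.
_FLEXOR_MOVEMENTS = frozenset(
    {
        "Hand Close",
        "Thumb Flexion",
        "Thumb Abduction",
        "Wrist Flexion",
        "Two Point Pinch",
        "Key Pinch",
        "Forearm Pronation",
    }
)


@dataclass(frozen=True)
class SleeveLayout:
    """Bipolar-channel grid of a sized sleeve.

    Channels are laid out row-major over rings along the forearm (ring 0 at
    the elbow) and 8 angular sectors around it; sectors 0-3 overlie the
    flexor side, 4-7 the extensor side. Electrode centres are 25 mm apart.
    """

    size_class: str
    n_channels: int
    grid: dict[int, tuple[int, int]]  # channel -> (ring, sector)
    side_labels: tuple[str, ...]  # per-sector "flexor"/"extensor"
    electrode_spacing_mm: float = 25.0

    @property
    def n_rings(self) -> int:
        return 1 + max(r for r, _ in self.grid.values())


def make_sleeve_layout(size_class: str) -> SleeveLayout:
    """Build the channel grid for a small/medium/large sleeve (64/71/75 channels)."""
    if size_class not in _SLEEVE_CHANNELS:
        raise ValueError(
            f"unknown sleeve size {size_class!r}; valid options: small, medium, large"
        )
    n = _SLEEVE_CHANNELS[size_class]
    grid = {ch: divmod(ch, _N_SECTORS) for ch in range(n)}
    sides = tuple(
        "flexor" if s < _N_SECTORS // 2 else "extensor" for s in range(_N_SECTORS)
    )
    return SleeveLayout(size_class=size_class, n_channels=n, grid=grid, side_labels=sides)


@dataclass(frozen=True)
class Segment:
    label: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class CueSchedule:
    """Ordered, gap-free labelled segments (movement cues and rests)."""

    segments: tuple[Segment, ...]
    lead_in_rest_s: float = 8.0
    profile: str = "stroke"

    def __post_init__(self):
        prev_off = 0.0
        for seg in self.segments:
            if not math.isclose(seg.onset_s, prev_off, abs_tol=1e-9):
                raise ValueError(
                    f"segments must tile time: segment {seg.label!r} starts at "
                    f"{seg.onset_s} but previous ended at {prev_off}"
                )
            if seg.offset_s <= seg.onset_s:
                raise ValueError(f"segment {seg.label!r} has non-positive duration")
            prev_off = seg.offset_s

    @property
    def duration_s(self) -> float:
        return self.segments[-1].offset_s

    @property
    def boundaries_s(self) -> np.ndarray:
        """Interior boundary times (between consecutive segments)."""
        return np.array([seg.onset_s for seg in self.segments[1:]])

    def labels_for_bins(self, n_bins: int, bin_width_s: float = 0.1) -> np.ndarray:
        """Class index per bin; a bin belongs to the segment containing its start."""
        starts = np.arange(n_bins) * bin_width_s
        out = np.empty(n_bins, dtype=np.int64)
        seg_iter = iter(self.segments)
        seg = next(seg_iter)
        for i, t in enumerate(starts):
            while t >= seg.offset_s - 1e-9:
                nxt = next(seg_iter, None)
                if nxt is None:
                    break
                seg = nxt
            out[i] = CLASS_INDEX[seg.label]
        return out

    def with_boundaries(self, boundaries_s) -> "CueSchedule":
        """Same labels/extent with interior boundaries replaced."""
        bounds = [self.segments[0].onset_s, *boundaries_s, self.segments[-1].offset_s]
        segs = tuple(
            Segment(seg.label, bounds[i], bounds[i + 1])
            for i, seg in enumerate(self.segments)
        )
        return replace(self, segments=segs)

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "lead_in_rest_s": self.lead_in_rest_s,
            "segments": [
                {"label": s.label, "onset_s": s.onset_s, "offset_s": s.offset_s}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CueSchedule":
        segs = tuple(
            Segment(s["label"], float(s["onset_s"]), float(s["offset_s"]))
            for s in d["segments"]
        )
        return cls(
            segments=segs,
            lead_in_rest_s=float(d.get("lead_in_rest_s", 8.0)),
            profile=d.get("profile", "stroke"),
        )


_PROFILE_RANGES = {"stroke": (4.0, 6.0), "able": (2.0, 3.0)}


def make_cue_schedule(
    movements,
    reps_per_movement: int,
    profile: str = "stroke",
    seed: int | None = None,
    lead_in_rest_s: float = 8.0,
) -> CueSchedule:
    """Alternating rest/cue schedule with randomized movement order.

    Opens with an 8 s lead-in rest; each cue and each interleaved rest has
    a duration drawn uniformly from the profile range (4-6 s for the stroke
    profile, 2-3 s for able-bodied). Each repetition round presents every
    requested movement once in shuffled order.
    """
    movements = list(movements)
    if not movements:
        raise ValueError("movement list must be non-empty")
    for m in movements:
        if m not in MOVEMENTS:
            raise ValueError(f"unknown movement {m!r}")
    if reps_per_movement < 1:
        raise ValueError("reps_per_movement must be >= 1")
    if profile not in _PROFILE_RANGES:
        raise ValueError(f"unknown profile {profile!r}; valid options: stroke, able")
    lo, hi = _PROFILE_RANGES[profile]
    rng = np.random.default_rng(seed)

    order: list[str] = []
    for _ in range(reps_per_movement):
        round_ = list(movements)
        rng.shuffle(round_)
        order.extend(round_)

    segs = [Segment(REST, 0.0, lead_in_rest_s)]
    t = lead_in_rest_s
    for mv in order:
        d_cue = rng.uniform(lo, hi)
        segs.append(Segment(mv, t, t + d_cue))
        t += d_cue
        d_rest = rng.uniform(lo, hi)
        segs.append(Segment(REST, t, t + d_rest))
        t += d_rest
    return CueSchedule(segments=tuple(segs), lead_in_rest_s=lead_in_rest_s, profile=profile)


@dataclass(frozen=True)
class LatencyModel:
    """Per-boundary reaction delay: uniform on [low_s, high_s], support in [0, 2]."""

    low_s: float = 0.2
    high_s: float = 1.2

    def __post_init__(self):
        if not (0.0 <= self.low_s <= self.high_s <= 2.0):
            raise ValueError("latency support must satisfy 0 <= low <= high <= 2 s")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low_s, self.high_s, size=n)


@dataclass(frozen=True)
class SimulationParams:
    sampling_rate: float = 3000.0
    pattern_spread: float = 1.0  # spatial SD of activation blobs, grid units
    impairment: float = 0.0  # in [0,1]; de-localizes patterns
    snr_db: float = 15.0  # movement-to-rest RMS ratio at the blob centre
    latency_model: LatencyModel = field(default_factory=LatencyModel)
    line_noise_amp: float = 2.0  # 60 Hz amplitude, uV
    baseline_rms: float = 5.0  # rest-state RMS per channel, uV
    movement_scores: dict | None = None  # label -> 0..3; default all 3
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if not (0.0 <= self.impairment <= 1.0):
            raise ValueError("impairment must lie in [0, 1]")
        if self.pattern_spread <= 0:
            raise ValueError("pattern_spread must be positive")

    def effective_spread(self) -> float:
        # impairment=1 triples the blob SD: activity spreads over neighbours
        return self.pattern_spread * (1.0 + 2.0 * self.impairment)


_SCORE_SCALE = {0: 0.0, 1: 0.33, 2: 0.66, 3: 1.0}


@dataclass(frozen=True)
class GroundTruth:
    true_segments: CueSchedule  # cue boundaries after applying latencies
    patterns: dict[str, np.ndarray]  # movement -> per-channel weights in [0,1]
    observed_movement_score: dict[str, int]
    boundary_latencies_s: np.ndarray  # per interior boundary, signed


@dataclass
class EMGRecording:
    """Raw multi-channel EMG (channels x time, uV) with its cue schedule."""

    samples: np.ndarray
    sampling_rate: float
    layout: SleeveLayout
    schedule: CueSchedule
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"channel count {self.samples.shape[0]} does not match layout "
                f"({self.layout.n_channels} channels)"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


def _blob_center(label: str, layout: SleeveLayout, occupied: set) -> tuple[int, int]:
    """Deterministic grid placement by hashing the movement label.

    Flexion-type movements land on flexor sectors, extension-type on
    extensor sectors; collisions probe forward so every movement gets a
    distinct centre.
    """
    h = int.from_bytes(hashlib.md5(label.encode()).digest()[:8], "big")
    n_rings = layout.n_rings
    half = _N_SECTORS // 2
    base = 0 if label in _FLEXOR_MOVEMENTS else half
    ring = h % n_rings
    sector = base + (h // n_rings) % half
    while (ring, sector) in occupied:
        sector += 1
        if sector >= base + half:
            sector = base
            ring = (ring + 1) % n_rings
    occupied.add((ring, sector))
    return ring, sector


def movement_patterns(
    layout: SleeveLayout, movements, spread: float
) -> dict[str, np.ndarray]:
    """Per-movement channel weights: a Gaussian blob on the sleeve grid.

    Distance wraps in the angular direction (the sleeve is a cylinder);
    weights are normalized to peak 1.
    """
    rings = np.array([layout.grid[c][0] for c in range(layout.n_channels)], float)
    sectors = np.array([layout.grid[c][1] for c in range(layout.n_channels)], float)
    occupied: set = set()
    patterns = {}
    for m in movements:
        r0, s0 = _blob_center(m, layout, occupied)
        d_ring = rings - r0
        d_sec = np.abs(sectors - s0)
        d_sec = np.minimum(d_sec, _N_SECTORS - d_sec)  # circular wrap
        d2 = d_ring**2 + d_sec**2
        w = np.exp(-d2 / (2.0 * spread**2))
        patterns[m] = w / w.max()
    return patterns


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple, fs: float
) -> np.ndarray:
    """Unit-RMS noise confined to the 20-400 Hz analysis band.

    White noise pushed through the same Butterworth design used by the
    preprocessing band-pass, then rescaled per channel to unit RMS.
    """
    from .preprocess import FilterSpec, design_bandpass_sos

    sos = design_bandpass_sos(FilterSpec(), fs)
    x = rng.standard_normal(shape)
    x = _signal.sosfilt(sos, x, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / rms


def simulate_emg(
    schedule: CueSchedule, layout: SleeveLayout, params: SimulationParams
) -> EMGRecording:
    """Synthesize a sleeve recording for a cue schedule.

    Signal model: every channel always carries band-limited baseline noise
    (RMS ``baseline_rms``) plus a 60 Hz sinusoid of amplitude
    ``line_noise_amp``. During movement *m*'s true activity interval — the
    cue interval with each boundary shifted by an independently drawn
    reaction latency — independent band-limited noise is added whose
    per-channel RMS is ``baseline_rms * 10**(snr_db/20)`` scaled by the
    movement's spatial weight vector and its observed-movement-score
    amplitude factor {0, 0.33, 0.66, 1.0}.
    """
    fs = params.sampling_rate
    n_t = int(round(schedule.duration_s * fs))
    n_ch = layout.n_channels
    rng = np.random.default_rng(params.seed)

    scores = {m: 3 for m in MOVEMENTS}
    if params.movement_scores:
        for k, v in params.movement_scores.items():
            if k not in MOVEMENTS or v not in _SCORE_SCALE:
                raise ValueError(f"invalid movement score entry {k!r}: {v!r}")
            scores[k] = v

    present = [m for m in MOVEMENTS if any(s.label == m for s in schedule.segments)]
    patterns = movement_patterns(layout, present, params.effective_spread())

    # latencies: one signed delay per interior boundary (cue onsets and offsets)
    n_bounds = len(schedule.segments) - 1
    lat = params.latency_model.draw(rng, n_bounds)
    cue_bounds = schedule.boundaries_s
    true_bounds = cue_bounds + lat
    # keep boundaries ordered and inside the record
    true_bounds = np.clip(true_bounds, 1e-3, schedule.duration_s - 1e-3)
    true_bounds = np.maximum.accumulate(true_bounds)
    true_schedule = schedule.with_boundaries(true_bounds)

    sig = _bandlimited_noise(rng, (n_ch, n_t), fs) * params.baseline_rms

    amp0 = params.baseline_rms * 10.0 ** (params.snr_db / 20.0)
    for seg in true_schedule.segments:
        if seg.label == REST:
            continue
        a = amp0 * _SCORE_SCALE[scores[seg.label]]
        if a <= 0:
            continue
        i0 = int(round(seg.onset_s * fs))
        i1 = int(round(seg.offset_s * fs))
        if i1 <= i0:
            continue
        burst = _bandlimited_noise(rng, (n_ch, i1 - i0), fs)
        sig[:, i0:i1] += burst * (a * patterns[seg.label][:, None])

    if params.line_noise_amp:
        t = np.arange(n_t) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        sig += params.line_noise_amp * np.sin(
            2 * np.pi * 60.0 * t[None, :] + phases[:, None]
        )

    gt = GroundTruth(
        true_segments=true_schedule,
        patterns=patterns,
        observed_movement_score={m: scores[m] for m in present},
        boundary_latencies_s=lat,
    )
    return EMGRecording(
        samples=sig.astype(np.float32),
        sampling_rate=fs,
        layout=layout,
        schedule=schedule,
        ground_truth=gt,
    )
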