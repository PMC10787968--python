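# Methods

## Problem setting

A wearable forearm sleeve records dozens of bipolar surface-EMG channels
(64, 71 or 75 depending on sleeve size; 3 kHz sampling) while a user is
cued to attempt one of 12 functional hand/wrist/forearm movements with
interleaved rests. The decoding task is 13-class (12 movements + Rest)
classification of 100 ms time bins. Users with post-stroke hemiparesis
produce weak, spatially de-localized EMG and react to cues with large,
variable latency; both effects are modelled explicitly.

## Feature pipeline

Raw channels are filtered causally (forward-only) with a 20–400 Hz
Butterworth band-pass of 10th-order transfer function (realized as
second-order sections; SciPy's band-pass design doubles the requested
order, so `butter(5, ...)`) cascaded with a 60 Hz notch. The notch
quality factor is not dictated by the decoding problem; Q = 30 keeps the
−3 dB notch width near 2 Hz, sparing the pass-band. Causality is chosen
over zero-phase filtering so the offline pipeline is bit-identical to
what an online system can compute; the streaming decoder carries the
filter state across 100 ms frames and reproduces batch filtering exactly.

RMS is taken over consecutive non-overlapping 100 ms bins (300 samples at
3 kHz; trailing partial bins are discarded, never padded). Features are
standardized per channel using mean/variance fitted on training data
only (variance floored at 1e-12 to guard constant channels), and
standardization is applied to the per-bin RMS *before* history stacking,
so all four lags of a channel share one statistic. Each prediction sample
concatenates the current bin and its three predecessors (400 ms); the
first three bins of a record have incomplete history and are flagged
invalid. A bin is labelled by the segment containing its start time
(half-open bins).

For offline model comparison, the middle W seconds of every cue and rest
segment are extracted (W = 2.5 s for the stroke profile, 1.5 s able) and
the first three bins of each window are dropped because their stacked
context reaches outside the window — round(W/0.1) − 3 samples per
segment, i.e. 22 and 12.

## Dynamic cue alignment

The alignment signal is the across-channel mean of the normalized RMS at
100 ms resolution (the construction is a design choice; per-channel or
raw-signal residuals would also be defensible). With segment boundaries
taken from the cue schedule, the objective is the total within-segment
sum of squared residuals around per-segment means. Boundaries are
optimized by exhaustive coordinate descent on the bin grid: sweeping
boundaries in temporal order, each is placed at the SSR-minimizing
position within ±2 s of its cued position, subject to ordering and every
segment keeping ≥1 bin, repeated until a sweep moves nothing (or 50
sweeps). Ties break toward the smaller shift, so already-aligned
boundaries stay put. SSR is non-increasing by construction and per-sweep
evaluation is O(1) per candidate via prefix sums. Shifts in both
directions are allowed by default; a `forward_only` flag restricts to
delays. Labels, segment count and order never change.

Static baselines translate every interior boundary by a constant
(0.8 s as an offline reaction-time estimate; 0.3 s in the online
convention).

## Classifiers

* **PCA + LR / PCA + SVM** — PCA is fitted on training data only,
  keeping the smallest component set explaining ≥95% of variance.
  Hyperparameters (C for LR; C and gamma for the RBF SVM) are selected by
  5-fold stratified cross-validated grid search over 9 log-spaced points
  in 1e-4…1e4 each; ties break toward the smallest C, then gamma, making
  selection invariant to sample order on cleanly separable data. The
  winning point is refitted on all training data. SVM probabilities come
  from Platt scaling on the final refit only (the grid is scored on hard
  accuracy), which cuts grid-search cost about five-fold.
* **MLP** — input (channels × 4) → dense 1000 → batch-norm → ReLU →
  dropout 0.2 → dense 500 → batch-norm → ReLU → dropout 0.2 → dense
  n-classes → softmax, written directly on NumPy with hand-derived
  backpropagation. Training: label-smoothing cross entropy with
  target-class probability 0.9 (remainder spread uniformly), Adam,
  one-cycle learning-rate schedule (cosine warm-up over the first 25% of
  steps from max_lr/25 to max_lr = 1e-3, then cosine anneal to
  max_lr/1e4), mini-batches of 64, up to 400 epochs with early stopping
  on a seeded random 10% validation split (patience 20, best weights
  restored). The early-stopping rule and validation split are design
  choices where several are defensible; validation *loss* is monitored
  because it is smoother than accuracy at these sample sizes.

Hard labels are the probability argmax with ties broken toward the
lowest class index (Rest first). Models persist as a single `.npz`
bundle: a JSON metadata record plus raw weight arrays for the MLP, or a
joblib payload for the sklearn estimators; round-trips preserve
predictions exactly (the MLP to float64 bit-equality).

## Metrics

Accuracy is the fraction of 100 ms bins predicted equal to ground truth;
chance level is the majority-class fraction (the best constant
predictor). Success rate scores each cue binarily: success requires ≥10
consecutive correct bins (1 s) lying strictly within the cue — runs
crossing cue edges do not count. Rest periods are excluded from the
success-rate denominator by default (`include_rest=True` inverts this).
Subset analyses (Rest-vs-Move; fixed {Rest, Hand Close, Hand Open};
Rest + top-k movements ranked by cross-validated per-class training
accuracy — never test data) subsample rest bins from the rest cue
immediately preceding each retained movement cue, in temporal order,
until rest is 50% of samples (within one sample), making subset chance
level 0.5.

## Synthetic data generator

The simulator emulates the *structure* of sleeve sessions, not muscle
physiology. Channels sit on a ring × 8-sector cylindrical grid (25 mm
pitch; sectors 0–3 flexor, 4–7 extensor). Each movement's spatial
pattern is a Gaussian blob (SD `pattern_spread`, default 1 grid unit)
centred at a deterministic, hash-derived grid cell on the anatomically
plausible side, with collision probing so centres are distinct.
Impairment ∈ [0,1] scales the blob SD by (1 + 2·impairment), so severe
impairment spreads activity across neighbouring channels and raises
inter-movement pattern similarity. Signals are band-limited noise
(white noise through the same 20–400 Hz design used in preprocessing,
rescaled to unit RMS): a baseline floor of 5 µV RMS on all channels,
plus, during each movement's *true* activity interval, an independent
burst whose per-channel RMS is baseline × 10^(SNR/20) × pattern weight ×
an observed-movement-score factor {0, 0.33, 0.66, 1.0} for scores
0–3. A 60 Hz sinusoid (default 2 µV, random phase per channel) is added
throughout. True activity intervals are the cue intervals with each
boundary delayed by an independently drawn reaction latency, uniform on
[0.2, 1.2] s by default — inside the 2 s shift cap and centred near the
high-hundreds-of-ms delays typical of impaired reaching — and recorded in
the ground truth exactly.

Default SNR is 15 dB at the blob centre; no public amplitude
distributions exist for this device class, so SNR is a free parameter of
the study conditions, chosen once as "clearly detectable but not
saturating" and not tuned thereafter.

The generator omits, deliberately: motor-unit dynamics, volume
conduction, electrode-skin impedance, motion artifacts, inter-session
electrode shift, and spectral differences between movements. Passing
tests therefore demonstrate the *pipeline's* correctness (label
alignment, windowing, training discipline, debouncing) under controlled
conditions — not clinical decoding performance on real subjects, whose
headline accuracies depend on data this package cannot ship.

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale, chosen as the smallest
configurations that still exercise every code path: able-profile blocks
(2–3 s segments), the 64-channel sleeve, 2–3 repetitions per movement,
and a 50-epoch version of the network recipe for the three-classifier
comparison (the full 400-epoch recipe is the default elsewhere). The
classifier comparison uses impairment 0 and zero latency, where the
separability of the simulated patterns makes near-ceiling accuracy the
correct outcome; the comparison's value is directional (all models far
above chance; the network not behind the linear models), not the
clinical magnitudes. Cue-shift recovery uses SNR 12 dB and uniform
[0.2, 1.2] s latencies over 20 simulated blocks.

Degenerate inputs: constant features normalize to 0; segments shorter
than the extraction window are skipped with a warning; schedules are
validated to tile time without gaps or overlaps; probability vectors
must sum to 1 within 1e-6 at the policy boundary.

## Known limitations

* Simulator realism as above; no claim of clinical performance.
* The SVM's Platt-scaled probabilities are calibrated on training data
  only and can be over-confident on small sets.
* Dynamic alignment assumes a piecewise-constant activity summary; slow
  ramps in amplitude bias recovered boundaries toward the ramp midpoint.
* ONNX/EDF interchange is not provided; the native formats are the
  `.npz` model bundle and HDF5/JSON data files.
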