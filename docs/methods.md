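# Methods

## Problem

Ground-contact (GC) detection in the acceleration phase of an athletic
sprint: given two resultant channels from a shank-mounted IMU — resultant
acceleration `a_RES` and resultant angular velocity `ω_RES`, both the
Euclidean norm of the raw tri-axial components, resampled to 250 Hz — label
every frame as contact (1) or flight (0). Contacts are the maximal runs of
1s; their boundaries are the initial-contact (IC, 0→1) and terminal-contact
(TC, 1→0) transitions, and their durations are the contact times that
sprint analysis cares about. Heuristic detectors (peak/threshold rules)
degrade in the acceleration phase, where step-to-step dynamics change the
most; the approach here is a learned per-timestep classifier.

## Model

The classifier is a stack of inception blocks adapted for dense per-frame
output. Each block computes

```
R(x) = BN(W_r ∗ x)                               (pointwise residual, C_in→128)
I(x) = BN([b1(x) ‖ b3(x) ‖ b5(x) ‖ b7(x)])       (4 branches, 32 channels each)
y    = ReLU(I(x) + R(x))
```

with branch `b1` a single pointwise convolution `C_in→32` and branches
`bk, k ∈ {3,5,7}` a pointwise bottleneck `C_in→32` followed by a kernel-k
temporal convolution `32→32`. The first block sees `C_in = 2`; all later
blocks see 128. The equations carry *no* activation or normalization inside
the branches, and that literal form is what is implemented (canonical
InceptionTime adds per-branch BN/ReLU; the alternative was noted and not
taken). After the last block a pointwise `128→1` convolution with bias and
a sigmoid give one contact probability per timestep. All convolutions are
same-padded (symmetric zero padding `(k−1)/2`), so the sequence length is
preserved end to end.

Implementation notes:

* The network, batch normalization, Adam and backpropagation are
  implemented directly in NumPy (float32), with each convolution evaluated
  as one BLAS contraction per kernel tap — for kernels ≤ 7 this is fast and
  keeps the code transparent. Gradient correctness is locked down by a
  finite-difference test over every parameter class.
* Convolutions followed by BN carry no bias (it is absorbed by BN); the
  head carries one.
* Weights are Kaiming-uniform (fan-in) initialized from a seeded generator;
  the seed is part of `ModelSpec`.
* Batch norm uses momentum 0.1, eps 1e-5, biased batch variance, and
  running statistics in eval mode. A layer whose running statistics were
  never updated (a freshly initialized model) falls back to batch
  statistics even in eval mode: the `(0, 1)` placeholders would otherwise
  leave the deep residual stack unnormalized (variance roughly doubles per
  block through `I + R`) and saturate the head. Trained or loaded models
  always use running statistics and are exactly deterministic.

## Dataset machinery

* **Scaling** — per run and per channel, min–max to `[−1.5, 1.5]`;
  touchdown peak magnitudes vary strongly across athletes/steps/legs and
  carry arbitrary units, and the per-run scale removes both. A degenerate
  constant channel maps to the midpoint 0. Channel-wise granularity is a
  deliberate choice: the two channels have unrelated units.
* **Windowing** — fixed-length windows of `T` frames cut every `stride`
  frames starting at frame 0; incomplete windows at the end of a run are
  discarded, so `N = floor((L − T)/stride) + 1`. `stride ≥ T` is rejected
  (the tuning grid skips such combinations).
* **Reassembly** — per-window probabilities are averaged over all windows
  covering each frame (raw probabilities, not binarized votes); frames
  covered by no complete window are reset to 0. Slicing the label tensor
  itself and reassembling reproduces the labels exactly on covered frames,
  which is tested.

## Training and tuning

Adam on mean per-timestep binary cross-entropy, batch 50, at most 30
epochs. Early stopping: strictly-lower-than-best validation BCE counts as
improvement; five consecutive non-improving epochs stop training, and the
best-validation-epoch weights are restored (the stated purpose is
overfitting avoidance, which implies restoration; "improve" tolerance and
restoration were both open and resolved this way). The tuning grid is
window ∈ {25,50,75,100,150,200} × stride ∈ {5,...,30} × blocks ∈
{6,...,21} × lr ∈ {0.01, 0.001, 0.0001}, 612 valid combinations, searched
exhaustively in process (the original sweep ran through an external
service; the search space is identical). The objective is the mean
per-stream averaged transition distance on VAL, computed on postprocessed
predictions — model selection should not be steered by trivially removable
prediction spikes. Ties prefer fewer blocks, then larger stride.

## Postprocessing and metrics

Probabilities are binarized at 0.5 (`≥ 0.5 → 1`); predicted contacts
strictly shorter than 12 frames (48 ms at 250 Hz, about half the shortest
elite sprint contact) are removed — a 12-frame contact is kept. Open-ended
contacts touching a stream boundary are flagged and excluded from duration
statistics.

* **Transition ("Hausdorff") distances** — IC and TC indices pooled per
  side; the symmetric nearest-neighbour distance multiset (one distance
  per true and per predicted transition) is summarized by its mean and
  median per stream. The classical Hausdorff maximum cannot produce the
  sub-integer per-run means these summaries are meant to convey and is
  exposed only as an option (`kind="max"`).
* **Event precision/recall** — greedy one-to-one overlap matching in
  temporal order; a match requires ≥ 1 shared frame. The matching rule was
  open; greedy temporal matching is the simplest deterministic rule that
  yields 100%/100% on near-perfect output. Precision with no predictions
  is reported as 1.0 (no false positives exist), recall as 0.
* **Rand index** — frame-level clustering agreement from the 2×2 confusion
  counts in closed form, property-tested against O(L²) pair enumeration
  and scikit-learn's `rand_score`.
* **Aggregation** — per-stream values first, then across streams: mean ±
  sample SD (ddof = 1, documented convention) for mean Hausdorff,
  precision, recall and Rand index; median ± MAD for the median Hausdorff.
  Frame quantities are mirrored in ms (×1000/fs).

## Agreement statistics

Contact-duration pairs come from the same overlap matching (step index =
temporal rank of the true contact, 1-based). Differences are fixed as
PRED − GT. Bland–Altman reports bias, 1.96·SD limits of agreement, and a
heteroscedasticity flag from regressing |d| on the pair means (r² > 0.1;
regressing signed d is available as an option — the regressed quantity was
unspecified). Wilcoxon signed-rank uses the Pratt zero rule with effect
size r = |Z|/√n and the conventional bands (<0.2 trivial, 0.2–0.49 small,
0.5–0.79 medium, ≥0.8 large); all-zero differences short-circuit to
p = 1, r = 0 rather than erroring. Spearman ρ is labeled on the Hopkins
bands. MAPE = mean(|d|/GT)·100 and RMSE = √mean(d²). A Shapiro–Wilk +
Levene gate records the parametric/nonparametric decision (nonparametric
if any p < 0.05). The frame-quantization bound — IC may be one frame early
and TC one frame late even at frame-perfect detection — is
2·(1000/fs)/GC·100 %, e.g. 8.5% for a 94 ms contact at 250 Hz.

## Synthetic study

The athlete recordings are not public, so a seeded generator reproduces
the study conditions: 12 athletes (6 F/6 M) × 3 runs × 2 legs with run 3
of athlete 1 excluded → 70 streams; athletes 2–11 contribute runs 1–2 to
TRAIN (40 streams) and run 3 to VAL (20); athletes 1 and 12 are held out
as TEST (10). Per-step contact durations are Gaussian with the observed
step-specific means/SDs (184 ± 30 ms at step 1 down to 104 ± 5 ms at step
10), rounded to frames and floored at 13 frames so no true contact can be
destroyed by the 12-frame postprocessing filter. Flight times follow a
contact-fraction schedule falling linearly from 77.4% of the step cycle at
step 1 to 50% at step 8, constant after. Signal morphology is an
invention (the real waveforms are unavailable): `a_RES` carries a damped
25 Hz oscillation at each IC riding on an elevated stance plateau against
a low flight baseline; `ω_RES` carries a Gaussian swing bump centred
mid-flight. Amplitudes take a per-athlete factor (uniform on [0.6, 1.6],
drawn once per athlete and keyed by athlete id so regeneration is
split-stable) times a per-step log-normal jitter (σ = 0.15) — this
heterogeneity is injected deliberately so per-run min–max scaling is
consequential. Additive Gaussian noise is 5% of each channel's impact
amplitude; channels are clipped at 0. An optional integer label lag
exercises the cross-correlation synchronizer, which recovers the injected
lag exactly from impact peaks vs label ICs.

What the generator does **not** emulate: real waveform spectra and
amplitudes (the study reports none — these parameters are realistic-order
choices, not estimates), velocity profiles, bilateral coupling between
legs, surface or footwear effects, and video labeling noise. Because the
labels are a nearly deterministic function of the synthetic signals, the
synthetic task is easier than the real one: passing end-to-end checks
demonstrates that the pipeline is implemented coherently (the model can
learn frame-accurate boundaries, the plumbing preserves alignment), not
that the architecture would reach the same accuracy on real athletes.

## Reference experiment and problem sizes

The packaged end-to-end experiment trains a 6-block model (window 100,
stride 15, lr 0.01 — stride/window/lr at the tuned optimum, block count at
the small end of the tuned grid, chosen as the package's default
single-CPU configuration) on the default synthetic study: ~1 400 training
windows, early stopping typically ends training within 10–20 epochs. On
the held-out synthetic TEST split this reaches 100% event precision and
recall and a per-stream-averaged Rand index ≈ 0.998. The full 18-block
optimum is available via `ModelSpec(n_blocks=18)`.

## Numerical choices and degenerate inputs

* Resampling is polyphase FIR (`scipy.signal.resample_poly`,
  1125→250 Hz = ratio 2/9) with output length `round(L·ratio)`; constant
  signals survive to within FIR passband ripple (~1e-5 relative), and
  small negative FIR ring on the nonnegative resultants is clipped to 0.
* Synchronization scans integer lags in `[−max_lag, +max_lag]` counting
  exact event coincidences of the two impulse trains; ties prefer the
  smallest |lag| (then the negative one); no coincidence at any lag is an
  explicit "unsynchronizable" error. It returns the lag to apply to the
  second train; jitter of ±1 frame on a minority of events leaves the peak
  unchanged.
* Metrics with no events (empty prediction or truth) are reported as
  missing values with cause, never silently dropped.
* All randomness flows through `numpy.random.default_rng`; per-run and
  per-athlete seeds derive from the master seed plus string keys via
  CRC-32, and per-combination tuning seeds from the master seed plus grid
  index.

## Known limitations

* The synthetic benchmark upper-bounds nothing about real-data accuracy
  (see above); reported headline numbers on it are pipeline checks.
* `tune()` over the full 612-combination grid is supported but
  computationally serious on one CPU; the tests exercise it on restricted
  grids.
* The Wilcoxon effect size uses the normal-approximation Z even at small
  n (matched-pairs rank-biserial is an alternative the literature also
  uses; the approximation is what the reported bands assume).
* Sub-frame event interpolation is out of scope: all timing quantities are
  quantized to the 4 ms frame grid at 250 Hz.
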