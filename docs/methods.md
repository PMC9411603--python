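# Methods

## The classification problem

One sample is a 12-lead ECG record sampled at 500 Hz (leads I, II, III,
aVR, aVL, aVF, V1–V6; voltages in mV), of variable duration, with patient
age and sex and exactly one rhythm label out of nine: normal sinus rhythm,
atrial fibrillation (AF), first-degree AV block (I-AVB), left/right bundle
branch block (LBBB/RBBB), premature atrial/ventricular contraction
(PAC/PVC), and ST-segment depression/elevation (STD/STE). Records that
carry several diagnoses are reduced to their first label — the model is a
single 9-way softmax, and secondary labels are retained only for audit.

## Two-dimensional representation and slicing

The 12 lead time-series become the columns of a matrix A ∈ ℝ^{L×12}
treated like a grayscale image; a trailing channel axis of size 1 makes the
slices 2D-convolution inputs of shape 8192×12×1. The fixed window of 8192
samples (16.384 s) is a power of two so that repeated 0.5× temporal
downsampling lands on integer lengths; it sits just above the ~16 s mean
record duration of the data profile the generator emulates. Windows
overlap by 4096 samples; short records are zero-padded, records below
1.5×8192 samples are tail-truncated, and records at or above that
threshold yield n = ⌊2L/8192⌋ − 1 overlapping slices, which augments the
training set with the long records' extra content. Slices inherit their
record's label.

Pipeline order is: bandpass filter → 2D construction → min–max
normalization of the whole record → slicing → dimension expansion. Two
consequences are deliberate: (i) all slices of a record share one affine
normalization map, whose parameters are returned for audit; (ii) padding
happens in the normalized domain, so padded samples are exactly 0.
Because rule 2 truncates tails (and rule 3 may leave an uncovered tail
shorter than 4096 samples), a record's global extremum can fall outside
every slice: the ±3 mV endpoints are guaranteed on the normalized record,
and slices are guaranteed to stay inside the interval.

Normalization rejects constant records (zero amplitude range) rather than
guessing; degenerate inputs are a data error, not a case to patch silently.

## Filtering

Denoising is a Butterworth bandpass, 0.5–49 Hz, order 3, applied
forward-backward (`sosfiltfilt`) per lead. Zero-phase filtering is chosen
because phase distortion would shift the clinically meaningful wave
boundaries (PR, ST segments) that the classes manipulate. The squared
magnitude response of the zero-phase realization is the oracle for every
attenuation claim: |H|² ≈ 1.0 at 10 Hz, 0.50 at the 0.5/49 Hz cutoffs,
0.47 at 50 Hz, 0.007 at 100 Hz. Note that an order-3 band edge at 49 Hz
attenuates 50 Hz mains by only ~53% in power; the filter's job is broadband
cleanup, and the Welch PSD diagnostic (`welch_diagnostic_plot`, windows
blackman/hanning/triangular × segment lengths 256/512/1024) is the
qualitative check that content above the cutoff collapses.

## DSE-ResNet

The trunk is 10 residual blocks of two Conv2D layers each — 20
convolutions, kernel (32, 1) — with batch normalization, ReLU and dropout
after each convolution. Channels run 12→24→48→96→192, doubling every four
convolutions (two blocks per stage). Block 1 (block-1) preserves
dimensions; blocks 2–10 (block-2) halve the time axis with a stride-2
first convolution, giving nine halvings (8192 → 16). Shortcuts use (2, 1)
max pooling for the temporal adjustment and zero-padding for channel
growth; the branch and shortcut are summed without a post-activation. The
lead axis is never downsampled.

The kernel (32, 1) means every convolution looks along time within one
lead; channels mix per lead position, identically for all leads. The
*detached* SE module sits after the whole trunk: global average pooling
over (time, lead) squeezes the 192-channel output to one vector, four
dense layers (ReLU bottlenecks of width 192/4, sigmoid output) produce a
channel gate, and the gate rescales the trunk output. Because every trunk
operation is lead-symmetric, a network that also pooled the head over
leads would be *exactly* invariant to lead permutation — the montage
would carry no information. The head therefore pools over time only and
flattens the (lead × channel) map into a 2304-vector, giving the head
lead-specific weights; with this wiring a permutation of the lead columns
measurably changes the output, as it must if inter-lead structure is to be
used. This was the one genuinely open wiring decision; the alternative
(per-lead SE squeeze) adds far more parameters for the same effect.

Age and sex enter the head as two scalars concatenated to the pooled
features: age/100 (missing → training-set mean), sex ∈ {0, 1} (female = 0,
male = 1, missing → 0.5). A two-layer dense head (width 32, ReLU) ends in
the 9-way softmax; training minimizes mean softmax cross-entropy (a
uniform predictor scores ln 9 ≈ 2.197).

### The numpy engine

Layers (time-axis Conv2D via strided windows + tensordot, batchnorm,
inverted dropout, (2,1) max pool, dense, SE gating) carry explicit
`forward`/`backward` methods in float32; the optimizer is SGD with
classical momentum (v ← μv − lr·∇; w ← w + v). Weight init is a
fan-in-scaled truncated normal (±2σ), seeded. Correctness is tested by
finite-difference checks per layer and end-to-end, by a
loss-decreases-after-one-step smoke test, and by driving a reduced network
to ≥95% training accuracy in 200 steps.

Two numerical details matter. First, mini-batch batchnorm statistics drift
during training, and evaluating with exponential running averages can
misrepresent a freshly trained network; after training (and before each
validation measurement) the running statistics are re-estimated as the
arithmetic mean of batch statistics over the training set with frozen
weights and dropout disabled. Second, ReLU is `np.maximum(x, 0)` so NaN
propagates: a diverged fold surfaces as a non-finite loss and is aborted
rather than silently "recovering" through a NaN-swallowing activation.

## Hyperparameter design

The tuned factors are learning rate {0.05, 0.1, 0.15}, dropout
{0.3, 0.5, 0.8} and momentum {0.5, 0.7, 0.9}. Instead of the 27-point
grid, a strength-2 covering array guarantees every cross-factor level pair
appears in at least one run. The published ten-run table is shipped
verbatim (`REFERENCE_TABLE`, verified 27/27 pairs) so experiments can use
the exact historical design; `generate` builds fresh arrays greedily (row
seeded from an uncovered pair, per-factor level chosen to maximize newly
covered pairs, ties broken by factor then level order; the seed only
permutes the per-row factor visiting order). Generated arrays are always
verified complete by exhaustive enumeration and never exceed the full
factorial.

## Training protocol, selection, ensembling

Per combination: stratified k-fold cross-validation (default k = 5) split
**by record**, so all slices of a record share a fold — slice-level splits
would leak overlapping windows across the train/validation boundary. The
stratifier deals each class's shuffled records round-robin with a rolling
fold pointer, keeping both fold sizes and class counts within ±1; classes
with fewer records than folds are assigned round-robin with a warning.
Default 50 epochs with best-validation-epoch checkpointing: the selected
weights never come from beyond the epoch with the lowest validation loss.
The fold with the lowest validation loss averaged over its final 5 epochs
(a window that damps epoch-to-epoch noise; the average of a single stated
epoch would be brittle) becomes the combination's *single optimal model*.

Inference on a record preprocesses it to slices, averages the per-slice
softmax vectors and takes the argmax. The ensemble collects each single
optimal model's record-level label and applies a plurality vote; ties
break by the highest summed probability among tied labels, then by class
order, with a `tie_broken` flag recorded. Voting cannot be guaranteed to
beat every constituent, so the tested property is non-degradation
(ensemble macro F1 within 0.05 of the best single model) rather than
strict dominance.

## Metrics

All per-class scores are one-vs-rest on the fixed-order 9×9 confusion
matrix; F1 uses the 0-convention when precision+recall is 0. Sensitivity
is numerically identical to recall. Sub-abnormal F1 merges the member
rows/columns into a super-class before scoring — the only construction
under which a single-member group (AF) reproduces the per-class value
exactly, and under which within-group confusions (e.g. LBBB predicted as
RBBB) are not errors. Row/column totals are conserved by merging. Reported
values round to 3 decimals.

## Synthetic data

The generator emulates the statistical profile the method assumes:
500 Hz, 12 leads, lognormal durations (μ = 2.6595, σ = 0.4756, clipped to
6–60 s) giving mean ≈16 s and ~12.7% of records beyond 1.5× the 16.384 s
window — the proportions that exercise all three slicing branches in
realistic ratios; a class mix defaulting to the strongly imbalanced
training-set profile of the public challenge data (RBBB and AF dominant,
LBBB and STE rare); heart rate 55–100 bpm; age ~N(60, 16²) years clipped
to 18–92, sex Bernoulli(½), each missing with probability 0.02.

A beat is five Gaussian bumps (P, Q, R, S, T) with fixed per-lead
polarity/scale factors from standard lead geometry (aVR inverted, deep S
in V1/V2, tall R in II/V4); amplitudes are lead-II mV values (R = 1.2 mV).
Class rules: AF — i.i.d. RR jitter (σ = 0.25·RR, giving cv ≥ 0.15) and
zero P amplitude; I-AVB — P peak 280 ms before R; LBBB/RBBB — QRS
complexes widened beyond 120 ms with gain patterns concentrated in the
leads where these blocks manifest (LBBB: I, V5, V6 positive, V1, V2, aVR
inverted; RBBB: tall wide V1–V3); PAC/PVC — every ~8th beat premature by
0.32·RR, the PVC variant with a wide, 1.6× tall, T-inverted ectopic
complex; STD/STE — a smooth ST plateau of ∓/± 0.1–0.3 mV between S and T.
Additive noise: per-lead baseline wander (0.1 mV, 0.3 Hz), common 50 Hz
line interference (0.05 mV), white noise (0.03 mV).

What the generator does **not** model: realistic QRS micro-morphology,
respiration-modulated wander, electrode artifacts, rhythm transitions
within a record, or multi-label pathology. Tests passing on this data show
the pipeline's operators respond to the features the classes manipulate —
not that the classifier reaches clinical performance on real ECG.
Built-in instrumentation (`detect_r_peaks`, `measure_features`) verifies
the fingerprints independently of the network: a threshold detector
recovers the configured heart rate within 10%, and a depth-1 rule cascade
on (RR cv, QRS width, ST offset) separates AF/Block/ST/Normal with >90%
accuracy on noise-free records, which is what makes the training smoke
tests learnable by construction.

## Problem sizes used in tests

Desk-scale runs use reduced configurations with the full wiring: slice
length 1024 (2.048 s), kernel 16, channels (4, 8) — 4 residual blocks, 8
convolutions — on 2-second noise-free records, batch 8–16, 6–10 epochs,
2 folds. The full-size network (8192×12×1 input, 20 convolutions, ~5.5M
parameters) is built and structurally verified but not trained in the test
suite. The end-to-end nine-class experiment trains 2 combinations × 2
folds on 63 records and evaluates on 27; it completes in roughly a minute
on one CPU with macro F1 far below the small-data ceiling — the assertion
is pipeline integrity and ensemble non-degradation, not headline accuracy.

## Known limitations

- The numpy engine is single-threaded-BLAS bound; full-scale (8192-input)
  training is out of scope for the test suite, though the code path is
  identical.
- WFDB support covers the single-file, 12-signal, format-16 layout only.
- The covering-array generator is greedy, not minimal: it matches the
  10-row reference for the 3×3×3 space but offers no optimality guarantee
  for larger spaces (row count ≤ full factorial is asserted instead).
- Early stopping restores the best-validation checkpoint within a fixed
  epoch budget; there is no patience-based abort.
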