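# Methods

## The problem and the model

`predann` trains a recognition model that identifies which song a
listener heard from a short window of multichannel EEG.  The difficulty
is that EEG is noisy and indirect, while the stimulus itself is clean
and information-rich.  The package's core idea is to use the
representation that a stimulus-side artificial neural network assigns to
the same music interval as an auxiliary supervisory signal for the EEG
model: if cortical and network representations of the same sound are
similar, predicting the network representation should help the EEG
encoder extract the stimulus-locked component of its input.

Two structurally identical convolutional encoders process the two
modalities independently (no shared parameters).  Each feeds two heads:
Projector I produces class logits over the `K` songs; Projector II
produces a contrastive embedding.  For a paired mini-batch of size `B`
with EEG embeddings `z^EII_i` and music embeddings `z^MII_i`, the
objective is

    L = L_clsE + L_clsM + λ · L_pred

where `L_clsE` and `L_clsM` are summed cross-entropies on the class
logits of each branch, and `L_pred` is a symmetric InfoNCE term over
temperature-scaled cosine similarities

    L_pred = − Σ_i [ log softmax_j( sim(sg(z^MII_i), z^EII_j)/τ )|_{j=i}
                   + log softmax_j( sim(sg(z^MII_j), z^EII_i)/τ )|_{j=i} ]

with `sg(·)` a stop-gradient on the music embeddings.  Both terms share
the matched-pair numerator; the first normalizes over EEG candidates for
a fixed music anchor, the second over music anchors for a fixed EEG
candidate.  Every off-diagonal pair in the batch is a negative,
regardless of class label — the loss is index-based, not label-masked.
The stop-gradient is the asymmetry that defines the method: the EEG
branch is trained to *predict* the stimulus representation while the
stimulus branch is shaped only by its own classification loss, so
alignment cannot degrade the stimulus-side features.  Setting `λ = 0`
recovers the classification-only baseline; disabling the stop-gradient
gives the symmetric ("stop-gradient-free") ablation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `λ` (`lambda_predann`) | 0.05 | weight of the contrastive term; 0 = baseline |
| `τ` (`temperature`) | 0.1 | similarity sharpening; constant, not learned |
| `stop_gradient` | on | blocks contrastive gradients into the music branch |
| `window_seconds` | 3 | training/evaluation window length |
| `delay_ms` | 200 | assumed stimulus-to-response latency; the EEG window starts this much later than the paired audio window |
| `train_stride_samples` | 200 | grid spacing of training windows (with a fresh random clip offset per epoch) |
| `eval_stride_samples` | 1 | window spacing at evaluation (desk-scale runs use 125 = 1 s) |
| `clamp bound` | ±20 | post-scaling amplitude clamp |
| `train_fraction` | 0.75 | stratified excerpt split, stratified on song label |

Preprocessing order is fixed: per-channel robust scaling
(median/interquartile range, linear-interpolation quartiles) first, then
clamping.  Channels with zero IQR are centered only and flagged with a
warning rather than dividing by zero.  Recordings are truncated to a
shared duration and cut into 30-s excerpts, which are the sampling units
of the stratified split.  Sample indices are 0-based, windows are
half-open `[start, start+W)`, delays round to the nearest sample, and
windows whose delayed end would cross an excerpt boundary are dropped
rather than zero-padded.

## Differentiation engine and encoders

No GPU tensor framework is required: the model is a nested dict of
numpy arrays, and all layers (temporal/2-D convolution via per-tap
tensor contractions, average pooling, linear heads) are composed from
reverse-mode-differentiable primitives (HIPS autograd).  This keeps runs
bit-reproducible given a seed and makes the stop-gradient contract
*exactly* auditable: `predann_gradient_norms` differentiates the
contrastive term alone and verifies the music branch's gradient is
identically zero, and every training run records this audit once.

All convolutions use kernel 3, stride 1, padding 1, so they preserve
temporal (and spatial) extent; only pooling downsamples.  Two families
are provided: `cnn1d` treats the EEG as channels × time, and `cnn2d`
lays each signal out as a single-plane grid (electrodes × time for EEG;
a height-1 grid for audio, so 2-D kernels act temporally).  The encoders
use conv → ReLU → average-pool blocks *without* batch normalization:
batch statistics would make outputs depend on batch composition, which
conflicts with the package's determinism contracts (identical inputs →
identical outputs under fixed weights; checkpoint reload reproduces
validation accuracy exactly) and is unstable at the small batch sizes
used here.  Optimization is Adam (lr 1e-3 default; the desk-scale study
uses 3e-3), batch 64, no schedule.  An "epoch" is one pass over the
stride grid of training windows with fresh random clip offsets, so over
many epochs every part of the signal is visited.  Checkpoint selection
is best window-level validation accuracy.

## The synthetic data generator

The generator emulates the structure — not the biophysics — of a
naturalistic music-listening EEG study.  Each of `K` stimuli combines a
class-specific carrier (6 + 3.5c Hz) and amplitude-modulation rate
(1 + 0.6c Hz) with a song-unique random envelope fluctuation of ~1.5 Hz
bandwidth.  The class-specific rates make songs separable; the unique
fluctuation gives each song a temporal fingerprint, so that windows
*within* a song are mutually distinguishable.  That fingerprint is what
makes the stimulus-to-response latency identifiable to the contrastive
objective: at ~1.5 Hz bandwidth the envelope decorrelates over a few
hundred milliseconds, matching the latency scale being probed, as in
real envelope-tracking work.

The neural response is the stimulus amplitude envelope (rectified,
8 Hz low-passed) convolved with a fixed front-loaded 3-tap kernel
(1.0, 0.3, 0.1), delayed by `delay_ms`, mixed into channels by
subject-specific standard-normal weights, plus per-channel noise (white
by default, pink behind a flag) scaled so the realized per-channel
SNR equals `snr_db` exactly.  The front-loaded kernel keeps the
stimulus–response cross-correlation peak at exactly the generating
latency.  Generation is a pure function of the config; every class,
latency, mixing vector and SNR is recorded as ground truth.

What the generator does **not** emulate: volume conduction, oscillatory
background (alpha), artifacts, non-stationarity, inter-subject latency
differences, or real music spectra.  Passing the study below therefore
shows the *pipeline and objective* behave as intended under a forward
model where the answer is known — not that any particular accuracy is
attainable on real recordings.

## The desk-scale study

The packaged study conditions are 5 songs × 2 subjects × 8 channels at
125 Hz, 120 s per (subject, song) recording (→ 40 excerpts, split 30/10),
3-s windows, generating latency 200 ms, 40 training epochs, λ ∈ {0, 0.05},
seeds {0, 1, 2}.  These sizes keep one end-to-end run at roughly half a
minute on one CPU while leaving every studied effect measurable:

* **High SNR (+6 dB)**: validation window accuracy reaches ≈0.98,
  far above the 0.2 chance level — the noise-free sanity check.
* **Low SNR (−10 dB)**: chosen so the classification-only baseline sits
  clearly above chance but well below ceiling (≈0.51 mean over seeds),
  the regime where auxiliary supervision can matter.  There the
  contrastive model (λ = 0.05) improves on the baseline in every seed
  (≈0.56 mean) — the direction, not the magnitude, of the full-scale
  finding.
* **Evaluation length**: longer excerpts (3→7 s, overlapping 3-s windows
  at a 1-s stride, non-overlapping length-L units tiled over validation
  excerpts) give non-decreasing mean-method accuracy.
* **Latency sweep**: retraining with assumed delays {0, 100, 200, 400} ms
  on 200 ms data localizes the optimum to the neighborhood of the
  generating latency.  At this scale the delay sensitivity is weak
  (differences of a few points over seeds), so the sweep localizes the
  optimum only to "at or adjacent to" the true value.

## Aggregation and statistics

For excerpts longer than the training window, per-window softmax vectors
are combined by **mean** (column-wise average), **max** (column-wise
maximum; one confident window can decide), or **majority** (per-window
argmax, then the modal class, ties broken by the earliest window's
prediction — the rule that reproduces the packaged worked example
exactly).  Exact argmax ties in mean/max resolve to the lowest class
index.

Paired models are compared with McNemar's test on binary
correct/incorrect arrays over the same items.  The default is the exact
two-sided binomial on the discordant counts,
`p = 2·P(X ≤ min(n01, n10) | n01+n10, ½)` capped at 1 (robust at small
discordant counts); a continuity-corrected chi-square variant is
available for large samples.  Zero discordant pairs yield p = 1 by
convention.  Per-song accuracies aggregate count-weighted across
subjects, so each complete partition's weighted mean equals the overall
accuracy.

## Numerical notes and limitations

* Softmaxes subtract a detached row maximum before exponentiation;
  cosine similarity normalizes each row internally, so Projector II
  outputs are not forcibly unit-normalized.
* The contrastive loss is summed (not averaged) over the batch, like the
  classification terms, so λ's meaning does not drift with batch size.
* Zero embedding rows and zero vectors in cosine similarity raise
  errors; `B = 1` batches give a zero contrastive loss by construction.
* The stratified split realizes the 75:25 ratio within integer rounding
  per class and is reproducible from its seed; classes with a single
  excerpt cannot be stratified and are rejected.
* The optional MATLAB v7.3 reader is a thin HDF5 accessor for real-data
  containers; it is never exercised by the synthetic path.
* Training at the full-study scale (thousands of epochs, 128 channels,
  20 subjects) is out of desk-scale reach; the packaged study is a
  scaled-down analogue whose purpose is directional, not quantitative,
  agreement.
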