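# Methods

## Problem setting

Two-class motor-imagery (MI) decoding from simultaneously recorded EEG and
fNIRS, with an emphasis on *cross-subject* generalization: a new (target)
subject contributes few labeled trials, and the decoder borrows structure
from an automatically chosen source subject per modality.  The package
implements the full chain — preprocessing, time-frequency
characterization, modality-specific CNN base networks, Wasserstein
trusted-score source selection, DCCA+CORAL transfer losses,
accuracy-weighted multimodal fusion, and cross-validated evaluation —
together with a synthetic paired EEG+fNIRS generator so the whole chain is
testable without any recorded data.

## Preprocessing

EEG: anti-aliased down-sampling to 200 Hz, zero-phase Butterworth band-pass
0.5–50 Hz (order 4, applied forward–backward so ERD latency is not
shifted), trials cut over the 10 s task window, and per-channel subtraction
of the mean of the 3 s pre-stimulus interval (ending at cue onset).  The
2 s cue is excluded from the trial window by default; a config switch
includes it, and an explicit `epoch_window_s` override supports analysis
epochs that include the baseline.

fNIRS: optional modified Beer–Lambert conversion of two-wavelength optical
density into ΔHbO/ΔHbR (extinction coefficients from the Gratzer
compilation; DPF 6.4 / 5.75 at 760 / 850 nm, overridable; source–detector
distance 3 cm), zero-phase band-pass 0.01–0.1 Hz, epoching at the native
rate with floor rounding, baseline subtraction over the 3 s pre-task
interval, and an optional resample-to-length (100 samples) that reproduces
the reference network input exactly.  By default the HbO chromophore feeds
the network; HbR is available via config.

## Time-frequency analysis

The short-time Fourier transform is the standard discrete one: frames
fully inside the signal, Hann window of 1 s with 50 % overlap by default
(≈1 Hz resolution, enough to resolve the 8–12 Hz alpha band over a 10 s
trial), one-sided magnitude-squared coefficients scaled so that with a
rectangular window and non-overlapping frames total spectrogram power
equals total signal energy.  Band edges: δ 0.5–4, θ 4–8, α 8–12, β 12–27,
γ 27–45 Hz.  ERD is quantified as the ratio of mean band power in the task
window to mean band power in the pre-stimulus baseline; for an oscillation
whose amplitude is scaled by `1 − d` during the task the expected ratio is
`(1 − d)²` plus the in-band noise floor.

## Base networks

Each modality has a three-block 1-D CNN feature extractor and a single
linear classifier to two logits.  Blocks: Conv1 (kernel 63, pad 31 for
EEG; 36/18 for fNIRS) → BN → sigmoid; Conv2 (kernel 30, no padding for
EEG; 101/50 for fNIRS) → BN → sigmoid → average pooling ÷4; depthwise
separable Conv3 (per-channel kernel 15, pad 7, then a 1×1 pointwise mix)
→ BN → sigmoid → average pooling ÷2 → flatten.  Filter counts F1 = 16 and
F2 = F1·D with D = 4.  Sigmoid activations follow the reference
architecture (not the ELU/ReLU customary in EEG CNNs).

Two printed lengths of the fNIRS table are mutually inconsistent with the
convolution/pooling formulas (Conv1 101 vs printed 100; the final pooling
prints 17 where floor division gives 12).  Pooling is therefore
implemented as *adaptive* average pooling to an explicit output length —
which is also how the reference text describes its pooling — with the
final fNIRS pooling targeting the printed 17 in the default
table-compatible mode, and Conv1 cropped by one sample.  A strict-formula
mode (`table_compat=False`) uses plain floor-division pooling instead.

Training: Adam (lr 0.001), softmax cross-entropy, batch 16, shuffled per
epoch from a named seed; batch-norm uses batch statistics in training and
frozen running statistics at evaluation.  Validation accuracy comes from a
held-out stratified 20 % split; the best-epoch snapshot is restored and
early stopping triggers after 20 epochs without improvement.  Weight
initialization is a uniform fan-in scheme.  The networks, their backward
passes and the optimizer are implemented directly on numpy arrays; every
analytic gradient is verified against central finite differences in the
test suite.

Because of the best-epoch snapshot, the recorded validation accuracy is an
optimistic estimate on small validation sets; chance-level assertions in
the tests therefore always score an independent test split.

## Source-domain selection

A subject is converted to empirical distributions channel by channel: all
preprocessed trial samples of one channel pool into one 1-D distribution.
The distance between two subjects is the mean over channels of the
channelwise order-1 Wasserstein distance (sorted-quantile coupling; the
translation property W(X, X+c) = |c| holds channelwise and is used as a
test oracle).  Alternatives (per-trial sliced Wasserstein, joint
multivariate transport, feature-space distances) are deliberate
extensions, not defaults.

Each subject's trusted score is

    T_k = Acc_k · (1 − Norm(mean_i W(k, i))),

where Acc_k is the subject's own validation accuracy and Norm min–max
normalizes the mean distance to all *other* subjects (self-term excluded)
across the roster.  If all mean distances are equal the normalization is
degenerate and Norm is defined as 0, so T_k = Acc_k.  The source subject
per modality is the trusted-score argmax with deterministic tie-breaks
(higher accuracy, lower mean distance, lexicographic id).  A shared-source
variant takes the argmax of the summed two-modality scores (the
same-source ablation arm).  Note that at the roster extremes min–max
normalization forces T_k = 0 regardless of accuracy; monotonicity of T_k
in Acc_k holds strictly only for subjects with normalized distance < 1.

## Transfer losses

For source features F_s and target features F_t (rows = trials):

* **Deep CORAL**: `‖C_s − C_t‖²_F / (4d²)` with unbiased covariances.
  Computed via Gram matrices (`tr(C_a C_b) = ‖X̃_a X̃_bᵀ‖²_F /
  ((n_a−1)(n_b−1))`), so no d×d matrix is ever formed and the loss scales
  to the flattened CNN feature dimension (d = 15 744 for the full EEG
  network).
* **DCCA**: minus the sum of the top-k singular values of
  `T = H_ss^{−1/2} H_st H_tt^{−1/2}` with ridge-regularized covariances
  (r = 1e-3 default) and an eigenvalue floor of 1e-8.  T is evaluated
  exactly in the row spaces of the centered batches (thin SVDs), again
  avoiding d×d matrices; the dense-covariance computation serves as a test
  oracle.  Batches are paired by position; source and target loaders use
  equal batch sizes reshuffled per epoch.  The loss is bounded in [−k, 0].
  k defaults to 1 (the leading canonical correlation): with transfer-time
  batches of ~16 trials in feature spaces of hundreds of dimensions, most
  canonical correlations of the whitened cross-covariance are spurious,
  and a large-k loss both overwhelms the cross-entropy in magnitude and —
  because batch pairing is blind to class — actively rewards
  class-invariant features.  Empirically, the capped-at-10 default turned
  the transfer gain negative on the simulator, while k = 1 preserves it;
  k remains fully configurable.  An optional class-conditioned variant
  (off by default) instead pairs labeled target trials with same-class
  source trials for the DCCA term, matching the within-class-alignment
  motivation of the loss, and further stabilizes training.
* **MMD** (ablation baseline): unbiased squared maximum mean discrepancy
  with a multi-bandwidth Gaussian kernel (median-heuristic × {0.5, 1, 2}
  by default).

The combined transfer loss of the full method is
`L_trans = L_dcca + L_coral`; the ablation arms substitute CORAL-only or
MMD-only.  All three losses have closed-form gradients with respect to
both feature batches (the DCCA gradient follows the canonical-correlation
singular-value derivative, carried in the low-rank bases), checked against
finite differences.

## Fusion model and transfer training

The fusion model initializes the two extractors from the selected source
subjects' checkpoints and classifies the weighted concatenation
`[a·F_eeg, b·F_nirs]` with one linear head — no hidden layers.  The
weighted *sum* form of the mixing equation is dimensionally impossible for
unequal feature lengths and contradicts the stated direct-connection
concatenation; weighted concatenation realizes the mixing ratio while
matching the described architecture.  The weights come from the target
subject's single-modality validation accuracies,
`a = A_eeg/(A_eeg+A_nirs)`, `b = A_nirs/(A_eeg+A_nirs)`, fixed at
pretraining time (not recomputed during transfer).

Each training step pairs a labeled target batch (cross-entropy through the
fused head) with equal-size source/target batches per modality whose
extracted features feed the transfer losses; the total objective

    L = L_clf + a·L_trans_eeg + b·L_trans_fnirs

is backpropagated with Adam at lr 0.001.  Both extractors remain trainable
(a freeze flag exists); labeled target trials are the CV training folds
while all target trials contribute (unlabeled) to the transfer losses.
Setting the transfer scale to 0 reduces the procedure exactly to
supervised fine-tuning, which doubles as the no-transfer baseline arm.

Batch-norm bookkeeping: the transfer-loss forward passes (source batches
and unlabeled target batches) normalize with their own batch statistics
but do **not** update the running statistics — only the labeled target
classification passes do.  Evaluation therefore normalizes with
statistics of the distribution the classifier was actually fit on;
letting source batches contaminate the running statistics measurably
degraded target predictions.

## Evaluation

Stratified 5-fold cross-validation (folds computed once per subject per
seed and shared across method arms), accuracy / precision / recall / F1
from 2×2 confusion matrices with the positive class fixed to *left*
(class 0), reported as percent mean ± SD (per-subject accuracy averages
folds; the pooled trace/sum accuracy is also recorded).  Zero-denominator
precision/recall is reported as 0 with a degenerate flag.  The Friedman
rank test compares methods across subjects on identical partitions; an
all-constant-rows matrix returns statistic 0, p = 1 by definition.

## Synthetic generator

EEG: per-channel 1/f-shaped Gaussian background (spectrally shaped white
noise), plus 10 Hz alpha and 20 Hz beta oscillations weighted by a smooth
"sensorimotor" bump per hemisphere (with per-subject jitter, and an option
to scramble the pattern as a negative control).  During the task window
the contralateral oscillation amplitude is multiplied by `1 − erd_depth`
with a 0.5 s ramp; the ipsilateral side desynchronizes by a quarter of the
depth.  Patient-like subjects multiply the ERD depth of the impaired side
by 0.2.  Defaults: alpha amplitude 4 µV, beta 2 µV, background std =
snr × alpha amplitude with snr 0.25 — fixed once so that the ERD
power-ratio recovery is accurate to ±0.05 across the depth grid at the
default trial count, before any downstream test was written.

fNIRS: ΔHbO = double-gamma kernel (unit peak, canonical 6/16 shape
parameters) convolved with the task boxcar, delayed by `hemo_delay`,
stronger contralaterally (ipsilateral 0.3×), normalized so the planted
contralateral peak equals `hemo_gain` (default 1 µM); ΔHbR = −0.3 × ΔHbO;
plus a ~0.095 Hz physiological oscillation, slow linear drift and white
noise (all scaled by `hemo_gain` and switchable to zero for oracle tests).

Populations draw per-subject parameters i.i.d. (ERD depth N(0.5, 0.08)
clipped to [0, 1], hemodynamic gain N(1, 0.2), delay N(1, 0.3) s, snr
N(0.25, 0.05), overall gain N(1, 0.15)) from seeds derived
deterministically from a master seed.  Labels alternate left/right through
the session schedule; the default paradigm is 2 s cue, 10 s task, 15 s
rest, 15 trials per hand per session, two sessions (60 trials).

What the generator does *not* emulate: volume conduction and channel
covariance structure, eye/muscle artifacts, optode-distance-dependent
sensitivity, session nonstationarity, and realistic patient heterogeneity.
Passing tests therefore demonstrate that the algorithms recover planted
structure under the stated statistical assumptions, not performance on
recorded clinical data.

## Study scales

Two named scales are used.  The *table* scale matches the reference
architecture inputs (30-channel EEG at 200 Hz → 30×2000 trials; 36-channel
fNIRS → 36×100).  The *compact* scale keeps the full paradigm (60 trials,
same timing) but uses 8 EEG channels at 50 Hz (→ 8×500), 12 fNIRS channels,
and F1 = 4, D = 2 networks; all training-based tests and the acceptance
studies run at this scale, which the package treats as its standard
reduced-size benchmark (a complete 6-subject cross-subject experiment runs
in a few minutes on one CPU).  Architecture checks always run at the table
scale, where they are purely analytic.

## Numerical choices

* Covariance ridge r = 1e-3 and eigenvalue floor 1e-8 stabilize the DCCA
  whitening; k caps at 10.
* The degenerate trusted-score normalization, metric tie-breaks, and the
  all-tied Friedman case are defined explicitly (see above) rather than
  left to library behavior.
* Adaptive pooling bins follow the floor/ceil convention
  `[⌊iL/O⌋, ⌈(i+1)L/O⌉)`.
* All randomness flows through named integer seeds (numpy Generators); no
  global random state is read or written anywhere.

## Known limitations

* The CNN stack is pure numpy on one CPU; it is intended for the compact
  study scale, not for training the full 30×2000 architecture on large
  cohorts.
* Sigmoid activations saturate easily; learning on raw oscillatory signals
  relies on batch normalization and is slower than with rectifying
  activations, which is one reason the compact scale uses reduced epochs.
* Single-source transfer only: multi-source weighting/ensembling and
  Riemannian alignment are out of scope.
* The external-format adapters cover only synthetic containers; readers
  for public MATLAB-format hybrid datasets are intentionally not bundled.
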