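# Methods

## Signal model and features

Band-limited EEG is treated as approximately Gaussian, so the differential
entropy of a window with sample variance σ̂² is taken in closed form,
DE = ½·log₂(2πeσ̂²) bits, with the unbiased (n−1) variance estimator and
log base 2 throughout. DE is a monotone function of log band power; its value
for unit-variance noise is ½·log₂(2πe) ≈ 2.047 bits, and doubling the
amplitude adds exactly one bit. Windows with variance below 1e−12 are rejected
as degenerate (the entropy diverges), with channel/band/sub-window context in
the error.

Each subject's recording is cut to a fixed analysis duration, band-decomposed
with 4th-order Butterworth filters applied forward–backward (zero phase, so
no band-dependent group delay desynchronises channels; filtering precedes
windowing so window edges are interior samples), and segmented into T = 10 s
windows. Two windowing modes exist: `tenfold` keeps exactly the first 10
windows at 1-s steps (90% overlap), the augmentation factor appropriate for
small cohorts and the mode all counts in this package assume (65 subjects →
650 windows); `dense` keeps every window that fits (a 5-min recording yields
291). The two conventions are mutually exclusive descriptions of "90% overlap
augmentation"; we default to tenfold because it preserves the 10× sample
arithmetic, and expose dense for power users.

A T-second window is summarised per channel and band by M = 32 overlapping
sub-windows of w = 1 s, starting at m·(T−w)/(M−1) for m = 0…31 (DE per
sub-window). How a single segment should yield a length-M node feature vector
is genuinely open; evenly spaced DE sub-windows keep the feature vocabulary
purely DE-based and give each channel a feature *vector* over which Pearson
correlation — hence the functional graph — is well defined. Feature
normalisation is a z-score per (channel, feature, band) coordinate fitted on
the training rows only (std floored at 1e−8 so constant coordinates map to 0).

## Graphs

The functional adjacency is the absolute Pearson correlation between channels'
DE feature vectors, computed independently for every window and band. The
absolute value is needed because symmetric degree normalisation requires
non-negative weights; it preserves coupling magnitude, the usual convention in
EEG graph learning. No thresholding or sparsification is applied. The
structural adjacency is the binary same-region relation of the 10-20 montage
(Frontal: Fp1 Fp2 F7 F3 Fz F4 F8; Central: C3 Cz C4; Parietal: P3 Pz P4;
Temporal: T3 T4 T5 T6; Occipital: O1 O2) — 87 unit entries, 68 off-diagonal.
Fp1/Fp2 are treated as frontal for graph construction; "prefrontal" appears
only as a display label in some importance tables. Both graphs are normalised
as D̂^{−1/2}(A+I)D̂^{−1/2} (self-loops added — the standard renormalisation
trick, which also floors isolated-node degrees), giving spectral radius ≤ 1.

## Network and training

Per band: two GCN layers, M→K=16 with the functional graph, then K→L=2 with
the structural graph, ReLU activations, separate weights per band (the
per-band indexing of the propagation rule), no GCN biases (none appear in the
propagation rule). The five N·L blocks are concatenated band-major and fed to
a 190→128→32→2 perceptron with biases and a softmax head. Default dimensions
give 31,362 parameters; `count_parameters` reports the count for any
configuration rather than asserting a canonical value, since no standard
bias/weight-sharing scheme reproduces commonly quoted round numbers exactly.

Training is minibatch Adam (default betas) on softmax cross-entropy,
lr = 0.001, batch 10, 200 epochs. The network is implemented directly in
numpy with hand-written backpropagation (verified against central finite
differences to 2e−5 and against per-node loop oracles to 1e−8); given a seed,
initialisation, batch order and therefore the entire trajectory are exactly
reproducible. Dropout/weight decay are available as future config hooks but
default off. AD is the positive class (index 1) everywhere; confusion counts
use a 0.5 threshold on the AD probability.

## Evaluation protocol

Splits are stratified random partitions of *subjects* (all 10 windows of a
subject on one side); with 36+29 subjects and test fraction 0.2 this yields
520/130 windows. k-fold CV partitions subjects into folds differing by at
most one in size, optionally stratified by class so every fold can score AUC.
Band evaluation retrains the model on band subsets (flatten size shrinks to
N·L·|subset|); electrode ablation retrains from scratch with each channel's
feature rows and graph rows/columns removed (N→18), ranking channels by AUC
drop against the full model on the same split. AUC uses the Mann–Whitney
midrank statistic (equal to trapezoidal ROC area).

The comparison toolkit pairs two classifiers: Wilcoxon signed-rank on
per-fold scores (the CV fold is the paired unit — a documented choice, the
pairing unit being otherwise unspecified in this literature; any paired
vectors are accepted), the DeLong test for correlated AUCs (structural
components with midrank ties; cross-checked against a 10,000-resample
stratified bootstrap), Cohen's d as mean difference over pooled sd, and
Benjamini–Hochberg adjustment applied by the caller across the whole
comparison family.

## Synthetic cohorts

Each subject's signal is a sum over the five bands of bandpass-filtered white
Gaussian noise. Channel c's band component is √w·s + √(1−w)·p with s a shared
and p a private unit-variance source, so the raw inter-channel correlation
equals the mixing weight w (`connectivity_strength`). Per-band variance is
base 100 µV² times a class multiplier times a per-subject log-normal jitter
(sd 0.35 in log₂ units, standing in for inter-subject heterogeneity; without
it, any contrast would be trivially separable). Default class profile —
AD: δ 1.5, θ 1.5, α 0.45, β 0.85, γ 0.85 relative to HC; coupling 0.35 (AD)
vs 0.60 (HC) — encodes the qualitative AD pattern: low-frequency power up,
alpha power and functional coupling down. No quantitative effect sizes are
available for these contrasts, so the multipliers are the package's choice of
a clearly detectable but not degenerate regime. Cohorts are pure functions of
(seed, label, subject index) via `SeedSequence` spawn keys.

What the generator does **not** emulate: 1/f spectral slope, nonstationarity,
ocular/muscle artifacts, volume-conduction geometry, or realistic spatial
covariance beyond the single shared source per band. Passing recovery tests
therefore demonstrate that the pipeline detects the *kind* of statistical
structure these contrasts produce — not clinical-grade performance on real
recordings.

The planted-channel recovery experiment (used by the ablation tests) disables
all class-level band/coupling contrasts and suppresses θ/α/β variance at Pz
only (×0.15/0.1/0.15) for AD, with subject jitter 0.2. The effect is made
deliberately strong: the experiment tests whether leave-one-electrode-out
*localises* a known source of signal, not whether a marginal effect is
detectable.

## Desk-scale sizes

Tests and the acceptance script keep the full 36+29 subject counts but use
20-s recordings at 128 Hz — exactly enough signal for the ten tenfold windows
— and 60-epoch training runs (loss plateaus well before that on these
cohorts). These sizes are the package's chosen desk-scale study conditions;
all counts (650/520/130) and recovery behaviours match the full-size design.

## Known limitations

- The Gaussian closed form under-estimates DE sensitivity to non-Gaussian
  signals; alternative entropy estimators are out of scope.
- EDF export needs an mne export backend; cohorts persist as FIF +
  `participants.tsv` (EDF/EEGLAB *reading* is supported).
- The functional graph densely couples channels, which smooths
  channel-localised effects; weak single-channel contrasts may need stronger
  planting or sparser graphs to localise.
- Training determinism is guaranteed for the numpy implementation on a fixed
  platform; exact bit-reproducibility across BLAS builds is not promised.
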