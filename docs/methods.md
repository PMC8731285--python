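# Methods

This note records the model, the conventions and the design choices the
implementation commits to, in the places where the published description
of the method leaves latitude.

## Windowing and splits

Windows are N = round(window_ms · fs / 1000) samples; the default
200 ms / 10 ms hop follows the usual real-time myoelectric-control
budget (≤ 300 ms decision latency, hence windows capped at 200 ms with a
configurable warning). A window is emitted only if all of its samples
share one movement label **and** one repetition index; windows spanning
a boundary are discarded rather than majority-labeled, which guarantees
clean labels and is the standard treatment for repetition-structured
sEMG protocols. Rest (label 0) windows are excluded by default.
Downsampling is plain decimation (every k-th sample) so the label and
repetition tracks stay exactly aligned; an anti-aliased mode
(`antialias=True`, order-8 Chebyshev via `scipy.signal.decimate`) is
available but off by default because filtering is not part of the
protocol being reproduced.

Intra-subject splits are repetition-wise: {1,3,4,6,7,8,9} / {2,5,10}
for 10-repetition protocols and {1,3,4,6} / {2,5} for 6. Repetition
indices are 1-based. Any other repetition count requires explicit
lists; a leakage audit (`evaluation.audit_no_leakage`) asserts that no
repetition feeds both sides.

## Wavelet packet conventions

* Filters: Daubechies-1 (Haar) only; level k = ⌊log₂ N⌋.
* Boundary mode: **periodization** (default), which keeps every level at
  ⌈len/2⌉ samples — for odd-length nodes the last sample is repeated
  before pairing. This is what makes the non-dyadic 20-sample window
  (200 ms at 100 Hz) decomposable to level 4 with D = 16 × 2 = 32, and
  it preserves orthonormality exactly for dyadic lengths (energy
  conservation and perfect reconstruction are tested against a
  brute-force orthogonal-matrix oracle).
* Analysis convention: a_i = (x_{2i} + x_{2i+1})/√2,
  d_i = (x_{2i} − x_{2i+1})/√2 (the PyWavelets convention; the test
  oracle is built to the same convention).
* Leaf order: **natural** (binary-tree, approximation before detail,
  i.e. paths `aaa, aad, ada, …`); Gray-code frequency order is available
  as an option. The choice only permutes image rows and is absorbed by
  the learned network, but it is fixed for reproducibility.
* The transform is backed by `pywt.WaveletPacket`; a vectorized batch
  implementation (`estimators.batch_haar_packet`) is used on window
  stacks and is tested for exact agreement with the tree path.
* Sub-band statistics utility: population std, biased g1 skewness, raw
  (non-excess) kurtosis (Gaussian → 3) unless `excess_kurtosis=True`;
  leaves shorter than 2 samples report 0 with a warning.

## Channel reorganization

The D × C image is widened to D × M by a pure column gather. The
ordering is the concatenation of the C/2 edge-disjoint zigzag
Hamiltonian paths of K_C (offsets 0, +1, −1, +2, −2, … from each of C/2
rotated starting points), which provably covers every unordered channel
pair as adjacent columns and yields M = C²/2 — reproducing both
published widths (50 at C = 10, 72 at C = 12). The published source of
this augmentation does not print its exact column sequence, so any
ordering satisfying the adjacency contract is admissible; a
user-supplied ordering file overrides the built-in one (coverage gaps
warn rather than error). Only the coefficient images are augmented; raw
windows feed the feature-learning stream untouched. Odd C is rejected
rather than guessed at.

## Network architecture

* Feature-learning stream (raw N × C × 1 input): conv3×3 → conv3×3 →
  LC1×1 → LC1×1 → FC; domain-knowledge stream (D × M × 1 input):
  conv1×1 → conv2×2 → LC1×1 → LC1×1 → FC. "LC" layers are locally
  connected: per-position 1×1 weights, no spatial sharing. The
  description of the first stream's LC layers as having "11 filters" in
  the source text is read as 1×1 (an 11×11 filter cannot fit a 20 × 10
  input, and the companion stream's LC layers are explicitly 1×1).
* Padding: `same` (zero) for 3×3 and 1×1 convolutions, `valid` for the
  2×2 convolution (output (D−1) × (M−1)); configurable.
* Batch norm + ReLU after every weighted layer; dropout at exactly five
  sites: after each stream's 2nd LC layer and FC layer, and after H₁'s
  first FC. H₂ contains no dropout.
* Fusion subnetworks (reference widths): H₁ = FC-512 → dropout →
  FC-512 → FC-classes/softmax; H₂ = FC-512 → FC-classes/softmax — the
  second-last FC of both subnetworks is 512. The published figure is
  only partially specified in text; this is the smallest layout
  satisfying every stated constraint, and all widths are
  config-overridable.
* The decision-fusion ablation appends a 2nd FC (512) plus softmax head
  to each stream and sums the two score vectors.
* Loss: sum of the cross-entropies of the individual softmax heads
  (default). Each head must emit calibrated scores for the final score
  summation to be meaningful; a `loss_mode="final"` switch trains on
  the averaged final scores instead.
* Batch norm: momentum 0.9, eps 1e-5, running-statistics inference.
  Weight init: He-normal (fan-in), suited to ReLU. All randomness
  (init, dropout, shuffling) flows through one seeded numpy Generator,
  so runs are bit-reproducible.
* Input standardization is off in the reference profile (the source is
  silent); the estimator's `standardize=True` flag (default in this
  package) standardizes both streams per feature with training-set
  statistics, which materially stabilizes SGD at desk scale.

The engine is a compact numpy implementation with manual
backpropagation (`pfnet.nn`); gradients are verified against central
finite differences in the test suite.

## Training recipe

Reference profile: plain SGD (no momentum, no weight decay — none is
specified for the method), batch 1000, 28 epochs, lr 0.1 divided by 10
at the 1-based 16th and 24th epochs (so 0.1 → 0.01 → 0.001). Phase 1
pre-trains one model on the pooled training-repetition windows of all
subjects at dropout 0.5 ("all available training data" is read as
cross-subject pooling; a per-subject-only mode is trivially obtained by
passing one subject). Phase 2 fine-tunes an independent copy per
subject at dropout 0.65; folds are isolated, so subject order is
irrelevant. Fine-tuning with 0 epochs returns the pre-trained
parameters unchanged. A class absent from a subject's windows stays in
the output head (warning).

## Desk-scale profile and problem sizes

The reference experiments need GPU-scale training on external
recordings, so tests and examples use a scaled-down profile with the
identical topology and recipe shape: 16 feature maps, FC widths
128/128/64, batch 64, 10 epochs (lr drops at 6 and 9), 6 fine-tune
epochs. The recovery study runs on the generator's default layout —
2 subjects × 5 movements × 6 repetitions × 8 channels at 100 Hz, 3 s
movements, 1 s rests, 200 ms windows with 100 ms hop → 870 windows per
subject (580 train / 290 test under the {1,3,4,6}/{2,5} split). Under
this profile the full fusion model recovers well-separated class
structure essentially perfectly and collapses to chance (1/5) when the
generator's separability parameters are zero; both are asserted by the
test suite, and the run fits in minutes on one CPU core.

## Synthetic generator

Movement-epoch sEMG is emulated as amplitude-modulated AR(2)-filtered
Gaussian noise:

* amplitudes a[m, c] = exp(σ_a · z[m, c]), z ~ N(0,1) drawn once per
  dataset (log-normal around 1; σ_a = `amplitude_separability`, 0 →
  unit amplitudes everywhere);
* per-class AR(2) poles at radius 0.9 and angle
  π/2 + σ_s · ((m−1)/(M−1) − ½) · 0.8π (σ_s =
  `spectral_separability`), giving each class an analytically known
  resonance that the wavelet sub-band energies pick up — the theoretical
  spectrum is exposed (`class_power_spectrum`) and checked against
  Welch periodograms;
* repetitions separated by rest gaps (label 0, repetition 0) of white
  noise at `noise_floor` (default 0.05), which is also added over
  movements.

Class parameters are shared across subjects (so pooled pre-training is
coherent); each subject gets an independent noise stream. At zero
separability on both axes, classes are exchangeable by construction.
The generator does **not** model motor-unit action potentials,
electrode shift, fatigue, force variation or amputee signal
degradation — passing the recovery tests shows the pipeline extracts
amplitude and spectral class structure, not that it attains any
particular accuracy on physiological recordings.

## Numerical and degenerate-input conventions

* Argmax ties in prediction resolve to the lowest class index.
* The across-subject spread is the population standard deviation
  (`ddof=0`); a sample-std switch exists.
* Softmax is computed with max-shift; cross-entropy guards with 1e-12.
* A window longer than its recording yields an empty window set with a
  warning; an empty test set is an error.
* Standardization divisors are guarded with +1e-8.

## Known limitations

* Only the Haar family is implemented; other wavelets would change leaf
  lengths and are out of scope.
* The numpy engine is single-threaded BLAS-bound; the reference profile
  (64 maps, batch 1000, 28 epochs) is supported but meant for patient
  offline runs, not interactive use.
* No majority voting across consecutive windows, no confusion-matrix
  tooling, no significance testing between variants — per-window
  accuracy aggregated across subjects is the single reported metric.
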