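# Methods

## Problem and pipeline

The package classifies cardiovascular anatomy — hypoplastic left heart
syndrome (HLHS) in Fontan circulation versus normal anatomy — from the
spatial arrangement of seven anatomical landmarks in an axial cine MRI
stack: (1) origin of the left common carotid artery, (2) aortic isthmus,
(3) tricuspid valve, (4) aortic / neo-aortic valve, (5) mitral valve,
(6) right ventricular apex, (7) descending aorta at diaphragm level.

The pipeline has two decoupled stages.  A multi-head 3D convolutional
network detects the landmarks by heatmap regression; a linear support
vector machine (SVM) then classifies the landmark *positions alone*,
expressed as a centred point cloud in millimetres.  Decoupling keeps the
classification interpretable: the decision depends only on clinically
meaningful coordinates, never on image texture or scanner parameters.

## Preprocessing

Acquired stacks vary in slice count (17–54) and in-plane matrix
(132×192 – 192×256).  Every stack is canonicalised to 33×256×256:

- slices beyond 33 (below the diaphragm) are discarded; stacks with
  fewer slices are padded with zero-valued slices at the bottom;
- each slice is resampled bilinearly to 256×256, anisotropically when
  the acquisition matrix is non-square, and the two in-plane spacings
  are rescaled independently so mm positions are preserved exactly
  (voxel-centre convention, origin adjusted by half the spacing change).

Coordinates are 0-based voxel indices ordered (z = slice, y = row,
x = column); positions refer to voxel centres, `mm = origin + index *
spacing`.  Annotations with a landmark beyond slice 33 are rejected
rather than silently cropped.

## Heatmap regression

Each landmark j has its own target volume

    t(v) = k · exp( − Σ_d (v_d − p_d)² / (2 σ_d²) )

with peak temperature k = 10³ at the landmark voxel p.  σ_d is one
voxel extent per axis, which makes the exponent dimensionless in index
units and automatically adapts the peak width to the anisotropic grid
(thick slices, finer in-plane resolution).  The large k keeps the
regression signal well above the all-zero background early in training.
Targets are built directly on the head output grid (33×64×64 by
default): in-plane annotation indices are divided by the output
downsampling factor and rounded to the nearest voxel.

The predicted landmark is the argmax voxel of the predicted heatmap.
When the maximum is attained at several voxels, the candidate with the
largest score S — the heatmap summed over the 7×7×7 neighbourhood,
clipped at the volume boundary (equivalent to zero padding for
non-negative heatmaps) — wins; any residual tie falls to the
lexicographically smallest index.  Note a degenerate consequence: on a
constant heatmap S itself discriminates (boundary windows hold fewer
voxels), so the winner is the most-interior, lexicographically smallest
voxel.  Coarse-grid predictions map back to the fine grid by the
block-centre convention (fine = factor·coarse + (factor−1)/2 in-plane)
and then to mm through the voxel geometry.

## Network

The detector is a U-Net-like encoder–decoder with a shared backbone and
seven segmentation heads, implemented in NumPy (channels-last tensors;
forward and hand-derived backward passes phrased as 27 GEMMs per
convolution, finite-difference-checked in the test suite).

- Resolution levels d = 0 … max_depth−1; in-plane resolution halves per
  level (z is never resampled); filters grow additively,
  f_d = first_layer_filters + 4d (default 6 → 6,10,…,30 at 7 levels).
- Downsampling is a strided 3×3×3 convolution (stride 1×2×2), upsampling
  the corresponding transpose convolution (implemented as the exact
  adjoint of the strided convolution); one non-strided convolution sits
  between consecutive resampling steps; skip connexions concatenate
  equal-resolution encoder features into the decoder.
- Decoder steps landing at depths ≤ head_split_depth (default 3, search
  range 2–6) are replicated per head; deeper steps are shared.
- Each head upsamples to full resolution, max-pools in-plane by 4 and
  finishes with a linear 3×3×3 convolution to one 33×64×64 volume.
- ReLU activations, He initialisation, zero ('same') padding throughout;
  3×3×3 kernels everywhere (kernel size is an open choice; 3³ is the
  standard U-Net pick).
- The input volume is standardised (zero mean, unit variance) at the
  network entry.  Scanner intensity scaling is arbitrary, and the
  standardisation makes the initial output scale — and hence the early
  optimisation trajectory — independent of it.  This matters at desk
  scale, where few optimisation steps are available (below).
- Decoder level order: upsample → concatenate skip → convolution; the
  head's max-pool precedes the final linear convolution.  These
  orderings are documented choices where the design was open.

Training: Adam, learning rate 5×10⁻⁴, batch size 2, 32 epochs, loss =
unweighted mean of the per-head MSE over heatmap voxels.  Batches
accumulate gradients sample by sample, so memory stays bounded; a fixed
seed makes initialisation, shuffling and hence the loss history exactly
reproducible on one machine.

Image augmentation (disabled by default — the final reference protocol
used none) applies one in-plane shift/rotation/scale similarity per
stack (limits 0.02 of image size, 4°, 0.15) to every slice and to the
annotation, plus intensity-only Gaussian blur (kernel limit 4 px) and a
mild radial distortion (limit 3, scaled by 0.01 as a relative warp
amplitude).  Pairs whose transformed landmark leaves the field of view
are skipped.  Augmentation doubles the training set (originals are
kept).

## Point-cloud classification

Detected landmark positions l_j (mm) are centred on the cloud mean
m = Σ_j l_j / 7, giving translation-invariant features L_j = l_j − m.
The classifier is a soft-margin linear SVM with library-default
regularisation (C = 1) on the 21 coordinates in landmark-major order
(L1z, L1y, L1x, …, L7x).  No scaling beyond centring is applied — all
coordinates share units (mm).  Linear-SVM fitting is deterministic for
a fixed input order (the solver needs no random initialisation).

Optional point-cloud augmentation adds 400 replicas per training cloud,
each landmark coordinate shifted independently by a uniform draw from
±10 mm; originals are kept, so n clouds become 401 n.  Replicas are not
re-centred: the uniform jitter *is* the stated augmentation law, and
re-centring would both distort it and break the ±10 mm bound.

Per-landmark weight summaries report the signed coefficient of largest
magnitude ("max") and the RMS of the three spatial coefficients per
landmark; the landmark with the largest RMS is flagged.  In phantom
cohorts built with the aortic-valve class shift, that flag lands on
landmark 4 — the qualitative signature a correct implementation must
reproduce.

## Evaluation

- Displacement E = ‖g − l‖ (mm) between predicted and annotated
  positions, summarised per landmark as mean and SD over subjects; when
  fold labels are supplied, statistics are computed per fold and then
  averaged.  Two summaries are reported and labelled: the mean
  *Euclidean* displacement, and the *signed per-component* mean (the
  systematic directional shift) — they answer different questions and
  are both part of the standard report.
- Interobserver variability E_inter: the same statistic between two
  observers' annotations; the ratio E/E_inter expresses network error
  in units of human disagreement.
- Bland–Altman per spatial component: bias = mean difference, limits of
  agreement = bias ± 1.96·SD (the conventional 95% normal multiplier),
  and a proportional-bias slope from least-squares regression of the
  difference on the pairwise mean.
- Accuracy = fraction of correct classifications.
- Stratified k-fold cross-validation (default k = 5, configurable):
  folds partition the cohort, each preserves the class ratio within one
  subject, and every subject validates exactly once.  For a 46 + 33
  cohort this yields validation folds of 15–16 and training folds of
  63–64 subjects.  The fold count is exposed rather than hard-wired
  because the reference protocol is described with five folds in the
  methods but four in two table captions; five is the default here.

In the full cross-validation harness the network is trained per fold on
the training split's annotations, the SVM is fitted on the training
split's ground-truth centred clouds, and validation subjects are scored
on network-detected clouds.

## Phantom generator

Real cohorts are not distributable, so every stage is exercised on
synthetic phantoms.  A phantom subject is a stack containing seven
bright Gaussian blobs (one per landmark; σ = half the 10 mm render
radius) with distinct amplitudes (500–1100) so appearance as well as
position identifies a landmark, a dimmer (300) max-composited tube
threading landmarks 1–2–7 as vessel-like context, and Gaussian
background noise (SD 20).  Landmark positions are drawn per class:
a control template, and a patient template that shifts the
aortic-valve landmark by 40 mm (landmarks 3 and 6 by ~10 mm), with
isotropic 3 mm within-class jitter — 40/3 far exceeds the 5× separation
that guarantees linearly separable centred clouds, mirroring the
reference cohort where annotated landmarks classify perfectly.  Cohort
sizes default to 46 patients + 33 controls.  All randomness flows from
one seed through per-subject spawned sequences, so any subject is
regenerable in isolation.  A simulated second observer adds Gaussian
mm offsets (re-quantised to voxels) to the ground truth.

What the phantom does *not* emulate: real anatomy and its covariation
across structures, bSSFP contrast, cine dynamics, partial-volume and
banding artefacts, or observer biases that correlate across landmarks.
Passing phantom tests therefore demonstrates that the machinery —
preprocessing, targets, network, extraction, centring, classification,
metrics — is correct and learnable end to end, not that the clinical
accuracy figures transfer.

## Desk-scale protocol

The reference training (33×256×256, 79 subjects, 32 epochs, batch 2)
is a GPU-scale computation.  The desk-scale protocol in
`landmarknet.experiments` runs the identical pipeline at reduced size:
33×64×64 phantoms (3 mm in-plane, 6 mm slices), max_depth 5,
head_split_depth 2, final pooling 2 (head grid 33×32×32), 16 training
subjects (8 per class), 12 held-out subjects, 10 epochs.  The
optimisation is rescaled for the short schedule: single-sample batches
maximise the number of Adam steps (160 instead of ~1000), the learning
rate is raised to 2×10⁻² with a 20-step linear warmup and then decays
linearly to 10% of its peak by the final step.  The warmup protects
the decoder ReLUs from the large initial residual — without it, a cold
start at full step size silences several heads' ReLU activations
entirely and those heads never recover within the schedule (observed
directly: zero live-activation fractions in the affected heads'
decoders).  The decay stabilises the late schedule — at a constant
2×10⁻² the single-sample gradient noise can knock an
already-converged head flat again.  Input standardisation makes the
initial output scale independent of phantom intensity so no steps are
wasted shrinking an arbitrary transient.  Success criteria: mean
held-out landmark displacement at or below the 10 mm blob radius, and
end-to-end classification accuracy ≥ 0.9.

Two further stabilisers address head-to-head variance on the short
schedule.  First, hidden-layer biases are initialised to a small
positive value (0.05) so every ReLU unit starts active; on a short
schedule a region of dead units cannot be revived in time.  (He
initialisation is kept for all kernel weights, including each head's
output convolution: experiments with zero-initialised output layers
showed a deadlock — while a head's output layer is near zero its
decoder receives no gradient, and the shared trunk, pulled by the
heads that fit first, can drift that head's features dead, observable
as a head pinned at exactly the all-zero-prediction loss.)  Second,
per-head training losses saturate at very different times, and an
unlucky draw in one head's decoder can leave that single head flat for
the entire schedule; after a mid-training checkpoint (epoch 5 of 10),
any head whose training loss still exceeds 0.9 of its
all-zero-prediction baseline — a statistic of the training data only,
and a level converging heads are well below by then — has its decoder
redrawn, and training continues with the total step count unchanged.
This per-head restart echoes the observation that the heads are
independent consumers of a shared trunk and can be (re)trained
separately.  The aortic-valve head is often the slowest to converge —
its target position is bimodal across classes (that is precisely the
class signal), so its heatmap task is the hardest at this scale.

## Numerical choices and limitations

- float32 arithmetic throughout the network; gradients validated against
  central finite differences at 2% relative tolerance.
- 'Same' padding convention: pad 1 voxel per axis, output size
  ⌊(n−1)/s⌋+1; strided outputs sample input positions 0, s, 2s, ….
- Centred clouds tolerate 10⁻⁹ mm deviation from zero mean.
- Ratio E/E_inter is reported as NaN when E_inter = 0.
- The SVM tie at decision value exactly 0 follows the library's
  assignment and is covered by a determinism test.
- The NumPy network trains at desk scale only; the full-resolution
  configuration is exercised for architecture/shape verification.
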