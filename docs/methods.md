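# Methods

## Scope and data model

The package analyses co-registered whole-body PET-CT studies: a PET
volume in standardised uptake values (SUV), a CT volume in Hounsfield
units (HU), a multi-channel binary organ mask, and — for training and
evaluation — a voxel label map with classes background (0), prostate
tumour/recurrence (1), lymph-node metastasis (2) and bone metastasis (3).
Arrays are indexed (x, y, z); the world position of voxel `i` is
`origin + i · spacing`. No clinical data ship with the package; the
phantom module generates structurally equivalent synthetic studies.

## Phantom model

A phantom is a deterministic function of its seed. Its anatomy is
geometric, not anatomical: a body ellipsoid of soft tissue (≈40 HU, mild
Gaussian detector noise, air outside), a skeleton of three vertical
columns (≈700 HU), a central prostate-bed sphere and a surrounding
pelvic-nodes shell. These four compartments form the organ-mask channels;
they are a minimal set sufficient to condition the classifier on
location, standing in for the richer organ segmentation a clinical
pipeline would supply.

PET background is Gaussian, mean 1.0 SUV, sd 0.25, clipped at zero.
Lesions are spheres with Gaussian-smoothed edges (σ = 1 voxel), a crude
stand-in for partial-volume blur; radii are drawn from 3–6 mm and peak
uptake from 5–15 SUV, well above background — the defaults deliberately
describe an easy, high-contrast detection task so that end-to-end tests
measure the pipeline, not the limits of a small network. Each class is
placed in its compartment (bone lesions entirely inside the skeleton);
placement is rejection sampling with bounded retries, and lesions keep a
one-voxel gap so per-class 26-connected component counts equal the
requested counts exactly. Labelled voxels are floored at
`background + 2 sd` so the documented invariant (lesion uptake strictly
above `background + 1 sd`) holds for every noise draw.

*Unspecific bone foci* — PET-avid spots inside the skeleton labelled
background — reproduce the benign bone-uptake confound of the
[18F]PSMA-1007 tracer, giving the evaluation a realistic false-positive
source.

What the phantom does **not** emulate: anatomical shape, scanner noise
spectra, attenuation/reconstruction physics, lesion shape irregularity,
and the clinical distribution of lesion sizes and uptakes. Passing
end-to-end tests therefore demonstrates that the machinery (sampling,
training, inference, matching, burden) is correct and self-consistent,
not that the trained network would perform at any particular level on
patient data.

Cohorts are split train/validation/test by largest-remainder
apportionment of the proportions 420 : 120 : 120, ties toward the earlier
bucket, so 660 studies give (420, 120, 120) and 30 give (19, 6, 5).

## Simulated readers

An alternative human "reading" is a stochastic perturbation of the truth:
each lesion (per-class 26-connected component) is dropped independently
with probability `p_drop_lesion`; survivors are dilated or eroded by up
to `boundary_jitter_voxels` (erosion backs off rather than deleting a
lesion); spurious lesions are added with Poisson-distributed count (mean
`p_add_spurious`), placed on background of both truth and output so they
act as genuine false positives. The zero perturbation is the identity.

## Preprocessing

CT is clamped to [−800, 800] HU and PET to [0, 25] SUV; "normalised" is
implemented as the affine map of the clamp window onto [0, 1] (the
simplest convention consistent with clamping; volumes carry a
`normalised` flag, which makes the operators idempotent). All grids are
resampled to 1.37 × 1.37 × 2.79 mm: trilinear for PET/CT, nearest
neighbour for organ channels and labels (no new codes can appear).
Output extent is physical extent / target spacing, rounded half-up; the
output grid is anchored at voxel 0. The classifier input is the channel
stack [CT, PET, organ channels…].

## Sampling

Each training study has a per-voxel sample mask, stored normalised to
sum 1. Initialisation: background voxels share total mass 0.5; the other
0.5 is split equally among the foreground classes *present*, uniformly
within a class (a study with no foreground falls back to a uniform mask
so it remains usable). Patch centres are categorical draws from the mask;
patches are extracted about the centre with mirror reflection at volume
boundaries (avoids constant-value padding artefacts). A "foreground
patch" is one whose centre voxel is foreground.

The adaptive update `w′ = 0.5 w + 0.5 (max w / max l) l` is covariant
under uniform rescaling of `w`, so applying it to the normalised stored
weights and re-normalising gives the same sampling distribution as any
raw-weight convention that differs by a global scale (asserted as a
property test). An all-zero loss map leaves the mask unchanged — the
update's `max l` denominator would be undefined, and zero loss means
there is nothing to adapt toward.

## Classifier and training

The voxel classifier is a 3D encoder–decoder with skip connections:
per level, two 3×3×3 same-padded convolutions with ReLU, 2×2×2 max
pooling down and nearest-neighbour upsampling with skip concatenation up,
a 1×1×1 head, softmax over 4 classes. Depth and width are configuration
(defaults: depth 2, 8 base filters, doubling per level); input spatial
sizes must be divisible by 2^depth. Exactly two dropout sites (rate 0.25)
exist regardless of depth — after the bottleneck and after the deepest
decoder block — and the convolution kernels carry an l2 penalty of 10⁻³.
The network, its backprop and the Nadam optimiser (Adam with Nesterov
momentum) are implemented in numpy; the backward pass is verified against
central finite differences in the test suite.

The loss is weighted categorical cross-entropy: per voxel
`−w_c log p(true class)` with `w_c = 2.5` for foreground classes and 1
for background, averaged over voxels. The weighting deliberately favours
sensitivity over precision. Probabilities are clamped at 10⁻⁷ inside the
log.

Training runs `n_rounds` rounds of `epochs_per_round` epochs (defaults
5 × 10, mirroring "10 epochs, repeated 5 times"; the wording is ambiguous
between 10 total and 10 per round, so both are configurable). Each epoch
draws its training patches through the sample masks (studies chosen
uniformly, centres by mask) and its validation patches through validation
masks frozen at initialisation — validation must not adapt to the model.
After every round, the masks of a random `refresh_fraction` (default 0.5)
of training studies are refreshed from the current per-voxel loss,
computed by whole-volume tiled prediction. The learning rate starts at
10⁻³ and halves after 5 consecutive epochs without a strict
validation-loss decrease. Non-finite loss aborts with a history dump.

Augmentation draws one isotropic scale from ±10%, one in-plane (x–y)
rotation from ±0.15 rad, and intensity shifts of ±100 HU (CT) and
±0.5 SUV (PET), each applied as the equivalent shift inside the
normalised window and clipped back to [0, 1]. The PET shift is read in
native SUV, parallel to the CT shift being stated in HU; a ±0.5 shift in
*normalised* units would be ±12.5 SUV — half the clinical uptake window —
and would drown the signal. Geometry uses trilinear interpolation for
continuous channels and nearest neighbour for organ channels and labels;
collapsed ranges make augmentation the exact identity.

## Inference

Whole volumes are predicted with a sliding window (default 32³ tiles,
8-voxel overlap), averaging class probabilities over every window
covering a voxel, then argmax with ties broken toward the lower class
code. Volumes smaller than a tile are mirror-padded to one tile and
cropped back. Dropout is off, so inference is deterministic.

## Lesion-level evaluation

A lesion is a maximal 26-connected component of one class (the most
permissive standard connectivity — fewest artificially split lesions);
matching is class-specific. Any voxel overlap counts: a reference lesion
overlapped by any candidate lesion is *detected*, a candidate overlapping
any reference is a true positive, and the two notions are tracked
separately so a single candidate spanning two references raises
sensitivity without inflating PPV. Sensitivity is detected references
over all references; PPV is TP/(TP+FP). This makes false positives and
false negatives dual: FP(X vs Y) = FN(Y vs X), verified in bulk against a
brute-force flood-fill oracle. Pairwise report tables pool counts over
shared studies; per-patient means divide by all shared patients; summary
rows average each candidate's per-reference pooled values (average of
ratios, the convention that reproduces the relationship between pooled
counts and printed mean sensitivities in published inter-reader tables).
Studies with no reference lesions of a class contribute to FP counts but
add nothing to the sensitivity denominator.

## Tumour burden

TLV is voxel count × voxel volume, in mL. The TLU of a lesion is its
SUVmean multiplied by its volume (the standard total-lesion-uptake
construction, analogous to total lesion glycolysis; adding SUV to a
volume would be dimensionally meaningless), summed per class. Burden is
additive over disjoint lesion sets and bounded by max-SUV × TLV.
Agreement between sources uses Spearman rank correlation (average ranks
on ties, two-sided p); vectors shorter than 3 are rejected and
zero-variance vectors yield NaN with a warning.

## Problem sizes used in the tests

The test suite and the worked examples run at desk scale, chosen as the
smallest sizes at which every mechanism is exercised meaningfully:
phantoms of 32³–48³ voxels at the standard spacing, cohorts of up to 30
studies, 16³ patches, and an end-to-end run of 2 rounds × 3 epochs ×
200 patches. The end-to-end configuration uses batch size 2: the batch
size is a free parameter, and a small batch keeps the number of optimiser
steps (600) meaningful where the full regime would take ~2500 steps per
epoch — with batch 8 the scaled run would make only 150 updates, too few
for the optimiser to leave the all-background regime regardless of
implementation quality. Bulk oracle comparisons (matching, mask update)
use 6³–8³ random grids, 100–1000 cases, fixed seeds.

## Known limitations

* The network is a compact numpy implementation intended for CPU-scale
  experiments; it is faithful in structure (encoder–decoder, skips, two
  dropout sites, l2, Nadam) but not tuned for clinical-scale training.
* The phantom's geometric anatomy cannot probe organ-mask quality or
  anatomical priors; organ masks are inputs, not something the package
  segments.
* Sampling bias introduced by the adaptive masks is not compensated by
  importance weighting in the loss (by design — the sampling *is* the
  curriculum).
* SUV computation from raw activity, DICOM ingestion, registration and
  scanner physics are out of scope; inputs are assumed co-registered and
  already in SUV/HU.
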