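# Methods

## The segmentation problem

The putamen is a paired deep-gray-matter nucleus whose volume is markedly
reduced in multiple system atrophy (MSA) but essentially preserved in
Parkinson's disease (PD) and healthy controls (HC).  Segmenting it
precisely on T1-weighted MRI is what makes putaminal volumetry usable as a
diagnostic marker (MSA vs PD/HC), and it is hard exactly where it matters:
in atrophic cases.  `patchwork3d` implements a hierarchical coarse-to-fine
patchwork of 3D U-Nets for this task, together with the evaluation
machinery (Dice, 95 % Hausdorff distance, volumetry, Bland–Altman,
ROC/AUC with DeLong comparisons) and a synthetic phantom generator that
stands in for patient data.

## The patchwork model

A single high-resolution 3D network over a whole head volume is memory-
and compute-prohibitive, while naive patching loses global context.  The
patchwork resolves the dilemma with a pyramid of patches of fixed matrix
size (32³ voxels) but decreasing physical size: level 0 spans a 150 mm
field of view per axis (4.6875 mm voxels), the finest level spans 32 mm at
1 mm isotropic resolution.  The number of levels between the two printed
endpoints is a free parameter (default 3); intermediate sizes follow a
geometric progression, giving the ladder 150 → 69.28 → 32 mm.

Each level owns a U-Net (max-pooling encoder, transposed-convolution
decoder, instance normalization + ReLU, softmax over three classes:
background / left putamen / right putamen).  Level 0 sees only its image
patch.  Every finer level additionally receives its parent's two
foreground-class probability maps, resampled trilinearly onto the child's
grid, as extra input channels — the mechanism by which a 32 mm patch knows
where it sits in the head.  The reference configuration uses feature
dimensions (8, 16, 16, 32, 64); the desk preset (4, 8, 16, 32) with
pointwise decoder convolutions is sized so a full training run fits in
minutes on one CPU core.  Whether conditioning uses probabilities or
logits, and foreground-only or all classes, is exposed as configuration
(defaults: probabilities, foreground only).

The segmentation head's bias is initialized to a confident-background
prior (+2 background, −2 per foreground class).  Foreground voxels are
rare (at the coarsest level ≈ 0.3 % of a patch), and starting at the class
prior removes the long initial phase in which the network only learns to
predict "background everywhere".

The network engine (3D convolutions, pooling, transposed convolutions,
instance norm, Adam) is implemented in numpy with hand-written backward
passes, the convolutions as direct single-core kernels; every backward
pass is gradient-checked against numerical differentiation in the test
suite, and the fast kernels are checked against an independent GEMM
lowering.

## Training

Patches are sampled as nested chains anchored at the finest level.
`label_bias` (default 0.8) is the *target fraction* of finest patches
containing at least one label voxel: a finest patch is anchored on a
random foreground voxel (with uniform jitter that keeps the anchor inside
the patch) with a per-subject probability `(b − q)/(1 − q)`, where `q` is
that subject's probability that a uniformly placed patch hits foreground
by chance; the realized label-containing fraction then equals `b`.  With
`label_bias = 0` the sampler is exactly uniform.  Parent patches are drawn
bottom-up, uniformly over the positions that keep the chain nested.

The loss is a binary cross-entropy variant of the top-K loss: per-voxel
BCE summed over the three softmax channels, averaged over the hardest
`topk_fraction` (default 0.1) voxels of each patch.  Selection is per
patch (hard-voxel mining); the first 10 % of each level's steps run at
full fraction as a warm-up.  Probabilities are clamped at 1e−7.  The exact
granularity of K (count vs fraction, per patch vs per batch) is a
documented design choice; per-patch fraction is the standard reading.

Levels are trained sequentially, coarse to fine, each with its own Adam
optimizer at learning rate 0.001; finer levels are conditioned on the
already-trained parents' predictions, matching the inference-time
distribution.  The total patch budget (reference 5,000,000; desk default
20,000 — counted across levels, one chain contributing one patch per
level) is split across levels as 2 : 1 : 1.  Level 0 receives the double
share because its task — deciding left vs right from the midline landmark
at coarse resolution under extreme class imbalance — is the slowest to
emerge; the finer levels inherit laterality through conditioning and
converge quickly.  One subject per diagnosis class is held out of the
sampling pool as a validation case, monitored with patch-level Dice on
fixed foreground-anchored chains during the finest phase; the
best-validation parameters are restored at the end.

## Inference

Branching mode follows the tree-like scheme: per pass, six coarsest-level
patches are drawn at random, scored by mean predicted foreground
probability, and the best three are kept; each kept patch spawns six
nested children at the next level, of which three are kept per parent
(3^k kept patches at level k; "keep 3 globally" is available as a config
switch), down to the finest level.  Ranking gates only the recursion: at
the finest level there is nothing below, so *every* evaluated finest
patch is stitched into the volume — stitching only the highest-scoring
leaves would bias the averaged probabilities toward foreground.  One pass
over three levels costs exactly 6 + 3·6 + 9·6 = 78 network evaluations.  Passes are independent restarts
(default 64, chosen so phantom Dice plateaus at the exhaustive-mode
value); stitched probabilities are unweighted per-voxel averages over all
covering patches, and unvisited voxels are background.  Exhaustive mode —
a regular grid of nested chains at 16 mm stride covering every voxel — is
the oracle that branching mode is tested against.

Binarization: a voxel is foreground when its maximum foreground-class
probability reaches 0.5, taking the argmax class; a largest-connected-
component filter per class (6-connectivity) is on by default.  Both are
explicit configuration.

## The phantom generator

Phantoms emulate the study conditions, not MRI physics.  A 160³ grid at
1 mm isotropic spacing contains a head-like envelope, an
interhemispheric-fissure-like dark CSF plane at the midline, two bilateral
ellipsoidal putamina (semi-axes 7.5 × 11 × 16 mm, mirror-symmetric at
±26 mm from the midline), and per side a caudate-like and a pallidum-like
distractor ellipsoid with their own intensities, all piecewise-constant
plus additive Gaussian noise (sd 0.1 on a brain intensity of 1.0), then
z-scored over the volume.  The midline plane matters: left and right
putamen are otherwise locally mirror-identical, and without a midline
landmark no translation-equivariant network could assign sides.  The
distractors (pallidum brighter than putamen, caudate slightly darker)
make pure intensity thresholding insufficient.

Atrophy is realized by scaling the putamen semi-axes by the cube root of
a volume factor, optionally preceded by removal of a dorsolateral planar
cap in normalized ellipsoid coordinates (applied to MSA subjects by
default) — a crude nod to the dorsolaterally accentuated degeneration in
MSA, with no claim of anatomical fidelity.  Cohorts draw each subject's
two-side total volume from the group distributions HC 4.61 ± 0.54 mL,
MSA 2.62 ± 1.03 mL, PD 4.34 ± 0.53 mL (normals truncated below at
0.5 mL, since the MSA distribution has non-negligible mass near zero),
then calibrate the atrophy factor by bisection so the voxelized mask hits
the drawn target (well inside the 3 % discretization tolerance).  The
configured volumes are treated as two-side totals, split equally between
sides.

What the phantoms do *not* model: bias fields, acquisition physics,
cortical anatomy, inter-subject shape variability beyond uniform scaling,
and asymmetry.  Passing the end-to-end tests therefore shows that the
pipeline — sampling, hierarchy, conditioning, loss, stitching, metrics —
works as specified at desk scale; it does not certify performance on
patient MRI.

## Evaluation and diagnostics

- **Dice**: 2|A∩B|/(|A|+|B|); both masks empty → 1.0, exactly one empty →
  0.0.  Reported per side and for the combined foreground.
- **HD95**: 95th percentile (linear interpolation) of the pooled
  bidirectional surface-to-surface nearest distances, surfaces being
  6-connected border voxels, distances between voxel centers in mm.
  Undefined (reported as missing, never 0) when a mask is empty.  The
  pooled-symmetric convention is the dominant one in segmentation
  benchmarks; per-direction variants are available.
- **Volumetry**: voxel count × voxel volume, reported in mL.
- **Bland–Altman**: mean difference and mean ± 1.96 SD limits of
  agreement over paired volumes.
- **ROC/AUC**: lower volume indicates MSA; the score is fixed as −volume
  so the orientation cannot silently invert.  The AUC is the
  Mann–Whitney pair statistic.  The 95 % CI uses the DeLong variance with
  a normal approximation.  The Youden cut point maximizes
  sensitivity + specificity − 1, realized as the midpoint between the two
  adjacent sorted volumes straddling the optimum, ties broken toward
  higher specificity.
- **DeLong's paired test** compares correlated AUCs via placement-value
  covariances; degenerate variance with equal AUCs returns z = 0, p = 1.
- **Binormal closed form** Φ((μ₋ − μ₊)/√(σ₊² + σ₋²)) serves as the
  analytic oracle for the simulation: with the printed group
  distributions it gives ≈ 0.931 for MSA vs PD.

## Numerical choices and degenerate inputs

Sample positions follow the cell-center rule (index p samples
lo + (p + ½)·spacing), 0-based, half-open boxes; grid-aligned extraction
is a verbatim sub-block copy.  Out-of-volume samples are filled with 0
(images are z-scored, so 0 is the global mean).  Candidate ranking breaks
ties by draw order.  Stitching touches only voxels strictly inside a
patch's sample lattice so trilinear weights sum to one and stitched class
probabilities stay normalized.  Volumes smaller than the coarsest patch
are handled by out-of-bounds fill.  Rotated input affines are resampled
to an axis-aligned grid at load time with a logged warning.

## Problem sizes

Desk-scale runs use a 20,000-patch budget (batch 16), ten training
phantoms plus one held-out phantom per class, exhaustive inference at
16 mm stride, 10,000 sampler draws for the bias estimate, and ≥ 200
replicates for the AUC simulation.  The reference-scale settings
(5,000,000 patches, batch 150, feature dimensions (8, 16, 16, 32, 64))
remain available in configuration.

## Known limitations

The phantom's geometric regularity makes the segmentation task easier
than patient MRI; desk-scale accuracies are not comparable to the
reference-scale results on real data.  The single-level 32³ baseline is
resolution-limited by construction (its oracle ceiling on the default
phantom is Dice ≈ 0.89), which is precisely the hierarchy's argument.
Anisotropic patch grids (the 128³ / 2×2×1.5 mm single-level variant) are
approximated by a cubic field of view.  DeLong CIs use the normal
approximation without finite-sample corrections.
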