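# patchwork3d

Hierarchical coarse-to-fine patchwork segmentation of the putamen, with
synthetic atrophic-putamen phantoms, segmentation metrics and volumetric
diagnostics.

## The problem

The putamen — a paired deep-gray-matter nucleus — atrophies markedly in
multiple system atrophy (MSA) but not in Parkinson's disease (PD) or
healthy controls (HC), which makes putaminal volumetry a candidate marker
for the difficult MSA-vs-PD differential.  Atlas- and surface-based
segmentation tools underperform exactly in the atrophic cases where the
measurement matters.  This package implements a Deep Neural Patchwork
(DNP): a stack of small patch-based 3D U-Nets of fixed matrix size
(32³ voxels) but decreasing physical size, from a 150 mm field of view
(4.6875 mm voxels) down to a 32 mm, 1 mm-isotropic patch, each finer level
conditioned on its parent's output.  The hierarchy supplies global context
to high-resolution patches without ever holding a full high-resolution
volume in the network.

Because patient MRI cannot ship with the code, the package also generates
phantom cohorts whose ground-truth putaminal volumes follow the reported
group distributions (HC 4.61 ± 0.54 mL, MSA 2.62 ± 1.03 mL,
PD 4.34 ± 0.53 mL, two-side totals), and reproduces the evaluation
pipeline: Dice, 95 % Hausdorff distance, volumetry, Bland–Altman
agreement, and ROC/AUC of volume for MSA vs pooled PD + HC with DeLong
confidence intervals, paired AUC comparison and Youden cut points.

## Worked example

```python
import numpy as np
from patchwork3d import (
    CohortConfig, PhantomConfig, PatchworkSegmenter, sample_cohort, dice,
)

train = sample_cohort(CohortConfig(group_sizes={"HC": 3, "MSA": 4, "PD": 3}),
                      PhantomConfig(), rng=11)
test = sample_cohort(CohortConfig(group_sizes={"HC": 1, "MSA": 1, "PD": 1}),
                     PhantomConfig(), rng=22)

seg = PatchworkSegmenter(random_state=0)   # 3 levels, desk-scale budget
seg.fit(train)

for subject in test:
    pred = seg.predict(subject.image, mode="exhaustive")
    d = dice(pred.data > 0, subject.mask.data > 0)
    print(subject.subject_id, subject.diagnosis, round(d, 3))
```

Output from this exact run (seeds as shown):

```
HC-000 HC 0.955
MSA-000 MSA 0.941
PD-000 PD 0.964
```

Each line is one held-out phantom: the Dice overlap between the
patchwork's exhaustive-mode segmentation and the ground-truth mask.  The
same-budget single-level baseline (`SingleLevelSegmenter`, one 32³ patch
covering 150 mm, i.e. 4.69 mm voxels) is resolution-limited to Dice
≈ 0.89 even with perfect predictions, which is the point of the
hierarchy.

The diagnostic side works from volumes alone:

```python
from patchwork3d import cohort_auc_experiment
res = cohort_auc_experiment(n_replicates=250, seed=42)
print(round(res["mean_auc"], 3))   # 0.933
```

i.e. ground-truth putaminal volume separates MSA from pooled PD + HC with
AUC ≈ 0.93 at the reported test-split group sizes (31 MSA / 74 PD /
15 HC).

A `patchwork3d` command-line tool wraps the same pipeline
(`simulate`, `train`, `predict`, `eval`, `diagnose`); see
`patchwork3d --help`.

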