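"""Shared fixtures.

The expensive end-to-end artifacts (a trained 3-level patchwork and the
same-budget single-level baseline, with their phantom cohorts) are built
once per session and shared by the acceptance, inference and hierarchy
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from patchwork3d.estimators import PatchworkSegmenter, SingleLevelSegmenter
from patchwork3d.phantom import (
    CohortConfig,
    PhantomConfig,
    make_putamen_mask,
    render_volume,
    sample_cohort,
)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-configuration phantom: (config, mask, rendered image)."""
    pc = PhantomConfig()
    mask = make_putamen_mask(pc)
    image = render_volume(pc, mask, np.random.default_rng(1234))
    return pc, mask, image


@pytest.fixture(scope="session")
def phantom_cohorts():
    """Small train (10 subjects) and held-out test (1 per class) cohorts."""
    pc = PhantomConfig()
    train = sample_cohort(CohortConfig(group_sizes={"HC": 3, "MSA": 4, "PD": 3}), pc, 11)
    test = sample_cohort(CohortConfig(group_sizes={"HC": 1, "MSA": 1, "PD": 1}), pc, 22)
    return train, test


@pytest.fixture(scope="session")
def trained_patchwork(phantom_cohorts):
    """Desk-scale 3-level patchwork trained on the 10-subject cohort."""
    train_cohort, _ = phantom_cohorts
    seg = PatchworkSegmenter(random_state=0)
    seg.fit(train_cohort)
    return seg


@pytest.fixture(scope="session")
def trained_baseline(phantom_cohorts):
    """Same-budget coarsest-only (single-level 32^3) baseline."""
    train_cohort, _ = phantom_cohorts
    seg = SingleLevelSegmenter(random_state=0)
    seg.fit(train_cohort)
    return seg
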