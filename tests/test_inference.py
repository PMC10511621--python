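"""Branching inference: candidate ranking, stitching, coverage, oracles."""

import numpy as np
import pytest

from patchwork3d.grid import VolumeGrid
from patchwork3d.inference import (
    InferenceConfig,
    binarize_and_split,
    predict_volume,
    rank_candidates,
    stitch,
)
from patchwork3d.model import DNPConfig, PatchworkModel, UNetConfig
from patchwork3d.metrics import dice
from patchwork3d.pyramid import PatchPyramidConfig, PatchSpec


class TestRankCandidates:
    def test_orders_by_score(self):
        scores = [0.9, 0.1, 0.5, 0.7, 0.2, 0.3]
        kept = rank_candidates(list(range(1, 7)), scores, 3)
        assert kept == [1, 4, 3]

    def test_ties_broken_by_draw_order(self):
        kept = rank_candidates(["a", "b", "c", "d"], [0.5, 0.5, 0.5, 0.5], 3)
        assert kept == ["a", "b", "c"]

    def test_keep_all_is_identity(self):
        kept = rank_candidates([10, 20, 30], [0.1, 0.9, 0.5], 3)
        assert sorted(kept) == [10, 20, 30]

    def test_fewer_candidates_than_keep(self):
        assert rank_candidates([1, 2], [0.2, 0.9], 5) == [2, 1]


class TestStitch:
    def _vol(self, n=32):
        return VolumeGrid(np.zeros((n, n, n), dtype=np.float32))

    def test_single_aligned_patch_direct_placement(self):
        vol = self._vol(32)
        probs = np.zeros((3, 32, 32, 32))
        probs[0] = 0.25
        probs[1] = 0.75
        spec = PatchSpec(0, (15.5, 15.5, 15.5), 32.0)  # exactly the grid
        field, visited = stitch([probs], [spec], vol)
        assert (visited == 1).all()
        assert np.allclose(field[1], 0.75, atol=1e-6)

    def test_overlapping_identical_predictions_idempotent(self):
        vol = self._vol(32)
        probs = np.zeros((3, 32, 32, 32))
        probs[0], probs[1] = 0.4, 0.6
        s1 = PatchSpec(0, (15.5, 15.5, 15.5), 32.0)
        field, visited = stitch([probs, probs], [s1, s1], vol)
        assert visited.max() == 2
        assert np.allclose(field[1][visited == 2], 0.6, atol=1e-6)

    def test_overlap_averages(self):
        vol = self._vol(32)
        a = np.zeros((3, 32, 32, 32))
        a[0], a[1] = 0.8, 0.2
        b = np.zeros((3, 32, 32, 32))
        b[0], b[1] = 0.4, 0.6
        s = PatchSpec(0, (15.5, 15.5, 15.5), 32.0)
        field, visited = stitch([a, b], [s, s], vol)
        assert np.allclose(field[1][visited == 2], 0.4, atol=1e-6)

    def test_probabilities_conserved(self):
        rng = np.random.default_rng(0)
        vol = self._vol(40)
        patches, specs = [], []
        for _ in range(5):
            z = rng.normal(size=(3, 32, 32, 32))
            e = np.exp(z)
            patches.append(e / e.sum(axis=0, keepdims=True))
            specs.append(PatchSpec(0, rng.uniform(10, 30, size=3), 32.0))
        field, visited = stitch(patches, specs, vol)
        sums = field.sum(axis=0)
        assert np.abs(sums[visited >= 1] - 1.0).max() <= 1e-5
        assert np.allclose(field[0][visited == 0], 1.0)


class TestBinarize:
    def test_argmax_above_threshold(self):
        prob = np.zeros((3, 2, 1, 1))
        prob[:, 0, 0, 0] = (0.2, 0.7, 0.1)
        prob[:, 1, 0, 0] = (0.9, 0.05, 0.05)
        mask = binarize_and_split(prob, InferenceConfig())
        assert mask.data[0, 0, 0] == 1
        assert mask.data[1, 0, 0] == 0

    def test_all_background_empty(self):
        prob = np.zeros((3, 4, 4, 4))
        prob[0] = 1.0
        mask = binarize_and_split(prob, InferenceConfig())
        assert not mask.data.any()

    def test_largest_component_filter(self):
        prob = np.zeros((3, 20, 8, 8))
        prob[0] = 1.0
        prob[1, 2:7, 2:6, 2:7] = 0.9  # 100-voxel blob
        prob[0, 2:7, 2:6, 2:7] = 0.1
        prob[1, 15:16, 2:3, 2:5] = 0.9  # 3-voxel blob
        prob[0, 15:16, 2:3, 2:5] = 0.1
        mask_on = binarize_and_split(prob, InferenceConfig(largest_component=True))
        mask_off = binarize_and_split(prob, InferenceConfig(largest_component=False))
        assert (mask_on.data == 1).sum() == 100
        assert (mask_off.data == 1).sum() == 103


class _BoxStub:
    """Scores foreground wherever the image patch is bright."""

    def predict_probs(self, x):
        bright = (x[:, 0] > 0.5).astype(np.float64)
        fg = 0.45 * bright
        return np.stack([1.0 - 2 * fg, fg, fg], axis=1)


def _stub_model(n_levels=3):
    cfg = DNPConfig(
        pyramid=PatchPyramidConfig(n_levels=n_levels), unet=UNetConfig.desk()
    )
    model = PatchworkModel(cfg, seed=0)
    model.nets = [_BoxStub() for _ in range(n_levels)]
    return model


@pytest.fixture(scope="module")
def box_volume():
    data = np.zeros((96, 96, 96), dtype=np.float32)
    data[40:72, 30:62, 35:67] = 1.0
    return VolumeGrid(data)


class TestBranchingCombinatorics:
    def test_one_pass_evaluation_count(self, box_volume):
        """6 draws/3 keeps per parent over 3 levels: 6 + 18 + 54 = 78 evals."""
        model = _stub_model()
        res = predict_volume(
            model, box_volume, InferenceConfig(n_passes=1, seed=0)
        )
        assert res.n_evaluations == 78

    def test_kept_finest_patches_track_the_box(self, box_volume):
        model = _stub_model()
        res = predict_volume(model, box_volume, InferenceConfig(n_passes=1, seed=1))
        # stitched foreground only appears where patches overlapped the box
        fg = res.prob[1] + res.prob[2]
        outside = fg[box_volume.data == 0]
        inside = fg[box_volume.data > 0]
        assert inside.max() > 0.5
        assert outside.max() <= inside.max()

    def test_branching_visits_subset_of_exhaustive(self, box_volume):
        model = _stub_model()
        bran = predict_volume(model, box_volume, InferenceConfig(n_passes=2, seed=0))
        exh = predict_volume(model, box_volume, InferenceConfig(mode="exhaustive"))
        assert (exh.visited >= 1).all()  # exhaustive coverage invariant
        assert ((bran.visited >= 1) <= (exh.visited >= 1)).all()

    def test_volume_smaller_than_coarse_patch_padded(self):
        model = _stub_model(n_levels=2)
        small = VolumeGrid(np.zeros((40, 40, 40), dtype=np.float32))
        res = predict_volume(model, small, InferenceConfig(n_passes=1, seed=0))
        assert res.prob.shape == (3, 40, 40, 40)


class TestTrainedModelInference:
    def test_branching_close_to_exhaustive(self, trained_patchwork, phantom_cohorts):
        """Branching at default passes matches the exhaustive oracle's
        cohort-mean Dice."""
        _, test_cohort = phantom_cohorts
        d_exh, d_bran = [], []
        for subject in test_cohort.subjects:
            exh = trained_patchwork.predict(subject.image, mode="exhaustive")
            bran = trained_patchwork.predict(subject.image, mode="branching")
            d_exh.append(dice(exh.data > 0, subject.mask.data > 0))
            d_bran.append(dice(bran.data > 0, subject.mask.data > 0))
        assert abs(np.mean(d_exh) - np.mean(d_bran)) <= 0.02

    def test_finest_level_not_worse_than_coarsest_alone(
        self, trained_patchwork, phantom_cohorts
    ):
        """Conditioning smoke test: the hierarchy must not hurt at toy scale."""
        from patchwork3d.model import DNPConfig, PatchworkModel
        from patchwork3d.pyramid import PatchPyramidConfig

        _, test_cohort = phantom_cohorts
        subject = test_cohort.subjects[0]
        full_model = trained_patchwork.model_
        coarse = PatchworkModel(
            DNPConfig(
                pyramid=PatchPyramidConfig(n_levels=1), unet=full_model.cfg.unet
            ),
            seed=0,
        )
        coarse.nets = [full_model.nets[0]]
        cfg = InferenceConfig(mode="exhaustive")
        d_full = dice(
            predict_volume(full_model, subject.image, cfg).mask.data > 0,
            subject.mask.data > 0,
        )
        d_coarse = dice(
            predict_volume(coarse, subject.image, cfg).mask.data > 0,
            subject.mask.data > 0,
        )
        assert d_full >= d_coarse

    def test_dice_nondecreasing_in_passes(self, trained_patchwork, phantom_cohorts):
        _, test_cohort = phantom_cohorts
        subject = test_cohort.subjects[0]
        medians = []
        for n_passes in (4, 16, 64):
            ds = []
            for seed in range(3):
                seg = predict_volume(
                    trained_patchwork.model_,
                    subject.image,
                    InferenceConfig(n_passes=n_passes, seed=seed),
                )
                ds.append(dice(seg.mask.data > 0, subject.mask.data > 0))
            medians.append(float(np.median(ds)))
        assert medians[0] <= medians[1] + 0.01
        assert medians[1] <= medians[2] + 0.01
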