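"""Sampler bias, top-K BCE loss, and scaled-down training runs."""

from dataclasses import replace

import numpy as np
import pytest

from patchwork3d.grid import LabelMask, VolumeGrid
from patchwork3d.model import DNPConfig, PatchworkModel, UNetConfig
from patchwork3d.phantom import PhantomConfig, make_putamen_mask, render_volume
from patchwork3d.pyramid import PatchPyramidConfig, extract_patch
from patchwork3d.trainer import (
    TrainConfig,
    biased_patch_sampler,
    topk_bce_loss,
    train,
)


@pytest.fixture(scope="module")
def phantom_pair():
    cfg = PhantomConfig()
    mask = make_putamen_mask(cfg)
    image = render_volume(cfg, mask, np.random.default_rng(0))
    return image, mask


def _hit_fraction(image, mask, pyramid, label_bias, n, seed):
    cfg = TrainConfig(label_bias=label_bias, validation=False)
    sampler = biased_patch_sampler([(image, mask)], pyramid, cfg, np.random.default_rng(seed))
    hits = 0
    for _ in range(n):
        _, chain = next(sampler)
        patch = extract_patch(mask, chain[-1], "label", pyramid.matrix)
        hits += bool((patch > 0).any())
    return hits / n


class TestBiasedSampler:
    def test_full_bias_always_hits(self, phantom_pair):
        image, mask = phantom_pair
        frac = _hit_fraction(image, mask, PatchPyramidConfig(), 1.0, 1000, 1)
        assert frac == 1.0

    @pytest.mark.parametrize("bias", [0.5, 0.8])
    def test_intermediate_bias_converges(self, phantom_pair, bias):
        image, mask = phantom_pair
        n = 3000
        frac = _hit_fraction(image, mask, PatchPyramidConfig(), bias, n, 2)
        half = 2.58 * np.sqrt(bias * (1 - bias) / n) + 0.01
        assert abs(frac - bias) <= half

    def test_zero_bias_matches_geometric_oracle(self, phantom_pair):
        """Uniform draws hit foreground at the rate given by box dilation.

        Brute-force oracle: enumerate candidate centers densely on the voxel
        lattice; a center hits iff any foreground voxel lies within the
        patch half-size box (computed with an integral image).
        """
        image, mask = phantom_pair
        half = 16  # patch half-size (mm) at 1 mm spacing
        fg = np.pad((mask.data > 0).astype(np.int64), half)
        # summed-area table over the padded field; box sum for every center
        # via 8-term inclusion-exclusion on shifted slices
        cum = fg.cumsum(0).cumsum(1).cumsum(2)
        P = np.zeros(tuple(s + 1 for s in fg.shape), dtype=np.int64)
        P[1:, 1:, 1:] = cum
        n = mask.data.shape[0]
        w = 2 * half + 1

        def sl(off):  # slice of length n starting at off
            return slice(off, off + n)

        s = (
            P[sl(w), sl(w), sl(w)]
            - P[sl(0), sl(w), sl(w)]
            - P[sl(w), sl(0), sl(w)]
            - P[sl(w), sl(w), sl(0)]
            + P[sl(0), sl(0), sl(w)]
            + P[sl(0), sl(w), sl(0)]
            + P[sl(w), sl(0), sl(0)]
            - P[sl(0), sl(0), sl(0)]
        )
        oracle = float((s > 0).mean())
        n = 4000
        frac = _hit_fraction(image, mask, PatchPyramidConfig(), 0.0, n, 3)
        se = np.sqrt(oracle * (1 - oracle) / n)
        assert abs(frac - oracle) <= 4 * se + 0.01

    def test_empty_mask_warns_and_degrades_gracefully(self):
        image = VolumeGrid(np.zeros((64, 64, 64), dtype=np.float32))
        mask = LabelMask(np.zeros((64, 64, 64), dtype=np.uint8))
        cfg = TrainConfig(label_bias=0.8, validation=False)
        with pytest.warns(UserWarning, match="empty mask"):
            sampler = biased_patch_sampler(
                [(image, mask)], PatchPyramidConfig(), cfg, np.random.default_rng(0)
            )
            _, chain = next(sampler)
        assert len(chain) == 3


class TestTopKBceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((1, 3, 4, 4, 4), dtype=np.float64)
        t[:, 0] = 1.0
        assert topk_bce_loss(t.copy(), t, 1.0) <= 1e-5

    def test_full_fraction_equals_mean_bce_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, size=(2, 3, 5, 5, 5))
        t = (rng.random((2, 3, 5, 5, 5)) > 0.5).astype(float)
        loss = topk_bce_loss(p, t, 1.0)
        oracle = float(np.mean(
            (-(t * np.log(p) + (1 - t) * np.log1p(-p))).reshape(2, 3, -1).sum(axis=1)
        ))
        assert abs(loss - oracle) <= 1e-8

    def test_four_voxel_half_fraction(self):
        # per-voxel BCE values (0.1, 0.2, 0.7, 1.0); top half -> (0.7+1.0)/2
        bce = np.array([0.1, 0.2, 0.7, 1.0])
        p = np.exp(-bce).reshape(1, 1, 4, 1, 1)
        t = np.ones_like(p)
        assert topk_bce_loss(p, t, 0.5) == pytest.approx(0.85, abs=1e-9)

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, size=(3, 3, 6, 6, 6))
        t = (rng.random(p.shape) > 0.7).astype(float)
        fractions = [0.05, 0.1, 0.25, 0.5, 0.75, 1.0]
        losses = [topk_bce_loss(p, t, f) for f in fractions]
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_invalid_fraction(self):
        p = np.full((1, 3, 2, 2, 2), 1 / 3)
        with pytest.raises(ValueError):
            topk_bce_loss(p, p, 0.0)

    def test_gradient_matches_numerical(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=(1, 3, 3, 1, 1))
        t = (rng.random(p.shape) > 0.5).astype(float)
        loss, gp = topk_bce_loss(p, t, 1.0, return_grad=True)
        for _ in range(5):
            idx = tuple(rng.integers(s) for s in p.shape)
            eps = 1e-7
            pp, pm = p.copy(), p.copy()
            pp[idx] += eps
            pm[idx] -= eps
            num = (topk_bce_loss(pp, t, 1.0) - topk_bce_loss(pm, t, 1.0)) / (2 * eps)
            assert gp[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


TINY_TRAIN = dict(
    n_patches=480,
    batch_size=8,
    validation=False,
)


class TestTraining:
    def test_empty_cohort_rejected(self):
        model = PatchworkModel(DNPConfig(unet=UNetConfig.desk()), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_seed_determinism(self, phantom_pair):
        image, mask = phantom_pair
        cfg = DNPConfig(
            pyramid=PatchPyramidConfig(n_levels=2, coarsest_fov_mm=96.0),
            unet=UNetConfig(feature_dims=(2, 4), decoder_kernel=1),
        )
        losses = []
        for _ in range(2):
            model = PatchworkModel(cfg, seed=0)
            result = train(model, [(image, mask)], TrainConfig(seed=3, **TINY_TRAIN))
            losses.append(result.log["loss"].to_numpy())
        assert np.array_equal(losses[0], losses[1])


@pytest.fixture(scope="session")
def overfit_run():
    """Single-phantom overfit: 2,000 patches, tiny 2-level configuration."""
    from patchwork3d.inference import InferenceConfig, predict_volume
    from patchwork3d.metrics import dice

    pc = PhantomConfig(noise_sd=0.05, distractors=False)
    mask = make_putamen_mask(pc)
    image = render_volume(pc, mask, np.random.default_rng(3))
    cfg = DNPConfig(
        pyramid=PatchPyramidConfig(n_levels=2, coarsest_fov_mm=96.0),
        unet=UNetConfig.desk(),
    )
    model = PatchworkModel(cfg, seed=0)
    # tiny config: single-chain batches maximize optimizer steps within the
    # 2,000-patch budget, equal per-level split, slightly raised step size
    tc = TrainConfig(
        n_patches=2000,
        batch_size=1,
        learning_rate=0.002,
        level_budget_weights=(1.0, 1.0),
        validation=False,
        seed=0,
    )
    result = train(model, [(image, mask)], tc)
    seg = predict_volume(model, image, InferenceConfig(mode="exhaustive"))
    d = dice(seg.mask.data > 0, mask.data > 0)
    return result, d


class TestOverfitSinglePhantom:
    def test_exhaustive_dice_on_training_phantom(self, overfit_run):
        _, d = overfit_run
        assert d >= 0.98

    def test_loss_decreases(self, overfit_run):
        # compare like with like: the warm-up prefix runs at full top-K
        # fraction, so only the post-warm-up (hard-voxel) trace is comparable
        result, _ = overfit_run
        finest = result.log[result.log["level"] == result.log["level"].max()]
        losses = finest["loss"].to_numpy()
        post = losses[int(np.ceil(0.1 * len(losses))):]
        k = max(1, len(post) // 10)
        assert post[-k:].mean() < post[:k].mean()
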