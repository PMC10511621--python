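"""Training: label-biased nested patch sampling, top-K BCE loss, Adam loop.

The sampler's ``label_bias`` is the *target fraction* of finest patches
containing at least one label voxel (default 0.8).  A finest patch is
anchored on a random foreground voxel with a per-subject probability
calibrated so that, together with the chance hits of the remaining
uniform draws, the overall label-containing fraction equals the target;
parent patches are then drawn bottom-up, uniformly over the positions
that keep the chain properly nested.

The loss is a binary cross-entropy variant of the top-K loss: per-voxel
BCE summed over the softmax class channels, averaged over the
``topk_fraction`` hardest voxels of each patch.  Selection is per patch
(hard-voxel mining); a warm-up period at full fraction avoids early
instability.  Each level is supervised with its own label patch and
updated by its own Adam optimizer; finer levels are conditioned on the
parent's detached predictions, exactly as at inference time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .grid import LabelMask, VolumeGrid
from .metrics import dice
from .model import PatchworkModel
from .phantom import PhantomCohort, PhantomSubject
from .pyramid import PatchPyramidConfig, PatchSpec, extract_patch, level_sizes

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainingResult",
    "biased_patch_sampler",
    "materialize_chain",
    "topk_bce_loss",
    "train",
]

EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Desk defaults (20,000 patches, batch 16) are sized for a one-CPU run;
    ``paper()`` restores the reference scale (5 million patches, batch 150).
    """

    learning_rate: float = 0.001
    batch_size: int = 16
    n_patches: int = 20_000
    label_bias: float = 0.8
    topk_fraction: float = 0.1
    warmup_fraction: float = 0.1  # initial fraction of each level's steps at topk=1
    level_budget_weights: tuple[float, ...] | None = None  # default: 2 for level 0, 1 each finer
    validation: bool = True
    val_interval: int = 50
    val_chains_per_case: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.label_bias <= 1.0):
            raise ValueError("label_bias must lie in [0, 1]")
        if not (0.0 < self.topk_fraction <= 1.0):
            raise ValueError("topk_fraction must lie in (0, 1]")

    @classmethod
    def paper(cls) -> "TrainConfig":
        return cls(batch_size=150, n_patches=5_000_000)


@dataclass
class TrainingResult:
    model: PatchworkModel
    log: pd.DataFrame
    best_val_dice: float = float("nan")


def _subject_arrays(subject) -> tuple[VolumeGrid, LabelMask]:
    if isinstance(subject, PhantomSubject):
        if subject.image is None:
            raise ValueError(f"subject {subject.subject_id} has no rendered image")
        return subject.image, subject.mask
    image, mask = subject
    return image, mask


def _draw_chain(
    image: VolumeGrid,
    mask: LabelMask,
    fg_world: np.ndarray | None,
    pyramid: PatchPyramidConfig,
    anchor_prob: float,
    rng: np.random.Generator,
) -> list[PatchSpec]:
    """One nested chain, anchored at a (possibly label-biased) finest center."""
    sizes = level_sizes(pyramid)
    finest_size = sizes[-1][0]
    lo, hi = image.world_bounds()
    if fg_world is not None and fg_world.size and rng.random() < anchor_prob:
        v = fg_world[rng.integers(len(fg_world))]
        # jitter keeps the anchor voxel strictly inside the finest patch
        slack = 0.5 * finest_size - max(float(image.spacing.max()), 1e-3)
        center = v + rng.uniform(-slack, slack, size=3)
    else:
        center = rng.uniform(lo, hi)
    chain = [PatchSpec(level=pyramid.n_levels - 1, center_mm=center, size_mm=finest_size)]
    for level in range(pyramid.n_levels - 2, -1, -1):
        child = chain[0]
        size = sizes[level][0]
        slack = 0.5 * (size - child.size_mm)
        center = child.center_mm + rng.uniform(-slack, slack, size=3)
        chain.insert(0, PatchSpec(level=level, center_mm=center, size_mm=size))
    return chain


def _uniform_hit_probability(mask: LabelMask, finest_size_mm: float) -> float:
    """Chance that a uniformly placed finest patch contains a label voxel.

    The hit region is the foreground dilated by the patch half-size box;
    evaluated on the voxel lattice of centers (adequate at mm spacing).
    """
    from scipy.ndimage import maximum_filter

    fg = mask.data > 0
    if not fg.any():
        return 0.0
    box = tuple(
        2 * int(np.floor(0.5 * finest_size_mm / s)) + 1 for s in mask.spacing
    )
    return float(maximum_filter(fg, size=box, mode="constant").mean())


def biased_patch_sampler(
    subjects,
    pyramid: PatchPyramidConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
):
    """Infinite stream of ``(subject_index, chain)`` nested patch chains.

    The finest patch is foreground-anchored with a per-subject probability
    ``(label_bias - q) / (1 - q)`` where ``q`` is the subject's uniform hit
    probability, so the realized label-containing fraction matches
    ``cfg.label_bias``.  Subjects with empty masks fall back to unbiased
    draws (warned once).
    """
    pairs = [_subject_arrays(s) for s in subjects]
    finest_size = level_sizes(pyramid)[-1][0]
    fg_worlds = []
    anchor_probs = []
    for i, (image, mask) in enumerate(pairs):
        idx = np.argwhere(mask.data > 0)
        if idx.size == 0:
            if cfg.label_bias > 0:
                warnings.warn(
                    f"subject {i} has an empty mask; it will only yield unbiased draws",
                    stacklevel=2,
                )
            fg_worlds.append(None)
            anchor_probs.append(0.0)
        else:
            fg_worlds.append(mask.voxel_to_world(idx))
            q = _uniform_hit_probability(mask, finest_size)
            anchor_probs.append(float(np.clip((cfg.label_bias - q) / max(1.0 - q, 1e-12), 0.0, 1.0)))
    while True:
        i = int(rng.integers(len(pairs)))
        image, mask = pairs[i]
        yield i, _draw_chain(image, mask, fg_worlds[i], pyramid, anchor_probs[i], rng)


def materialize_chain(
    image: VolumeGrid,
    mask: LabelMask | None,
    chain: list[PatchSpec],
    matrix: int = 32,
) -> tuple[list[np.ndarray], list[np.ndarray] | None]:
    """Extract image (trilinear) and label (nearest) patches for a chain."""
    imgs = [extract_patch(image, spec, "image", matrix) for spec in chain]
    if mask is None:
        return imgs, None
    labs = [extract_patch(mask, spec, "label", matrix) for spec in chain]
    return imgs, labs


def topk_bce_loss(
    pred_probs: np.ndarray,
    target_onehot: np.ndarray,
    topk_fraction: float,
    return_grad: bool = False,
):
    """Binary cross-entropy over class channels, averaged over the hardest voxels.

    ``pred_probs`` and ``target_onehot`` are (B, C, ...) of equal shape;
    per-voxel BCE is summed over C, the ``topk_fraction`` largest per-voxel
    losses within each patch are kept, and their mean (over kept voxels and
    batch) is returned.  ``topk_fraction=1`` is plain mean BCE.
    """
    if topk_fraction <= 0 or topk_fraction > 1:
        raise ValueError("topk_fraction must lie in (0, 1]")
    p = np.clip(pred_probs, EPS, 1.0 - EPS)
    t = target_onehot
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    B, C = p.shape[0], p.shape[1]
    n_vox = int(np.prod(p.shape[2:]))
    bce = -(t * np.log(p) + (1 - t) * np.log1p(-p))  # (B, C, ...)
    per_vox = bce.reshape(B, C, n_vox).sum(axis=1)  # (B, n_vox)
    k = int(np.ceil(topk_fraction * n_vox))
    if k >= n_vox:
        sel = np.ones((B, n_vox), dtype=bool)
    else:
        thresh_idx = np.argpartition(per_vox, n_vox - k, axis=1)[:, n_vox - k :]
        sel = np.zeros((B, n_vox), dtype=bool)
        np.put_along_axis(sel, thresh_idx, True, axis=1)
    loss = float(per_vox[sel].sum() / (B * k))
    if not return_grad:
        return loss
    gp = np.where(t.astype(bool), -1.0 / p, 1.0 / (1.0 - p))
    gp = gp * sel.reshape(B, 1, *pred_probs.shape[2:]) / (B * k)
    # zero gradient where clipping was active and pushes further out of range
    gp = gp.astype(pred_probs.dtype)
    return loss, gp


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def train(
    model: PatchworkModel,
    cohort,
    cfg: TrainConfig | None = None,
) -> TrainingResult:
    """Train a patchwork on a cohort of (image, mask) subjects.

    Levels are trained coarse to fine, each against its own label patch;
    finer levels are conditioned on the (already trained) parent levels'
    predictions, exactly as at inference.  The total patch budget
    ``cfg.n_patches`` is split across levels by ``level_budget_weights``
    (default: twice the share for level 0, whose left/right semantics are
    the slowest to emerge).  One validation case per diagnosis class (when
    diagnoses are available) is held out of the sampling pool and monitored
    with patch-level Dice during the finest level's phase; the
    best-validation parameters are restored at the end.  Deterministic
    given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    subjects = list(cohort.subjects) if isinstance(cohort, PhantomCohort) else list(cohort)
    if not subjects:
        raise ValueError("empty cohort")
    ss = np.random.SeedSequence([cfg.seed, 0x7261])
    rng_split, rng_sample, rng_val = [np.random.default_rng(s) for s in ss.spawn(3)]

    val_subjects: list = []
    train_subjects = subjects
    if cfg.validation:
        by_class: dict[str, list] = {}
        for s in subjects:
            key = s.diagnosis if isinstance(s, PhantomSubject) else "all"
            by_class.setdefault(key, []).append(s)
        if all(len(v) >= 2 for v in by_class.values()) and len(by_class) < len(subjects):
            for key in sorted(by_class):
                pick = by_class[key][int(rng_split.integers(len(by_class[key])))]
                val_subjects.append(pick)
            train_subjects = [s for s in subjects if s not in val_subjects]

    pyramid = model.cfg.pyramid
    matrix = model.cfg.unet.matrix
    n_classes = model.cfg.unet.out_classes
    n_levels = pyramid.n_levels
    sampler = biased_patch_sampler(train_subjects, pyramid, cfg, rng_sample)
    pairs = [_subject_arrays(s) for s in train_subjects]

    weights = cfg.level_budget_weights
    if weights is None:
        weights = tuple([2.0] + [1.0] * (n_levels - 1))
    if len(weights) != n_levels:
        raise ValueError("one budget weight per level required")
    w = np.asarray(weights, dtype=float)
    total_steps = max(n_levels, cfg.n_patches // cfg.batch_size)
    level_steps = np.maximum(1, np.floor(total_steps * w / w.sum()).astype(int))

    val_chains = _make_val_chains(model, val_subjects, cfg, rng_val) if val_subjects else None

    log_rows = []
    best_val = -np.inf
    best_state = None
    for lvl in range(n_levels):
        net = model.nets[lvl]
        optim = _nn.Adam(net.params(), lr=cfg.learning_rate)
        n_steps = int(level_steps[lvl])
        warmup_steps = int(np.ceil(cfg.warmup_fraction * n_steps))
        is_finest = lvl == n_levels - 1
        for step in range(n_steps):
            frac = 1.0 if step < warmup_steps else cfg.topk_fraction
            batch = [next(sampler) for _ in range(cfg.batch_size)]
            chains = [chain for _si, chain in batch]
            imgs = np.empty((lvl + 1, cfg.batch_size, matrix, matrix, matrix), np.float32)
            labs = np.empty((cfg.batch_size, matrix, matrix, matrix), np.int16)
            for j, (si, chain) in enumerate(batch):
                image, mask = pairs[si]
                for k in range(lvl + 1):
                    imgs[k, j] = extract_patch(image, chain[k], "image", matrix)
                labs[j] = extract_patch(mask, chain[lvl], "label", matrix)

            # conditioning from the already-trained coarser levels
            parent_probs = None
            for k in range(lvl + 1):
                x = imgs[k][:, None]
                if k > 0:
                    cond = np.stack(
                        [
                            model.conditioning(parent_probs[j], chains[j][k - 1], chains[j][k])
                            for j in range(cfg.batch_size)
                        ]
                    ).astype(np.float32)
                    x = np.concatenate([x, cond], axis=1)
                if k < lvl:
                    parent_probs = model.nets[k].predict_probs(x)

            logits = net.forward(x)
            probs = _nn.softmax(logits, axis=1)
            target = _onehot(labs, n_classes)
            loss, gp = topk_bce_loss(probs, target, frac, return_grad=True)
            glogits = _nn.softmax_backward(probs, gp, axis=1)
            optim.zero_grad()
            net.backward(glogits)
            optim.step()

            row = {"level": lvl, "step": step, "loss": loss}
            if (
                val_chains is not None
                and is_finest
                and (step % cfg.val_interval == 0 or step == n_steps - 1)
            ):
                val_dice = _validate(model, val_chains)
                for key, v in val_dice.items():
                    row[f"val_dice_{key}"] = v
                mean_val = float(np.mean(list(val_dice.values())))
                row["val_dice_mean"] = mean_val
                if mean_val > best_val:
                    best_val = mean_val
                    best_state = [n.get_state() for n in model.nets]
            log_rows.append(row)

    if best_state is not None:
        for net, state in zip(model.nets, best_state):
            net.set_state(state)
    return TrainingResult(
        model=model,
        log=pd.DataFrame(log_rows),
        best_val_dice=best_val if np.isfinite(best_val) else float("nan"),
    )


def _make_val_chains(model, val_subjects, cfg: TrainConfig, rng) -> list:
    """Fixed foreground-anchored chains per validation case (patch-level Dice)."""
    out = []
    for s in val_subjects:
        image, mask = _subject_arrays(s)
        key = s.diagnosis if isinstance(s, PhantomSubject) else "case"
        fg = np.argwhere(mask.data > 0)
        fg_world = mask.voxel_to_world(fg) if fg.size else None
        chains = [
            _draw_chain(image, mask, fg_world, model.cfg.pyramid, 1.0, rng)
            for _ in range(cfg.val_chains_per_case)
        ]
        mats = [materialize_chain(image, mask, c, model.cfg.unet.matrix) for c in chains]
        out.append((key, chains, mats))
    return out


def _validate(model: PatchworkModel, val_chains) -> dict[str, float]:
    from .model import forward_hierarchy  # local import to avoid cycle at module load

    scores: dict[str, list[float]] = {}
    for key, chains, mats in val_chains:
        for chain, (imgs, labs) in zip(chains, mats):
            probs = forward_hierarchy(model.nets, imgs, chain, model.cfg)
            pred = probs.argmax(axis=0) * (probs[1:].sum(axis=0) >= 0.5)
            scores.setdefault(key, []).append(dice(pred > 0, labs[-1] > 0))
    return {k: float(np.mean(v)) for k, v in scores.items()}
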