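"""Full-volume prediction: tree-like branching sampling and exhaustive mode.

Branching mode mirrors the patchwork's random patching scheme: per pass,
several coarsest-level patches are drawn at random, each is scored by its
mean predicted foreground probability, and the highest-scoring candidates
are kept; each kept patch spawns nested child candidates at the next finer
level, and so on down to the finest level, whose predictions are stitched
into the volume.  Defaults follow the 6-draw / 3-keep-per-parent rule, so
one pass over a 3-level pyramid costs exactly 6 + 3*6 + 9*6 = 78 network
evaluations.  Repeating the tree with independent restarts (``n_passes``)
accumulates coverage of the label-bearing parts of the volume.

Exhaustive mode slides a regular grid of nested chains over the whole
volume and serves as the oracle: every in-volume voxel is visited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label

from ._resample import grid_sample_trilinear
from .grid import LabelMask, VolumeGrid
from .model import PatchworkModel
from .pyramid import PatchSpec, level_sizes, patch_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "SegmentationResult",
    "rank_candidates",
    "predict_volume",
    "stitch",
    "binarize_and_split",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Branching/exhaustive prediction settings."""

    n_candidates: int = 6
    n_keep: int = 3
    n_passes: int = 64
    threshold: float = 0.5
    mode: str = "branching"  # or "exhaustive"
    overlap_stride_mm: float = 16.0
    keep_rule: str = "per_parent"  # or "global"
    largest_component: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_keep <= self.n_candidates):
            raise ValueError("need 1 <= n_keep <= n_candidates")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.mode not in ("branching", "exhaustive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SegmentationResult:
    prob: np.ndarray  # (C, X, Y, Z) class probabilities on the input grid
    visited: np.ndarray  # per-voxel evaluation counts
    mask: LabelMask
    n_evaluations: int = 0


def rank_candidates(candidates: list, scores, n_keep: int) -> list:
    """Keep the ``n_keep`` highest-scoring candidates, in score order.

    Ties are broken by draw order (earlier draw wins).  If fewer candidates
    than ``n_keep`` are supplied, all are kept (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    if len(candidates) != len(scores):
        raise ValueError("one score per candidate required")
    if len(candidates) < n_keep:
        logger.warning("only %d candidates for n_keep=%d; keeping all", len(candidates), n_keep)
        n_keep = len(candidates)
    # stable sort on -score preserves draw order among ties
    order = np.argsort(-scores, kind="stable")[:n_keep]
    return [candidates[i] for i in order]


def _resample_to_grid(
    patch_probs: np.ndarray,
    spec: PatchSpec,
    vol: VolumeGrid,
    prob_acc: np.ndarray,
    visited: np.ndarray,
    matrix: int,
) -> None:
    """Accumulate one finest patch into the volume-level probability field.

    Only voxels strictly inside the patch's sample lattice are touched, so
    the trilinear weights always sum to one and stitched class
    probabilities stay normalized.
    """
    lo, _hi = patch_bounds(spec)
    spacing_p = spec.size_mm / matrix
    # voxel index range whose centers fall inside the patch interior
    centers_lo = lo + 0.5 * spacing_p
    centers_hi = lo + (matrix - 0.5) * spacing_p
    i_lo = np.maximum(np.ceil((centers_lo - vol.origin) / vol.spacing - 1e-9), 0).astype(int)
    i_hi = np.minimum(
        np.floor((centers_hi - vol.origin) / vol.spacing + 1e-9), np.array(vol.shape) - 1
    ).astype(int)
    if np.any(i_hi < i_lo):
        return
    axes = [
        (vol.origin[ax] + np.arange(i_lo[ax], i_hi[ax] + 1) * vol.spacing[ax] - lo[ax])
        / spacing_p
        - 0.5
        for ax in range(3)
    ]
    sl = tuple(slice(i_lo[ax], i_hi[ax] + 1) for ax in range(3))
    for c in range(patch_probs.shape[0]):
        prob_acc[c][sl] += grid_sample_trilinear(
            patch_probs[c].astype(np.float32, copy=False), *axes, clamp=True
        )
    visited[sl] += 1


def stitch(
    patch_probs: list[np.ndarray],
    specs: list[PatchSpec],
    vol: VolumeGrid,
    n_classes: int = 3,
    matrix: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Average finest-patch probabilities into a volume-level field.

    Returns the per-class probability field (unvisited voxels carry the
    background prior: background 1, foreground 0) and the visited counts.
    """
    prob_acc = np.zeros((n_classes,) + vol.shape, dtype=np.float64)
    visited = np.zeros(vol.shape, dtype=np.int32)
    for probs, spec in zip(patch_probs, specs):
        _resample_to_grid(probs, spec, vol, prob_acc, visited, matrix)
    out = np.zeros_like(prob_acc)
    seen = visited > 0
    for c in range(n_classes):
        out[c][seen] = prob_acc[c][seen] / visited[seen]
    out[0][~seen] = 1.0
    return out, visited


def binarize_and_split(
    prob: np.ndarray,
    cfg: InferenceConfig,
    spacing=None,
    origin=None,
) -> LabelMask:
    """Threshold a 3-class probability field into a side-separated mask.

    A voxel is foreground when its maximum foreground-class probability
    reaches the threshold; it then takes the argmax foreground class.  The
    optional largest-connected-component filter (on by default) keeps one
    6-connected component per class.
    """
    fg = prob[1:]
    best = fg.argmax(axis=0)
    keep = fg.max(axis=0) >= cfg.threshold
    data = np.where(keep, best + 1, 0).astype(np.uint8)
    if cfg.largest_component:
        for code in (1, 2):
            comp, n = cc_label(data == code)
            if n > 1:
                sizes = np.bincount(comp.ravel())[1:]
                keep_id = int(sizes.argmax()) + 1
                data[(data == code) & (comp != keep_id)] = 0
    return LabelMask(
        data=data,
        spacing=np.ones(3) if spacing is None else spacing,
        origin=np.zeros(3) if origin is None else origin,
    )


class _BatchedEvaluator:
    """Evaluates many (spec, parent) patches per level with batched forwards."""

    def __init__(self, model: PatchworkModel, vol: VolumeGrid, batch: int = 16):
        from .pyramid import extract_patch

        self.model = model
        self.vol = vol
        self.batch = batch
        self.matrix = model.cfg.unet.matrix
        self._extract = extract_patch
        self.n_evaluations = 0

    def evaluate(
        self,
        level: int,
        specs: list[PatchSpec],
        parents: list[tuple[np.ndarray, PatchSpec] | None],
    ) -> list[np.ndarray]:
        m = self.matrix
        xs = []
        for spec, parent in zip(specs, parents):
            img = self._extract(self.vol, spec, "image", m)[None].astype(np.float32)
            if level > 0:
                probs_p, spec_p = parent
                cond = self.model.conditioning(probs_p, spec_p, spec).astype(np.float32)
                img = np.concatenate([img, cond], axis=0)
            xs.append(img)
        out = []
        net = self.model.nets[level]
        for i in range(0, len(xs), self.batch):
            chunk = np.stack(xs[i : i + self.batch])
            probs = net.predict_probs(chunk)
            out.extend(probs)
            self.n_evaluations += len(chunk)
        return out


def _exhaustive_chains(model: PatchworkModel, vol: VolumeGrid, cfg: InferenceConfig):
    """Regular grid of nested chains covering every voxel."""
    sizes = level_sizes(model.cfg.pyramid)
    finest = sizes[-1][0]
    lo, hi = vol.world_bounds()
    centers_1d = []
    for ax in range(3):
        extent = hi[ax] - lo[ax]
        if extent <= finest:
            centers_1d.append(np.array([0.5 * (lo[ax] + hi[ax])]))
            continue
        start = lo[ax] + 0.5 * finest
        stop = hi[ax] - 0.5 * finest
        c = list(np.arange(start, stop, cfg.overlap_stride_mm))
        if not c or abs(c[-1] - stop) > 1e-9:
            c.append(stop)
        centers_1d.append(np.array(c))
    cx, cy, cz = np.meshgrid(*centers_1d, indexing="ij")
    centers = np.stack([cx, cy, cz], axis=-1).reshape(-1, 3)
    chains = []
    for center in centers:
        chain = [
            PatchSpec(level=k, center_mm=center, size_mm=sizes[k][0])
            for k in range(model.cfg.pyramid.n_levels)
        ]
        chains.append(chain)
    return chains


def predict_volume(
    model: PatchworkModel, vol: VolumeGrid, cfg: InferenceConfig | None = None
) -> SegmentationResult:
    """Segment a full volume with the trained patchwork."""
    cfg = cfg or InferenceConfig()
    sizes = level_sizes(model.cfg.pyramid)
    n_levels = model.cfg.pyramid.n_levels
    ev = _BatchedEvaluator(model, vol)
    finest_probs: list[np.ndarray] = []
    finest_specs: list[PatchSpec] = []

    if cfg.mode == "exhaustive":
        chains = _exhaustive_chains(model, vol, cfg)
        parents = [None] * len(chains)
        for level in range(n_levels):
            specs = [c[level] for c in chains]
            probs = ev.evaluate(level, specs, parents)
            parents = [(p, s) for p, s in zip(probs, specs)]
        finest_probs = [p for p, _ in parents]
        finest_specs = [c[-1] for c in chains]
    else:
        rng = np.random.default_rng(cfg.seed)
        lo, hi = vol.world_bounds()
        for _ in range(cfg.n_passes):
            kept: list[tuple[np.ndarray, PatchSpec] | None] = [None]
            kept_specs: list[PatchSpec | None] = [None]
            for level in range(n_levels):
                size = sizes[level][0]
                cand_specs: list[PatchSpec] = []
                cand_parents: list = []
                for parent in zip(kept, kept_specs):
                    probs_p, spec_p = parent[0], parent[1]
                    for _j in range(cfg.n_candidates):
                        if level == 0:
                            c_lo = np.minimum(lo + 0.5 * size, 0.5 * (lo + hi))
                            c_hi = np.maximum(hi - 0.5 * size, 0.5 * (lo + hi))
                            center = rng.uniform(c_lo, c_hi)
                            spec = PatchSpec(level=0, center_mm=center, size_mm=size)
                        else:
                            slack = 0.5 * (spec_p.size_mm - size)
                            center = spec_p.center_mm + rng.uniform(-slack, slack, size=3)
                            spec = PatchSpec(level=level, center_mm=center, size_mm=size)
                        cand_specs.append(spec)
                        cand_parents.append(probs_p if level == 0 else (probs_p, spec_p))
                probs = ev.evaluate(level, cand_specs, cand_parents if level > 0 else [None] * len(cand_specs))
                scores = [float(p[1:].mean()) for p in probs]
                if cfg.keep_rule == "global":
                    idx = rank_candidates(list(range(len(cand_specs))), scores, cfg.n_keep)
                else:  # per parent
                    idx = []
                    for g in range(0, len(cand_specs), cfg.n_candidates):
                        sub = list(range(g, g + len(cand_specs[g : g + cfg.n_candidates])))
                        idx.extend(
                            rank_candidates(sub, [scores[i] for i in sub], cfg.n_keep)
                        )
                kept = [probs[i] for i in idx]
                kept_specs = [cand_specs[i] for i in idx]
                if level == n_levels - 1:
                    # ranking only gates the recursion; there is no finer
                    # level, so every evaluated finest patch is stitched
                    # (selecting high-scoring leaves would bias the average
                    # toward foreground)
                    finest_probs.extend(probs)
                    finest_specs.extend(cand_specs)

    prob, visited = stitch(
        finest_probs, finest_specs, vol, model.cfg.unet.out_classes, model.cfg.unet.matrix
    )
    mask = binarize_and_split(prob, cfg, spacing=vol.spacing, origin=vol.origin)
    return SegmentationResult(prob=prob, visited=visited, mask=mask, n_evaluations=ev.n_evaluations)
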