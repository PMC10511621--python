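"""Patch-pyramid geometry: the ladder of nested patch scales.

The patchwork operates on patches of a fixed matrix size (default 32^3
voxels) but decreasing physical size: the coarsest level spans a 150 mm
field of view per axis (4.6875 mm voxels), the finest level spans
``matrix * finest_spacing_mm`` = 32 mm at 1 mm isotropic resolution.
Intermediate levels follow a geometric progression between the two
endpoints, giving a smooth resolution ladder.

All world<->voxel logic for patches lives here; every other module
consumes patches only through :func:`extract_patch` and
:func:`draw_nested_child`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._resample import grid_sample_nearest, grid_sample_trilinear
from .grid import VolumeGrid, _as_vec3

__all__ = [
    "PatchPyramidConfig",
    "PatchSpec",
    "level_sizes",
    "patch_bounds",
    "extract_patch",
    "draw_nested_child",
]


@dataclass(frozen=True)
class PatchPyramidConfig:
    """Geometry of the nested patch hierarchy.

    ``n_levels`` is not dictated by the 150 mm / 1 mm endpoints; it controls
    how many geometric steps lie between them and is exposed as config.
    """

    n_levels: int = 3
    matrix: int = 32
    coarsest_fov_mm: float = 150.0
    finest_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if self.matrix < 1:
            raise ValueError("matrix must be >= 1")
        if self.coarsest_fov_mm <= 0 or self.finest_spacing_mm <= 0:
            raise ValueError("sizes must be > 0")
        finest = self.matrix * self.finest_spacing_mm
        if self.n_levels > 1 and finest >= self.coarsest_fov_mm:
            raise ValueError(
                "finest patch size must be smaller than the coarsest field of view "
                f"({finest} mm >= {self.coarsest_fov_mm} mm)"
            )

    @property
    def finest_size_mm(self) -> float:
        return self.matrix * self.finest_spacing_mm


@dataclass(frozen=True)
class PatchSpec:
    """One patch: pyramid level, world center (mm) and physical side length (mm)."""

    level: int
    center_mm: np.ndarray
    size_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center_mm", _as_vec3(self.center_mm, "center_mm"))
        if not np.all(np.isfinite(self.center_mm)):
            raise ValueError(f"patch center must be finite, got {self.center_mm}")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be > 0")


def level_sizes(cfg: PatchPyramidConfig) -> list[tuple[float, float]]:
    """Per-level ``(size_mm, spacing_mm)``.

    Level 0 spans ``coarsest_fov_mm``; the last level spans
    ``matrix * finest_spacing_mm``; intermediate sizes interpolate
    geometrically.  Spacing is always ``size / matrix``.  For a
    single-level pyramid the sole level is the coarse one.
    """
    if cfg.n_levels == 1:
        sizes = [cfg.coarsest_fov_mm]
    else:
        ratio = cfg.finest_size_mm / cfg.coarsest_fov_mm
        sizes = [
            cfg.coarsest_fov_mm * ratio ** (k / (cfg.n_levels - 1)) for k in range(cfg.n_levels)
        ]
    return [(s, s / cfg.matrix) for s in sizes]


def patch_bounds(spec: PatchSpec) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned world box of a patch: ``center +- size/2`` per axis."""
    half = 0.5 * spec.size_mm
    return spec.center_mm - half, spec.center_mm + half


def _sample_positions(spec: PatchSpec, matrix: int) -> tuple[np.ndarray, float]:
    """1D world sample coordinates per axis (cell-center rule) and patch spacing."""
    lo, _ = patch_bounds(spec)
    spacing = spec.size_mm / matrix
    offsets = (np.arange(matrix) + 0.5) * spacing
    return lo[:, None] + offsets[None, :], spacing


def extract_patch(
    vol: VolumeGrid,
    spec: PatchSpec,
    mode: str = "image",
    matrix: int = 32,
    fill: float = 0.0,
) -> np.ndarray:
    """Resample a ``matrix^3`` patch from a volume.

    Patch voxel ``p`` (0-based) samples world position
    ``lo + (p + 0.5) * (size / matrix)``.  Image mode interpolates
    trilinearly, label mode takes the nearest voxel; positions outside the
    volume receive ``fill``.  When the patch grid coincides with the volume
    grid the result is an exact sub-block copy.
    """
    if mode not in ("image", "label"):
        raise ValueError(f"mode must be 'image' or 'label', got {mode!r}")
    pos, spacing = _sample_positions(spec, matrix)
    # continuous voxel coordinates of the sample positions, per axis
    coords1d = (pos - vol.origin[:, None]) / vol.spacing[:, None]

    aligned = np.allclose(spacing, vol.spacing, rtol=0, atol=1e-9)
    if aligned:
        starts = np.rint(coords1d[:, 0]).astype(int)
        if np.allclose(coords1d[:, 0], starts, atol=1e-6) and np.all(starts >= 0) and np.all(
            starts + matrix <= np.array(vol.shape)
        ):
            # grid-aligned fast path: bit-identical sub-block copy
            sl = tuple(slice(s, s + matrix) for s in starts)
            return vol.data[sl].copy()

    # crop to the patch's bounding box so gathers stay patch-sized
    data = vol.data
    shifted = []
    sub = data
    for ax in range(3):
        c = coords1d[ax]
        i0 = int(np.clip(np.floor(c.min()) - 1, 0, data.shape[ax] - 1))
        i1 = int(np.clip(np.ceil(c.max()) + 2, i0 + 1, data.shape[ax]))
        sub = sub[(slice(None),) * ax + (slice(i0, i1),)]
        shifted.append(c - i0)
    if mode == "image":
        return grid_sample_trilinear(sub, *shifted, fill=fill)
    return grid_sample_nearest(sub, *shifted, fill=fill)


def draw_nested_child(
    parent: PatchSpec, cfg: PatchPyramidConfig, rng: np.random.Generator
) -> PatchSpec:
    """Draw a child patch one level below ``parent``, uniformly within it.

    The child's box is contained in the parent's; its center is uniform over
    the admissible region (the parent box shrunk by the child half-size per
    side).  When the child size equals the parent size the child center is
    forced to the parent center.
    """
    if parent.level >= cfg.n_levels - 1:
        raise ValueError(f"patch at level {parent.level} is already the finest level")
    sizes = level_sizes(cfg)
    child_size = sizes[parent.level + 1][0]
    slack = 0.5 * (parent.size_mm - child_size)
    if slack < 0:
        raise ValueError("child size exceeds parent size; invalid pyramid")
    center = parent.center_mm + rng.uniform(-slack, slack, size=3)
    return PatchSpec(level=parent.level + 1, center_mm=center, size_mm=child_size)


def validate_chain(chain: list[PatchSpec], cfg: PatchPyramidConfig, atol: float = 1e-6) -> None:
    """Raise if ``chain`` is not a properly nested root->leaf patch chain."""
    sizes = level_sizes(cfg)
    if len(chain) != cfg.n_levels:
        raise ValueError(f"chain has {len(chain)} patches for a {cfg.n_levels}-level pyramid")
    for k, spec in enumerate(chain):
        if spec.level != k:
            raise ValueError(f"chain position {k} holds a level-{spec.level} patch")
        if abs(spec.size_mm - sizes[k][0]) > atol:
            raise ValueError(
                f"level-{k} patch size {spec.size_mm} != pyramid size {sizes[k][0]}"
            )
    for parent, child in zip(chain, chain[1:]):
        plo, phi = patch_bounds(parent)
        clo, chi = patch_bounds(child)
        if np.any(clo < plo - atol) or np.any(chi > phi + atol):
            raise ValueError("broken nesting: child box not contained in parent box")
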