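"""Axis-aligned 3D scalar grids and label masks.

A :class:`VolumeGrid` is the in-memory container for one volumetric image:
a 3D array plus per-axis voxel spacing (mm) and the world coordinate of the
center of voxel (0, 0, 0).  Grids are axis aligned — the world position of
voxel index ``i`` is ``origin + i * spacing`` — which is all the patchwork
needs; rotated acquisitions are resampled to this frame at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "LabelMask", "BACKGROUND", "LEFT_PUTAMEN", "RIGHT_PUTAMEN"]

BACKGROUND = 0
LEFT_PUTAMEN = 1
RIGHT_PUTAMEN = 2


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(3, float(v))
    if v.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 vector, got shape {v.shape}")
    return v


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing and world origin.

    Parameters
    ----------
    data:
        3D array of voxel values.
    spacing:
        Per-axis voxel size in mm (scalar broadcasts to all axes).
    origin:
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, world) -> np.ndarray:
        """Continuous voxel index of world positions (mm); inverse of voxel_to_world."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer world box of the grid (voxel edges, not centers)."""
        lo = self.origin - 0.5 * self.spacing
        hi = self.origin + (np.array(self.shape) - 0.5) * self.spacing
        return lo, hi

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid | LabelMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelMask(VolumeGrid):
    """Integer mask on a :class:`VolumeGrid` frame.

    Codes: 0 background, 1 left putamen, 2 right putamen.
    """

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label mask values must be integers")
            self.data = rounded.astype(np.uint8)
        super().__post_init__()
        bad = np.setdiff1d(np.unique(self.data), [BACKGROUND, LEFT_PUTAMEN, RIGHT_PUTAMEN])
        if bad.size:
            raise ValueError(f"label mask contains unknown codes {bad.tolist()}")
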