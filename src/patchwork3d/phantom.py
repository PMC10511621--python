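"""Synthetic atrophic-putamen phantoms.

Generates T1-weighted-like volumes containing two bilateral ellipsoidal
"putamen" structures inside a head-like envelope, plus caudate- and
pallidum-like distractor ellipsoids, piecewise-constant intensities and
additive Gaussian noise.  Cohorts of phantoms follow the group volume
distributions reported for healthy controls (4.61 +- 0.54 mL), multiple
system atrophy (2.62 +- 1.03 mL) and Parkinson's disease (4.34 +- 0.53 mL),
treated as two-side totals and truncated below at 0.5 mL.

Atrophy is realized by scaling the putamen semi-axes by the cube root of a
volume factor, optionally preceded by erosion of a dorsolateral cap — a
crude nod to the dorsolaterally accentuated putaminal degeneration seen in
MSA, without any claim of anatomical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .grid import LabelMask, VolumeGrid, LEFT_PUTAMEN, RIGHT_PUTAMEN

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "PhantomSubject",
    "PhantomCohort",
    "make_putamen_mask",
    "render_volume",
    "sample_target_volumes",
    "sample_cohort",
]

# group volume distributions (two-side totals, mL): mean, sd
GROUP_VOLUME_ML = {
    "HC": (4.61, 0.54),
    "MSA": (2.62, 1.03),
    "PD": (4.34, 0.53),
}
GROUP_SIZES = {"HC": 15, "MSA": 31, "PD": 74}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity model of one phantom volume.

    Axis convention: axis 0 = left-right (left putamen at lower x),
    axis 1 = posterior-anterior, axis 2 = inferior-superior.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    spacing_mm: float = 1.0
    putamen_semi_axes_mm: tuple[float, float, float] = (7.5, 11.0, 16.0)
    putamen_lateral_offset_mm: float = 26.0  # center distance from midline
    atrophy_factor: float = 1.0  # volume scale in (0, 1]
    dorsolateral_erosion: bool = False
    erosion_cap: float = 0.55  # normalized plane offset of the removed cap
    # piecewise-constant intensity means, arbitrary units before z-scoring
    intensity_air: float = 0.0
    intensity_brain: float = 1.0
    intensity_putamen: float = 1.5
    intensity_caudate: float = 1.35
    intensity_pallidum: float = 1.75
    intensity_csf: float = 0.1
    fissure_halfwidth_mm: float = 2.5
    noise_sd: float = 0.1
    distractors: bool = True

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.putamen_semi_axes_mm):
            raise ValueError("putamen semi-axes must be > 0")
        if not (0 < self.atrophy_factor <= 1):
            raise ValueError("atrophy_factor must lie in (0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be > 0")

    @property
    def center_mm(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.grid_shape) - 1) * self.spacing_mm

    def putamen_centers(self) -> dict[int, np.ndarray]:
        c = self.center_mm
        off = np.array([self.putamen_lateral_offset_mm, 0.0, 0.0])
        return {LEFT_PUTAMEN: c - off, RIGHT_PUTAMEN: c + off}

    @property
    def full_volume_mm3(self) -> float:
        """Analytic two-side ellipsoid volume at atrophy_factor 1, no erosion."""
        a, b, c = self.putamen_semi_axes_mm
        return 2.0 * (4.0 / 3.0) * np.pi * a * b * c


@dataclass(frozen=True)
class CohortConfig:
    """Sample sizes and volume distributions of a synthetic cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    group_volumes_mL: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GROUP_VOLUME_ML)
    )
    truncation_mL: float = 0.5
    msa_dorsolateral_erosion: bool = True

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if any(sd <= 0 for _, sd in self.group_volumes_mL.values()):
            raise ValueError("group volume sds must be > 0")
        if self.truncation_mL <= 0:
            raise ValueError("truncation bound must be > 0")


@dataclass
class PhantomSubject:
    subject_id: str
    diagnosis: str
    image: VolumeGrid | None
    mask: LabelMask
    true_volume_mL: dict[str, float]  # keys: left, right, total


@dataclass
class PhantomCohort:
    subjects: list[PhantomSubject]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "diagnosis": [s.diagnosis for s in self.subjects],
                "true_volume_mL": [s.true_volume_mL["total"] for s in self.subjects],
            }
        )


def _coord_axes(cfg: PhantomConfig) -> list[np.ndarray]:
    return [np.arange(n) * cfg.spacing_mm for n in cfg.grid_shape]


def _ellipsoid_voxels(
    cfg: PhantomConfig,
    center: np.ndarray,
    semi_axes: np.ndarray,
    erode_cap_dir: np.ndarray | None = None,
    erosion_cap: float = 0.55,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Boolean field of voxels inside an ellipsoid, on a cropped bounding box.

    ``erode_cap_dir``, if given, is a unit vector in normalized ellipsoid
    coordinates; voxels with normalized projection onto it above
    ``erosion_cap`` are removed (a planar cap).
    """
    axes = _coord_axes(cfg)
    los, his = [], []
    for ax in range(3):
        lo = int(np.floor((center[ax] - semi_axes[ax]) / cfg.spacing_mm)) - 1
        hi = int(np.ceil((center[ax] + semi_axes[ax]) / cfg.spacing_mm)) + 2
        if lo < 0 or hi > cfg.grid_shape[ax]:
            raise ValueError("structure extends outside the phantom grid")
        los.append(lo)
        his.append(hi)
    sl = tuple(slice(lo, hi) for lo, hi in zip(los, his))
    u = [
        (axes[ax][sl[ax]] - center[ax]) / semi_axes[ax]
        for ax in range(3)
    ]
    ux, uy, uz = np.meshgrid(*u, indexing="ij")
    inside = ux * ux + uy * uy + uz * uz <= 1.0
    if erode_cap_dir is not None:
        proj = ux * erode_cap_dir[0] + uy * erode_cap_dir[1] + uz * erode_cap_dir[2]
        inside &= proj <= erosion_cap
    return sl, inside


def make_putamen_mask(cfg: PhantomConfig) -> LabelMask:
    """Voxelize the bilateral putamen ellipsoids into a label mask.

    The atrophy factor ``f`` scales each semi-axis by ``f**(1/3)`` so the
    analytic volume scales linearly with ``f``; the optional dorsolateral
    cap is removed in normalized coordinates and therefore commutes with
    the scaling.
    """
    semi = np.asarray(cfg.putamen_semi_axes_mm) * cfg.atrophy_factor ** (1.0 / 3.0)
    data = np.zeros(cfg.grid_shape, dtype=np.uint8)
    centers = cfg.putamen_centers()
    regions = {}
    for code, center in centers.items():
        cap_dir = None
        if cfg.dorsolateral_erosion:
            # lateral (away from midline) + superior, in normalized coords
            lat = -1.0 if code == LEFT_PUTAMEN else 1.0
            cap_dir = np.array([lat, 0.0, 1.0]) / np.sqrt(2.0)
        sl, inside = _ellipsoid_voxels(cfg, center, semi, cap_dir, cfg.erosion_cap)
        regions[code] = (sl, inside)
    # disjointness: paint both and count
    for code, (sl, inside) in regions.items():
        sub = data[sl]
        if np.any(sub[inside] != 0):
            raise ValueError("left and right putamen structures overlap")
        sub[inside] = code
    return LabelMask(data=data, spacing=np.full(3, cfg.spacing_mm), origin=np.zeros(3))


def _distractor_specs(cfg: PhantomConfig) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Caudate- and pallidum-like confusers per side: (center, semi_axes, intensity)."""
    c = cfg.center_mm
    out = []
    for side in (-1.0, 1.0):
        # caudate-like: more medial, anterior and superior, elongated
        out.append(
            (
                c + np.array([side * 13.0, 16.0, 12.0]),
                np.array([4.0, 9.0, 12.0]),
                cfg.intensity_caudate,
            )
        )
        # pallidum-like: medial to the putamen, smaller
        out.append(
            (
                c + np.array([side * 12.0, -2.0, -2.0]),
                np.array([4.0, 6.0, 8.0]),
                cfg.intensity_pallidum,
            )
        )
    return out


def render_volume(
    cfg: PhantomConfig, mask: LabelMask, rng: np.random.Generator
) -> VolumeGrid:
    """Render a z-scored T1w-like volume for a putamen mask.

    Piecewise-constant means (air / brain envelope / distractors / putamen,
    the mask painting last) plus additive Gaussian noise; the result is
    z-scored over the whole volume so patches can be filled with 0 outside.
    Rendering depends on the diagnosis only through the mask geometry.
    """
    data = np.full(cfg.grid_shape, cfg.intensity_air, dtype=np.float32)
    # head-like envelope
    head_semi = 0.5 * (np.asarray(cfg.grid_shape) * cfg.spacing_mm) - 6.0
    sl, inside = _ellipsoid_voxels(cfg, cfg.center_mm, head_semi)
    data[sl][inside] = cfg.intensity_brain
    # interhemispheric-fissure-like CSF plane: the midline landmark that
    # makes left/right assignment learnable from local context
    if cfg.fissure_halfwidth_mm > 0:
        xs = _coord_axes(cfg)[0]
        mid = np.abs(xs - cfg.center_mm[0]) <= cfg.fissure_halfwidth_mm
        fissure = np.zeros(cfg.grid_shape, dtype=bool)
        fissure[mid] = True
        fissure &= data > cfg.intensity_air  # only inside the head
        data[fissure] = cfg.intensity_csf
    if cfg.distractors:
        for center, semi, intensity in _distractor_specs(cfg):
            sl, inside = _ellipsoid_voxels(cfg, center, semi)
            data[sl][inside] = intensity
    data[mask.data > 0] = cfg.intensity_putamen
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape).astype(np.float32)
    data = (data - data.mean()) / data.std()
    return VolumeGrid(
        data=data.astype(np.float32), spacing=np.full(3, cfg.spacing_mm), origin=np.zeros(3)
    )


def sample_target_volumes(cc: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject target total putaminal volumes (mL) per group.

    Volumes follow the configured normal distributions truncated below at
    ``truncation_mL`` (the MSA distribution has non-negligible mass near 0).
    """
    rows = []
    for group in sorted(cc.group_sizes):
        n = cc.group_sizes[group]
        if n == 0:
            continue
        mean, sd = cc.group_volumes_mL[group]
        a = (cc.truncation_mL - mean) / sd
        vols = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        for i, v in enumerate(vols):
            rows.append({"subject_id": f"{group}-{i:03d}", "diagnosis": group, "volume_mL": v})
    return pd.DataFrame(rows)


def _calibrate_atrophy(cfg: PhantomConfig, target_mm3: float) -> tuple[float, LabelMask]:
    """Find the atrophy factor whose voxelized mask hits a target total volume.

    The voxel count is monotone in the factor, so a short bisection reaches
    well below the 3 % discretization tolerance.
    """
    vox = cfg.spacing_mm**3

    def realized(f: float) -> tuple[float, LabelMask]:
        m = make_putamen_mask(replace(cfg, atrophy_factor=f))
        return float(np.count_nonzero(m.data)) * vox, m

    lo, hi = 1e-4, 1.0
    v_hi, m_hi = realized(hi)
    if target_mm3 >= v_hi:
        return hi, m_hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v_mid, m_mid = realized(mid)
        if abs(v_mid - target_mm3) / target_mm3 < 0.005:
            return mid, m_mid
        if v_mid < target_mm3:
            lo = mid
        else:
            hi = mid
    return mid, m_mid


def sample_cohort(
    cc: CohortConfig,
    pc: PhantomConfig,
    rng: np.random.Generator | int,
    render: bool = True,
) -> PhantomCohort:
    """Generate a cohort of phantom subjects.

    Each subject's target total volume is drawn from its group's truncated
    normal; the atrophy factor is then calibrated so the voxelized mask hits
    the target.  MSA subjects additionally get the dorsolateral erosion cap
    when ``cc.msa_dorsolateral_erosion`` is set.  Deterministic given the rng
    seed; ``render=False`` skips the image (masks and volumes only).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    targets = sample_target_volumes(cc, rng)
    subjects = []
    vox = pc.spacing_mm**3
    for row in targets.itertuples(index=False):
        cfg = replace(
            pc,
            dorsolateral_erosion=pc.dorsolateral_erosion
            or (cc.msa_dorsolateral_erosion and row.diagnosis == "MSA"),
        )
        _, mask = _calibrate_atrophy(cfg, row.volume_mL * 1000.0)
        left = float(np.count_nonzero(mask.data == LEFT_PUTAMEN)) * vox / 1000.0
        right = float(np.count_nonzero(mask.data == RIGHT_PUTAMEN)) * vox / 1000.0
        image = render_volume(cfg, mask, rng) if render else None
        subjects.append(
            PhantomSubject(
                subject_id=row.subject_id,
                diagnosis=row.diagnosis,
                image=image,
                mask=mask,
                true_volume_mL={"left": left, "right": right, "total": left + right},
            )
        )
    return PhantomCohort(subjects=subjects)
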