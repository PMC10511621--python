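"""Segmentation-quality metrics: Dice, 95 % Hausdorff distance, volumetry,
Bland-Altman agreement.

Conventions (stated explicitly because atrophic cases can produce empty
predictions): Dice of two empty masks is 1.0, of one empty mask 0.0; the
95 % Hausdorff distance is undefined (raises) when either mask is empty.
hd95 uses the pooled symmetric convention: the 95th percentile (linear
interpolation) of both directed surface-to-surface nearest-distance
multisets pooled together, with surfaces taken as 6-connected border
voxels and distances measured between voxel centers in mm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .grid import LabelMask, LEFT_PUTAMEN, RIGHT_PUTAMEN

__all__ = [
    "dice",
    "hd95",
    "mask_volume",
    "bland_altman",
    "evaluate_masks",
    "EmptyMaskError",
]


class EmptyMaskError(ValueError):
    """Raised when a metric is undefined for empty input masks."""


def _as_bool(a) -> np.ndarray:
    arr = a.data if isinstance(a, LabelMask) else np.asarray(a)
    return arr.astype(bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks.

    Both masks empty -> 1.0 by convention; exactly one empty -> 0.0.
    """
    A, B = _as_bool(a), _as_bool(b)
    if A.shape != B.shape:
        raise ValueError(f"mask grids differ: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(A, B).sum())
    return 2.0 * inter / (na + nb)


def _surface_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """World coordinates (mm) of 6-connected border voxels."""
    border = mask & ~binary_erosion(mask, border_value=0)
    idx = np.argwhere(border)
    return idx * spacing[None, :]


def hd95(a, b, spacing=1.0, percentile: float = 95.0, direction: str = "pooled") -> float:
    """95th percentile of surface-to-surface nearest distances, in mm.

    The default pools both directed distance multisets (the symmetric
    convention); ``direction="ab"`` or ``"ba"`` gives the directed variants.
    """
    A, B = _as_bool(a), _as_bool(b)
    if A.shape != B.shape:
        raise ValueError(f"mask grids differ: {A.shape} vs {B.shape}")
    if not A.any() or not B.any():
        raise EmptyMaskError("hd95 is undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    if sp.ndim == 0:
        sp = np.full(3, float(sp))
    pa = _surface_points(A, sp)
    pb = _surface_points(B, sp)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    if direction == "ab":
        pooled = d_ab
    elif direction == "ba":
        pooled = d_ba
    elif direction == "pooled":
        pooled = np.concatenate([d_ab, d_ba])
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(np.percentile(pooled, percentile))


def mask_volume(mask: LabelMask, spacing=None) -> dict[str, float]:
    """Volumes in mL per class and total (voxel count x voxel volume)."""
    sp = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    if sp.ndim == 0:
        sp = np.full(3, float(sp))
    vox_mL = float(np.prod(sp)) / 1000.0
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    left = int((data == LEFT_PUTAMEN).sum()) * vox_mL
    right = int((data == RIGHT_PUTAMEN).sum()) * vox_mL
    return {"left": left, "right": right, "total": left + right}


def bland_altman(method: np.ndarray, reference: np.ndarray) -> dict:
    """Bland-Altman agreement statistics over paired measurements.

    Returns the mean difference (method - reference), the 1.96-SD limits of
    agreement, and the per-pair (mean, difference) plot data.
    """
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("method and reference must be 1D arrays of equal length")
    if m.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = m - r
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd,
        "loa_lower": mean_diff - 1.96 * sd,
        "loa_upper": mean_diff + 1.96 * sd,
        "means": 0.5 * (m + r),
        "diffs": diff,
    }


def evaluate_masks(pred: LabelMask, ref: LabelMask) -> dict:
    """Per-side and combined Dice / hd95 / volumes for one subject.

    hd95 entries are NaN (reported as missing) where a side is empty in
    either mask.
    """
    if not pred.same_grid(ref):
        raise ValueError("prediction and reference are on different grids")
    out: dict[str, float] = {}
    for name, code in [("left", LEFT_PUTAMEN), ("right", RIGHT_PUTAMEN)]:
        p = pred.data == code
        r = ref.data == code
        out[f"dice_{name}"] = dice(p, r)
        try:
            out[f"hd95_{name}"] = hd95(p, r, pred.spacing)
        except EmptyMaskError:
            out[f"hd95_{name}"] = float("nan")
    p, r = pred.data > 0, ref.data > 0
    out["dice_combined"] = dice(p, r)
    try:
        out["hd95_combined"] = hd95(p, r, pred.spacing)
    except EmptyMaskError:
        out["hd95_combined"] = float("nan")
    vp, vr = mask_volume(pred), mask_volume(ref)
    for k in ("left", "right", "total"):
        out[f"volume_pred_{k}_mL"] = vp[k]
        out[f"volume_ref_{k}_mL"] = vr[k]
    return out


def evaluate_cohort(pairs: list[tuple[str, LabelMask, LabelMask]]) -> pd.DataFrame:
    """Tabulate :func:`evaluate_masks` over (subject_id, pred, ref) triples."""
    rows = []
    for sid, pred, ref in pairs:
        row = {"subject_id": sid}
        row.update(evaluate_masks(pred, ref))
        rows.append(row)
    return pd.DataFrame(rows)
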