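"""NIfTI volumes, TSV cohort manifests, YAML run configs, seeds.

NIfTI-1 is the sole volumetric format (.nii / .nii.gz, via nibabel).
Grids are axis aligned in memory; inputs with rotated affines are
resampled onto an axis-aligned grid at load time with a logged warning.
Manifests are tab-separated with a header — diff-able and spreadsheet-safe.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import affine_transform

from .grid import LabelMask, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "split_cohort",
    "save_cohort",
    "load_config",
    "save_config",
    "write_provenance",
]

DIAGNOSES = ("HC", "MSA", "PD")


def _grid_from_nifti(img) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    if aff is None or not np.isfinite(aff).all():
        raise ValueError("volume has no usable affine")
    rot = aff[:3, :3]
    if abs(np.linalg.det(rot)) < 1e-12:
        raise ValueError("affine is not invertible")
    spacing = np.linalg.norm(rot, axis=0)
    offdiag = rot - np.diag(np.diag(rot))
    if np.abs(offdiag).max() > 1e-4 * spacing.max():
        logger.warning("rotated affine detected; resampling to an axis-aligned grid")
        return _resample_axis_aligned(data.astype(np.float32), aff)
    diag = np.diag(rot)
    origin = aff[:3, 3].astype(float).copy()
    out = data
    # fold axis flips (negative spacing) into the data layout
    for ax in range(3):
        if diag[ax] < 0:
            out = np.flip(out, axis=ax)
            origin[ax] = origin[ax] + diag[ax] * (data.shape[ax] - 1)
    return np.ascontiguousarray(out), spacing, origin


def _resample_axis_aligned(data, aff):
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    corners = np.array(
        [[i, j, k] for i in (0, data.shape[0] - 1) for j in (0, data.shape[1] - 1) for k in (0, data.shape[2] - 1)]
    )
    world = (aff[:3, :3] @ corners.T).T + aff[:3, 3]
    lo, hi = world.min(axis=0), world.max(axis=0)
    shape = np.maximum(np.round((hi - lo) / spacing).astype(int) + 1, 1)
    # world = aff @ index  =>  index = inv(aff) @ (origin + out_index * spacing)
    inv = np.linalg.inv(aff[:3, :3])
    matrix = inv * spacing[None, :]
    offset = inv @ (lo - aff[:3, 3])
    out = affine_transform(
        data, matrix, offset=offset, output_shape=tuple(shape), order=1, mode="constant"
    )
    return out, spacing, lo


def read_volume(path) -> VolumeGrid:
    """Load a NIfTI volume as an axis-aligned :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return VolumeGrid(data=np.asarray(data, dtype=np.float32), spacing=spacing, origin=origin)


def read_mask(path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    return LabelMask(data=np.rint(np.asarray(data)).astype(np.uint8), spacing=spacing, origin=origin)


def _affine(grid: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _save_nifti(img: "nib.Nifti1Image", path) -> None:
    """Byte-deterministic save: .gz output embeds no timestamp."""
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
    else:
        nib.save(img, str(path))


def write_volume(vol: VolumeGrid, path) -> None:
    _save_nifti(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol)), path)


def write_mask(mask: LabelMask, path) -> None:
    _save_nifti(nib.Nifti1Image(np.asarray(mask.data, dtype=np.uint8), _affine(mask)), path)


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest (TSV with a header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "diagnosis"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dup}")
    bad = set(df["diagnosis"]) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnoses {sorted(bad)}; expected one of {DIAGNOSES}")
    if check_files:
        base = Path(path).parent
        for col in ("image_path", "mask_path"):
            if col in df.columns:
                for p in df[col].dropna():
                    fp = Path(p)
                    if not fp.is_absolute():
                        fp = base / fp
                    if not fp.exists():
                        raise FileNotFoundError(f"{col} entry does not exist: {p}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def split_cohort(
    manifest: pd.DataFrame, train_fraction: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level train/test split, stratified by diagnosis.

    Each diagnosis group is split with its training count rounded to the
    nearest integer (at least one subject on each side), guaranteeing
    disjointness and reproducibility by seed.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for dx, group in manifest.groupby("diagnosis", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"diagnosis group {dx!r} has {n} subject(s); cannot stratify")
        n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
        perm = rng.permutation(n)
        idx = group.index.to_numpy()[perm]
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train = manifest.loc[sorted(train_idx)].reset_index(drop=True)
    test = manifest.loc[sorted(test_idx)].reset_index(drop=True)
    return train, test


def save_cohort(cohort, out_dir) -> pd.DataFrame:
    """Write per-subject NIfTI image + mask and the cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        img_path = out_dir / f"{s.subject_id}_T1w.nii.gz"
        mask_path = out_dir / f"{s.subject_id}_mask.nii.gz"
        if s.image is not None:
            write_volume(s.image, img_path)
        write_mask(s.mask, mask_path)
        rows.append(
            {
                "subject_id": s.subject_id,
                "diagnosis": s.diagnosis,
                "image_path": img_path.name if s.image is not None else "",
                "mask_path": mask_path.name,
                "true_volume_mL": s.true_volume_mL["total"],
            }
        )
    df = pd.DataFrame(rows)
    write_manifest(df, out_dir / "manifest.tsv")
    return df


# ---- run configuration ----

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "runs",
    "pyramid": {"n_levels": 3, "matrix": 32, "coarsest_fov_mm": 150.0, "finest_spacing_mm": 1.0},
    "model": {
        "feature_dims": [4, 8, 16, 32],
        "convs_per_block": 1,
        "out_classes": 3,
        "decoder_kernel": 1,
    },
    "training": {
        "learning_rate": 0.001,
        "batch_size": 16,
        "n_patches": 20000,
        "label_bias": 0.8,
        "topk_fraction": 0.1,
    },
    "inference": {
        "n_candidates": 6,
        "n_keep": 3,
        "n_passes": 64,
        "threshold": 0.5,
        "mode": "branching",
        "overlap_stride_mm": 16.0,
    },
    "phantom": {"grid_shape": [160, 160, 160], "spacing_mm": 1.0, "noise_sd": 0.1},
    "cohort": {
        "group_sizes": {"HC": 15, "MSA": 31, "PD": 74},
        "truncation_mL": 0.5,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML run config on top of the defaults (round-trips losslessly)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_provenance(out_dir, cfg: dict, seed: int) -> None:
    """Machine-readable provenance record for an output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "patchwork3d",
        "version": __version__,
        "seed": seed,
        "config": cfg,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
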