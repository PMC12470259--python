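"""Readers/writers for NIfTI volumes, PNG slice pairs, and dataset manifests.

Conventions: arrays are indexed (row, column) = (y, x); axial slices lie
along the third axis of a NIfTI array; slice indices are 0-based.  Image
intensities are widened to floating point on load.  Mask volumes must
contain at most two distinct values; any nonzero value maps to 1 (a warning
is logged when the on-disk values were not already {0, 1}).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .phantom import SubjectVolume

log = logging.getLogger("hippseg")

_PNG_IMG_SCALE = 65535.0  # 16-bit image PNGs
_MANIFEST_COLUMNS = ["subject_id", "slice_index", "image_path", "mask_path", "split"]


# ------------------------------------------------------------------- NIfTI

def _coerce_mask(arr: np.ndarray, origin: str) -> np.ndarray:
    values = np.unique(arr)
    if len(values) > 2:
        raise ValidationError(
            f"mask {origin} has {len(values)} distinct values; expected binary")
    if not set(np.asarray(values).tolist()) <= {0, 1}:
        log.warning("mask %s values %s mapped to {0,1}", origin, values.tolist())
    return (arr > 0).astype(np.uint8)


def write_volume(volume: SubjectVolume, prefix: str | Path) -> list[tuple[Path, Path]]:
    """Write ``<prefix>_img.nii.gz`` and ``<prefix>_mask.nii.gz``.

    Returns one (image_path, mask_path) pair per slice (all slices share the
    same files; per-slice rows reference them for manifest building).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.spacing, 1.0])
    img_path = prefix.parent / (prefix.name + "_img.nii.gz")
    mask_path = prefix.parent / (prefix.name + "_mask.nii.gz")
    # (S, H, W) -> (H, W, S): axial slices along the third axis
    nib.save(nib.Nifti1Image(
        np.ascontiguousarray(volume.slices.transpose(1, 2, 0)).astype(np.float32),
        affine), img_path)
    nib.save(nib.Nifti1Image(
        np.ascontiguousarray(volume.masks.transpose(1, 2, 0)).astype(np.uint8),
        affine), mask_path)
    return [(img_path, mask_path)] * volume.n_slices


def read_volume(image_path: str | Path, mask_path: str | Path | None = None,
                subject_id: str | None = None) -> SubjectVolume:
    """Load a subject from NIfTI files written by :func:`write_volume` (or any
    NIfTI pair with axial slices along the third axis)."""
    image_path = Path(image_path)
    if not image_path.exists():
        raise ValidationError(f"volume not found: {image_path}")
    try:
        img = np.asanyarray(nib.load(image_path).dataobj)
    except Exception as exc:  # corrupt header etc.
        raise ValidationError(f"cannot read NIfTI {image_path}: {exc}") from exc
    if img.ndim != 3:
        raise ValidationError(f"{image_path}: expected a 3-D volume, got {img.shape}")
    slices = img.astype(np.float64).transpose(2, 0, 1)
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise ValidationError(f"mask volume not found: {mask_path}")
        m = np.asanyarray(nib.load(mask_path).dataobj)
        if m.shape != img.shape:
            raise ValidationError(
                f"image shape {img.shape} != mask shape {m.shape} "
                f"({image_path} vs {mask_path})")
        masks = _coerce_mask(m, str(mask_path)).transpose(2, 0, 1)
    else:
        masks = np.zeros_like(slices, dtype=np.uint8)
    sid = subject_id or image_path.name.split("_img")[0].split(".")[0]
    return SubjectVolume(subject_id=sid, slices=slices, masks=masks)


# --------------------------------------------------------------------- PNG

def write_png_slices(volume: SubjectVolume, out_dir: str | Path
                     ) -> list[tuple[Path, Path]]:
    """Write one 16-bit image PNG and one 8-bit {0,255} mask PNG per slice."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(volume.n_slices):
        img_path = out_dir / f"slice_{i:03d}_img.png"
        mask_path = out_dir / f"slice_{i:03d}_mask.png"
        img16 = np.clip(volume.slices[i], 0, 1) * _PNG_IMG_SCALE
        iio.imwrite(img_path, img16.round().astype(np.uint16))
        iio.imwrite(mask_path, (volume.masks[i] * 255).astype(np.uint8))
        pairs.append((img_path, mask_path))
    return pairs


def read_png_slices(slice_dir: str | Path, subject_id: str | None = None
                    ) -> SubjectVolume:
    """Load a subject from a directory of paired slice PNGs (0-based order)."""
    slice_dir = Path(slice_dir)
    img_files = sorted(slice_dir.glob("slice_*_img.png"))
    if not img_files:
        raise ValidationError(f"no slice PNGs found under {slice_dir}")
    slices, masks = [], []
    for img_path in img_files:
        mask_path = slice_dir / img_path.name.replace("_img.png", "_mask.png")
        if not mask_path.exists():
            raise ValidationError(f"unpaired slice image: {img_path}")
        slices.append(iio.imread(img_path).astype(np.float64) / _PNG_IMG_SCALE)
        masks.append(_coerce_mask(iio.imread(mask_path), str(mask_path)))
    return SubjectVolume(subject_id=subject_id or slice_dir.name,
                         slices=np.stack(slices), masks=np.stack(masks))


# ---------------------------------------------------------------- manifests

def manifest_from_rows(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    """Manifest invariants: required columns, per-subject split assignment."""
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    per_subject = df.groupby("subject_id")["split"].nunique()
    mixed = per_subject[per_subject > 1]
    if len(mixed):
        raise ValidationError(
            f"split assigned per slice, not per subject, for: {list(mixed.index)}")
    bad = set(df["split"].unique()) - {"train", "test", "none"}
    if bad:
        raise ValidationError(f"unknown split labels: {sorted(bad)}")


def save_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    validate_manifest(df)
    return df


def build_manifest(root: str | Path, split_spec: dict | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Discover paired data under ``root`` and assign a subject-level split.

    Two layouts are recognized: per-subject PNG directories written by
    :func:`write_png_slices`, and per-subject NIfTI pairs
    (``<sid>_img.nii.gz`` / ``<sid>_mask.nii.gz``; the Decathlon
    ``imagesTr``/``labelsTr`` pairing is handled by pointing ``root`` at the
    task folder).  ``split_spec`` is either ``{"train_subjects": n}``
    (first n subjects after a seeded shuffle) or explicit ID lists
    ``{"train_ids": [...], "test_ids": [...]}`` — explicit lists take
    precedence.
    """
    root = Path(root)
    rows = []
    subjects: dict[str, list] = {}
    png_dirs = sorted(d for d in root.iterdir() if d.is_dir()
                      and list(d.glob("slice_*_img.png"))) if root.exists() else []
    if png_dirs:
        for d in png_dirs:
            pairs = []
            for i, img in enumerate(sorted(d.glob("slice_*_img.png"))):
                mask = d / img.name.replace("_img.png", "_mask.png")
                if not mask.exists():
                    raise ValidationError(f"unpaired slice image: {img}")
                pairs.append((i, img, mask))
            subjects[d.name] = pairs
    else:
        imgs = sorted(root.glob("**/*_img.nii.gz")) if root.exists() else []
        if root.exists() and (root / "imagesTr").is_dir():
            for img in sorted((root / "imagesTr").glob("*.nii*")):
                mask = root / "labelsTr" / img.name
                if not mask.exists():
                    raise ValidationError(f"no label for {img}")
                sid = img.name.split(".")[0]
                n = np.asanyarray(nib.load(img).dataobj).shape[-1]
                subjects[sid] = [(i, img, mask) for i in range(n)]
        else:
            for img in imgs:
                mask = img.parent / img.name.replace("_img.nii.gz", "_mask.nii.gz")
                if not mask.exists():
                    raise ValidationError(f"unpaired volume: {img}")
                sid = img.name.replace("_img.nii.gz", "")
                n = np.asanyarray(nib.load(img).dataobj).shape[-1]
                subjects[sid] = [(i, img, mask) for i in range(n)]
    if not subjects:
        raise ValidationError(f"no paired data discovered under {root}")

    ids = sorted(subjects)
    split_of = {sid: "none" for sid in ids}
    if split_spec:
        if "train_ids" in split_spec or "test_ids" in split_spec:
            for sid in split_spec.get("train_ids", []):
                split_of[sid] = "train"
            for sid in split_spec.get("test_ids", []):
                split_of[sid] = "test"
        elif "train_subjects" in split_spec:
            order = np.random.default_rng(seed).permutation(len(ids))
            n_train = int(split_spec["train_subjects"])
            for rank, idx in enumerate(order):
                split_of[ids[idx]] = "train" if rank < n_train else "test"
    for sid in ids:
        for i, img, mask in subjects[sid]:
            rows.append((sid, i, str(img), str(mask), split_of[sid]))
    return manifest_from_rows(rows)


def load_split(manifest: pd.DataFrame, split: str) -> list[SubjectVolume]:
    """Materialize every subject of a manifest split into memory."""
    out = []
    for sid, group in manifest[manifest["split"] == split].groupby("subject_id"):
        first = Path(group.iloc[0]["image_path"])
        if first.suffix == ".png":
            out.append(read_png_slices(first.parent, subject_id=sid))
        else:
            out.append(read_volume(first, group.iloc[0]["mask_path"], subject_id=sid))
    return out
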