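"""Synthetic hippocampus-like phantom volumes.

Each phantom subject is a stack of axial slices in which a small, bright,
crescent-shaped structure (the difference of two offset discs — the simplest
shape with the concavity and thinness that make hippocampal delineation hard)
appears only within a central band of slices.  The crescent's centre and
orientation drift smoothly from slice to slice, so adjacent masks overlap
strongly and inter-slice context carries real signal.  Images get a smooth
tissue texture, a low-frequency multiplicative bias field (emulating coil
inhomogeneity), and additive Gaussian noise; masks are the exact noiseless
crescent supports.

Defaults mirror the bookkeeping of a cross-sectional hippocampus study:
189 slices per subject with a ~30-slice labelled band, and a foreground that
occupies only a few percent of each labelled slice (the small-structure
regime that makes this segmentation task non-trivial).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError


@dataclass(frozen=True)
class PhantomParams:
    n_subjects: int = 135
    slices_per_subject: int = 189
    labeled_band: int = 30
    image_size: tuple[int, int] = (192, 160)
    crescent_outer_radius: tuple[float, float] = (12.0, 18.0)
    crescent_thickness: tuple[float, float] = (4.0, 6.0)
    drift_per_slice: float = 1.0
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.labeled_band > self.slices_per_subject:
            raise ValidationError(
                f"labeled_band={self.labeled_band} exceeds "
                f"slices_per_subject={self.slices_per_subject}")
        if self.crescent_outer_radius[0] <= 0 or self.crescent_thickness[0] <= 0:
            raise ValidationError("crescent radius and thickness must be positive")
        if self.drift_per_slice < 0:
            raise ValidationError("drift_per_slice must be >= 0")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


@dataclass
class SubjectVolume:
    subject_id: str
    slices: np.ndarray          # (S, H, W) float in [0, 1]
    masks: np.ndarray           # (S, H, W) uint8 in {0, 1}
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.slices.shape != self.masks.shape:
            raise ValidationError(
                f"slices shape {self.slices.shape} != masks shape {self.masks.shape}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.masks.reshape(self.n_slices, -1).any(axis=1))


def _crescent_mask(shape: tuple[int, int], center: np.ndarray, radius: float,
                   thickness: float, angle: float) -> np.ndarray:
    """Support of disc(center, radius) minus an equal disc offset by
    ``thickness`` along ``angle`` — a crescent of maximal width ``thickness``."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d_out = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    cy = center[0] + thickness * np.sin(angle)
    cx = center[1] + thickness * np.cos(angle)
    d_in = (yy - cy) ** 2 + (xx - cx) ** 2
    return (d_out <= radius ** 2) & (d_in > radius ** 2)


def generate_subject(params: PhantomParams, subject_seed: int) -> SubjectVolume:
    """Generate one phantom subject, bit-reproducible from ``subject_seed``."""
    rng = np.random.default_rng(subject_seed)
    h, w = params.image_size
    s = params.slices_per_subject
    band = params.labeled_band
    band_start = (s - band) // 2

    radius = rng.uniform(*params.crescent_outer_radius)
    thickness = rng.uniform(*params.crescent_thickness)
    margin = radius + 2.0
    if 2 * margin >= min(h, w):
        raise ValidationError(
            f"crescent radius {radius:.1f} too large for image size {h}x{w}")
    center = np.array([
        rng.uniform(0.35 * h, 0.65 * h),
        rng.uniform(0.35 * w, 0.65 * w),
    ])
    angle = rng.uniform(0, 2 * np.pi)

    # smooth multiplicative bias field, fixed across the volume (coil pattern)
    fy, fx = rng.uniform(0.3, 0.7, size=2)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    bias = 1.0 + params.bias_amplitude * np.cos(
        2 * np.pi * (fy * yy / h + fx * xx / w) + phase)

    slices = np.empty((s, h, w), dtype=np.float64)
    masks = np.zeros((s, h, w), dtype=np.uint8)
    for i in range(s):
        texture = gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
        img = 0.35 + 0.05 * texture / max(texture.std(), 1e-9)
        in_band = band_start <= i < band_start + band
        if in_band:
            mask = _crescent_mask((h, w), center, radius, thickness, angle)
            masks[i] = mask.astype(np.uint8)
            img = img + 0.35 * mask
            # smooth drift for the next in-band slice (step norm <= drift)
            step = rng.uniform(-1.0, 1.0, size=2)
            norm = np.hypot(*step)
            if norm > 1.0:
                step /= norm
            center = np.clip(center + params.drift_per_slice * step,
                             [margin, margin], [h - margin, w - margin])
            angle += rng.uniform(-0.03, 0.03)
        img = img * bias + rng.normal(0.0, params.noise_sigma, size=(h, w))
        slices[i] = np.clip(img, 0.0, 1.0)
    return SubjectVolume(subject_id=f"sub-{subject_seed:08d}", slices=slices,
                         masks=masks)


def _subject_seed(params: PhantomParams, index: int) -> int:
    return int((params.seed * 1_000_003 + index) % (2 ** 31))


def generate_volumes(params: PhantomParams) -> list[SubjectVolume]:
    """All subjects of a phantom dataset, in memory, deterministically."""
    vols = []
    for i in range(params.n_subjects):
        v = generate_subject(params, _subject_seed(params, i))
        v.subject_id = f"sub-{i:03d}"
        vols.append(v)
    return vols


def generate_dataset(params: PhantomParams, out_dir: str | Path,
                     train_subjects: int | None = None, fmt: str = "png"):
    """Write a phantom dataset to disk and return its manifest.

    ``train_subjects`` first subjects are marked ``train`` and the rest
    ``test`` (subject-level split); with ``None`` every row's split is
    ``none``.  ``fmt`` selects per-slice PNG pairs or per-subject NIfTI.
    """
    from . import io as hio  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if train_subjects is not None and train_subjects > params.n_subjects:
        raise ValidationError("train_subjects exceeds n_subjects")
    rows = []
    for i in range(params.n_subjects):
        vol = generate_subject(params, _subject_seed(params, i))
        vol.subject_id = f"sub-{i:03d}"
        split = "none"
        if train_subjects is not None:
            split = "train" if i < train_subjects else "test"
        if fmt == "png":
            paths = hio.write_png_slices(vol, out_dir / vol.subject_id)
        elif fmt == "nifti":
            paths = hio.write_volume(vol, out_dir / vol.subject_id)
        else:
            raise ValidationError(f"unknown format {fmt!r}")
        for idx, (img_path, mask_path) in enumerate(paths):
            rows.append((vol.subject_id, idx, str(img_path), str(mask_path), split))
    manifest = hio.manifest_from_rows(rows)
    hio.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def dataset_layout(params: PhantomParams, train_subjects: int | None = None,
                   root: str | Path = "."):
    """Manifest bookkeeping only: the rows :func:`generate_dataset` would
    produce (subject ids, slice indices, prospective paths, subject-level
    split), without generating any image data.  Useful for planning splits
    and verifying image counts at full study scale."""
    from . import io as hio

    root = Path(root)
    if train_subjects is not None and train_subjects > params.n_subjects:
        raise ValidationError("train_subjects exceeds n_subjects")
    rows = []
    for i in range(params.n_subjects):
        sid = f"sub-{i:03d}"
        split = "none"
        if train_subjects is not None:
            split = "train" if i < train_subjects else "test"
        for idx in range(params.slices_per_subject):
            rows.append((sid, idx,
                         str(root / sid / f"slice_{idx:03d}_img.png"),
                         str(root / sid / f"slice_{idx:03d}_mask.png"), split))
    return hio.manifest_from_rows(rows)


def fixture_params() -> PhantomParams:
    """The standard small benchmark: 20 subjects x 12 slices at 64 x 64 with a
    6-slice labelled band, fixed seed 7."""
    return PhantomParams(
        n_subjects=20, slices_per_subject=12, labeled_band=6,
        image_size=(64, 64), crescent_outer_radius=(10.0, 13.0),
        crescent_thickness=(4.0, 6.0), drift_per_slice=1.0,
        noise_sigma=0.03, bias_amplitude=0.10, seed=7)


def fixture_volumes() -> list[SubjectVolume]:
    """In-memory volumes of the standard benchmark."""
    return generate_volumes(fixture_params())


def fixture_benchmark(out_dir: str | Path):
    """Write the standard benchmark to ``out_dir`` (PNG slices + manifest)
    with its canonical 15/5 subject-level train/test split."""
    return generate_dataset(fixture_params(), out_dir, train_subjects=15)
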