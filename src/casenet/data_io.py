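"""Image/mask I/O, intensity normalization, splits, folds and augmentation.

Slices are (row, col) 2D arrays; masks are binary with 1 = fetal foreground.
Volumes are NIfTI files (slice axis last) or paired directories of grayscale
PNGs. Splitting and cross-validation operate on *patient identifiers only*,
so slice-level leakage between partitions is impossible by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage.transform import AffineTransform, warp
from sklearn.model_selection import KFold

__all__ = [
    "SliceSample",
    "DatasetSplit",
    "AugmentationSpec",
    "load_volume",
    "save_volume",
    "normalize_intensity",
    "split_patients",
    "make_folds",
    "augment",
]

NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass
class SliceSample:
    """One 2D grayscale slice with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    slice_index: int
    gestational_age: float | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ"
            )
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask must be binary 0/1, found values {vals[:5]}")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class DatasetSplit:
    """Patient-level train/val/test partition."""

    train: list[str]
    val: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int | None = None

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise ValueError(f"patients in two partitions: {sorted(overlap)}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train": list(self.train),
                "val": list(self.val),
                "test": list(self.test),
                "fractions": list(self.fractions),
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetSplit":
        d = json.loads(text)
        return cls(
            d["train"], d["val"], d["test"], tuple(d["fractions"]), d.get("seed")
        )


@dataclass
class AugmentationSpec:
    """Geometric training-time augmentation: the five basic transforms.

    Stretch/zoom entries are multiplicative factor ranges (1.0 = identity),
    shear is in degrees, horizontal_flip is a probability.
    """

    horizontal_stretch_range: tuple[float, float] = (0.9, 1.1)
    vertical_stretch_range: tuple[float, float] = (0.9, 1.1)
    shear_range: tuple[float, float] = (-8.0, 8.0)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    horizontal_flip: float = 0.5

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls((1.0, 1.0), (1.0, 1.0), (0.0, 0.0), (1.0, 1.0), 0.0)


# ---------------------------------------------------------------------------
# loading / saving


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(NIFTI_SUFFIXES)


def _load_stack(path: Path) -> np.ndarray:
    """Return a (n_slices, H, W) float array from a NIfTI file or PNG dir."""
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".pgm")
        )
        if not files:
            raise ValueError(
                f"{path} is a directory with no PNG slices; supported inputs are "
                "NIfTI volumes (.nii/.nii.gz) or directories of grayscale PNGs"
            )
        return np.stack([np.asarray(iio.imread(f), dtype=np.float64) for f in files])
    if _is_nifti(path):
        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if vol.ndim != 3:
            raise ValueError(f"{path} is not a 3D volume (shape {vol.shape})")
        return np.moveaxis(vol, -1, 0)
    raise ValueError(
        f"unsupported format for {path}; supported: NIfTI volume (.nii/.nii.gz) "
        "or a directory of grayscale PNG slices"
    )


def load_volume(image_path, mask_path, patient_id: str | None = None,
                gestational_age: float | None = None) -> list[SliceSample]:
    """Load a paired image/mask volume as per-slice samples.

    Masks are binarized at > 0. Raises if the two volumes disagree in slice
    count or in-plane shape.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = _load_stack(image_path)
    msk = _load_stack(mask_path)
    if img.shape != msk.shape:
        raise ValueError(
            f"shape mismatch between {image_path} {img.shape} and "
            f"{mask_path} {msk.shape}"
        )
    if patient_id is None:
        patient_id = image_path.name.split(".")[0]
    return [
        SliceSample(
            image=img[i].astype(np.float32),
            mask=(msk[i] > 0).astype(np.uint8),
            patient_id=patient_id,
            slice_index=i,
            gestational_age=gestational_age,
        )
        for i in range(img.shape[0])
    ]


def save_volume(stack: np.ndarray, path) -> None:
    """Write a (n_slices, H, W) stack as NIfTI (slice axis last)."""
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"{path} must end in .nii or .nii.gz")
    vol = np.moveaxis(np.asarray(stack), 0, -1)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# normalization


def normalize_intensity(image: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Rescale intensities to a common range across acquisitions.

    ``minmax`` (default) maps to [0, 1]; a constant image maps to zeros.
    ``zscore`` standardizes to zero mean / unit variance.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if method == "minmax":
        lo, hi = image.min(), image.max()
        if hi == lo:
            return np.zeros_like(image)
        return (image - lo) / (hi - lo)
    if method == "zscore":
        sd = image.std()
        return (image - image.mean()) / sd if sd > 0 else np.zeros_like(image)
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# splits and folds


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [math.floor(r) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def split_patients(
    patient_ids,
    fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
    gestational_ages: dict | None = None,
) -> DatasetSplit:
    """Seeded patient-level 60/20/20 (by default) partition.

    If ``gestational_ages`` (patient_id -> weeks) is given, patients are
    stratified by age tertile so each partition spans the age range.
    """
    patient_ids = list(patient_ids)
    if len(patient_ids) < 5:
        raise ValueError(f"need at least 5 patients, got {len(patient_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(len(patient_ids), fractions)
    parts: list[list[str]] = [[], [], []]

    if gestational_ages:
        # age-ordered sequence, shuffled within tertiles, then dealt to the
        # partition with the largest remaining quota relative to its fraction,
        # so each partition samples the whole age range at exact global counts
        order = sorted(patient_ids, key=lambda p: (gestational_ages[p], p))
        n = len(order)
        shuffled = []
        for stratum in (order[: n // 3], order[n // 3 : 2 * n // 3], order[2 * n // 3 :]):
            stratum = list(stratum)
            rng.shuffle(stratum)
            shuffled.extend(stratum)
        remaining = list(counts)
        for pid in shuffled:
            j = int(np.argmax([r / f if f > 0 else -1 for r, f in zip(remaining, fractions)]))
            parts[j].append(pid)
            remaining[j] -= 1
    else:
        shuffled = list(patient_ids)
        rng.shuffle(shuffled)
        i = 0
        for part, c in zip(parts, counts):
            part.extend(shuffled[i : i + c])
            i += c
    return DatasetSplit(parts[0], parts[1], parts[2], tuple(fractions), seed)


def make_folds(train_patient_ids, k: int = 5, seed: int = 0):
    """k-fold CV at patient level: list of (fit_ids, holdout_ids) pairs."""
    ids = np.asarray(list(train_patient_ids))
    if len(ids) < k:
        raise ValueError(f"{len(ids)} patients cannot form {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (list(ids[fit_idx]), list(ids[hold_idx])) for fit_idx, hold_idx in kf.split(ids)
    ]


# ---------------------------------------------------------------------------
# augmentation


def _sample_transform(spec: AugmentationSpec, rng):
    sx = rng.uniform(*spec.horizontal_stretch_range)
    sy = rng.uniform(*spec.vertical_stretch_range)
    shear = rng.uniform(*spec.shear_range)
    zoom = rng.uniform(*spec.zoom_range)
    flip = rng.random() < spec.horizontal_flip
    return sx, sy, shear, zoom, flip


def _affine_about_center(shape, sx, sy, shear_deg, zoom):
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    t = AffineTransform(scale=(sx * zoom, sy * zoom), shear=np.deg2rad(shear_deg))
    shift = AffineTransform(translation=(-cx, -cy))
    unshift = AffineTransform(translation=(cx, cy))
    return shift + t + unshift  # "+" applies the left transform first


def augment(
    sample: SliceSample, spec: AugmentationSpec, rng, image_order: int = 1
) -> SliceSample:
    """Apply one sampled geometric transform identically to image and mask.

    The image is warped with bilinear interpolation (``image_order=1``; pass 0
    for nearest-neighbour), the mask always with nearest-neighbour, so the
    mask stays exactly binary. Output shape is unchanged (the warp resamples
    onto the original grid). ``rng`` is a ``numpy.random.Generator``.
    """
    sx, sy, shear, zoom, flip = _sample_transform(spec, rng)
    img, msk = sample.image, sample.mask
    if (sx, sy, shear, zoom) != (1.0, 1.0, 0.0, 1.0):
        tform = _affine_about_center(img.shape, sx, sy, shear, zoom)
        # warp pulls output pixels from tform.inverse-mapped input locations
        img = warp(
            img.astype(np.float64), tform.inverse, order=image_order,
            preserve_range=True,
        ).astype(np.float32)
        msk = (
            warp(msk.astype(np.float64), tform.inverse, order=0, preserve_range=True)
            > 0.5
        ).astype(np.uint8)
    if flip:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    return replace(sample, image=img, mask=msk)
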