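"""Preprocessing, augmentation and leakage-free patient-level stratified CV.

All slices of one patient land in exactly one fold (MRI slices of a volume
are strongly correlated, so slice-level splitting leaks information between
train and test).  Stratification is at patient level per class: a seeded
per-class shuffle followed by a round-robin deal keeps per-fold class counts
within one patient of proportional.  Augmentation runs only on training-split
records; the driver enforces this and the fold splits are disjoint by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform
from skimage.filters import gaussian

__all__ = [
    "SliceRecord", "FoldAssignment", "AugmentationConfig", "ProtocolViolationError",
    "preprocess", "assign_patient_folds", "build_fold_splits", "augment",
]


class ProtocolViolationError(RuntimeError):
    """Raised when augmentation is requested for a non-training record."""


@dataclass
class SliceRecord:
    image_id: str
    patient_id: str
    label: object
    pixels: np.ndarray  # 2-D grayscale

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("slice pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels.astype(np.float64))):
            raise ValueError("slice pixels must be finite")


@dataclass
class FoldAssignment:
    patient_to_fold: dict
    n_folds: int
    seed: int

    def fold_of(self, patient_id) -> int:
        return self.patient_to_fold[patient_id]


@dataclass
class AugmentationConfig:
    """Per-transform probabilities and magnitudes applied to training slices."""
    crop_prob: float = 0.5
    crop_area: float = 0.9             # cropped fraction of each dimension
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    brightness_contrast_prob: float = 0.2
    brightness_delta: float = 0.2      # fraction of full range
    contrast_delta: float = 0.2
    rotation_prob: float = 0.5
    rotation_deg: float = 50.0
    blur_prob: float = 0.2
    blur_sigma: float = 1.0
    affine_prob: float = 0.5
    affine_shift: float = 0.0625       # fraction of image dimensions
    affine_scale: float = 0.10         # up to +/- 10 %
    affine_deg: float = 45.0

    def __post_init__(self):
        for name in ("crop_prob", "hflip_prob", "vflip_prob",
                     "brightness_contrast_prob", "rotation_prob", "blur_prob",
                     "affine_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(crop_prob=0, hflip_prob=0, vflip_prob=0,
                   brightness_contrast_prob=0, rotation_prob=0, blur_prob=0,
                   affine_prob=0)

    @classmethod
    def flips_only(cls) -> "AugmentationConfig":
        cfg = cls.disabled()
        cfg.hflip_prob = 0.5
        cfg.vflip_prob = 0.5
        return cfg


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Resize (bilinear), min-max scale to [0, 255], store as uint8.

    A constant image has no range to stretch; it maps to all zeros with a
    warning.  The returned array is uint8; callers feeding the network divide
    by 255 (see :func:`to_network_input`).  Applying ``preprocess`` to its own
    output changes nothing.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if img.shape != (target_size, target_size):
        img = sktransform.resize(img, (target_size, target_size), order=1,
                                 mode="edge", anti_aliasing=False,
                                 preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image in preprocess; mapping to zeros", stacklevel=2)
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.floor(scaled).astype(np.uint8)


def to_network_input(u8: np.ndarray) -> np.ndarray:
    """uint8 image -> float array in [0, 1] for the backbone."""
    return np.asarray(u8, dtype=np.float64) / 255.0


# ---------------------------------------------------------------------------
# folds and splits
# ---------------------------------------------------------------------------

def assign_patient_folds(records, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified patient-level fold assignment: per-class seeded shuffle then
    round-robin deal, so per-fold class counts are within one patient of
    proportional and the assignment is reproducible from the seed."""
    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.label, set()).add(rec.patient_id)
    for label, patients in by_class.items():
        if len(patients) < k:
            raise ValueError(
                f"class {label!r} has only {len(patients)} patients; "
                f"needs at least {k} for {k}-fold patient-level CV")
    rng = np.random.default_rng(seed)
    mapping: dict = {}
    for label in sorted(by_class, key=str):
        patients = sorted(by_class[label], key=str)
        rng.shuffle(patients)
        for i, pid in enumerate(patients):
            mapping[pid] = i % k
    return FoldAssignment(mapping, k, seed)


def build_fold_splits(records, assignment: FoldAssignment, fold: int,
                      validation_folds: int = 1):
    """(train, validation, test) record lists for one fold.

    Test = the held-out fold's slices.  Validation = the next
    ``validation_folds`` fold(s) cyclically after it; train = the rest.  Every
    patient appears in exactly one of the three splits.
    """
    k = assignment.n_folds
    if not 0 <= fold < k:
        raise ValueError(f"fold must be in [0, {k})")
    val_folds = {(fold + 1 + i) % k for i in range(validation_folds)}
    if fold in val_folds or len(val_folds) >= k - 1:
        raise ValueError("validation folds must leave at least one training fold")
    train, val, test = [], [], []
    for rec in records:
        f = assignment.fold_of(rec.patient_id)
        if f == fold:
            test.append(rec)
        elif f in val_folds:
            val.append(rec)
        else:
            train.append(rec)
    return train, val, test


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _warp(img: np.ndarray, tform) -> np.ndarray:
    return sktransform.warp(img, tform, order=1, mode="constant", cval=0.0,
                            preserve_range=True)


def augment(image: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator, *, is_training: bool = True) -> np.ndarray:
    """Apply each configured transform independently with its probability.

    Deterministic for a fixed generator state.  The pipeline driver only ever
    calls this on training-split records; calling it with
    ``is_training=False`` raises :class:`ProtocolViolationError`.
    Returns a float image on the input's intensity scale.
    """
    if not is_training:
        raise ProtocolViolationError("augmentation requested for a non-training record")
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    scale_max = 255.0 if img.max() > 1.5 else 1.0

    if rng.random() < cfg.crop_prob:
        ch, cw = max(1, round(h * cfg.crop_area)), max(1, round(w * cfg.crop_area))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        img = sktransform.resize(img[top:top + ch, left:left + cw], (h, w), order=1,
                                 mode="edge", anti_aliasing=False, preserve_range=True)
    if rng.random() < cfg.hflip_prob:
        img = img[:, ::-1].copy()
    if rng.random() < cfg.vflip_prob:
        img = img[::-1, :].copy()
    if rng.random() < cfg.brightness_contrast_prob:
        brightness = rng.uniform(-cfg.brightness_delta, cfg.brightness_delta) * scale_max
        contrast = 1.0 + rng.uniform(-cfg.contrast_delta, cfg.contrast_delta)
        img = np.clip((img - img.mean()) * contrast + img.mean() + brightness,
                      0.0, scale_max)
    if rng.random() < cfg.rotation_prob:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = sktransform.rotate(img, angle, order=1, mode="constant", cval=0.0,
                                 preserve_range=True)
    if rng.random() < cfg.blur_prob:
        img = gaussian(img, sigma=cfg.blur_sigma, preserve_range=True)
    if rng.random() < cfg.affine_prob:
        shift = rng.uniform(-cfg.affine_shift, cfg.affine_shift, size=2) * (h, w)
        scale = 1.0 + rng.uniform(-cfg.affine_scale, cfg.affine_scale)
        angle = np.deg2rad(rng.uniform(-cfg.affine_deg, cfg.affine_deg))
        center = np.array([w, h]) / 2.0 - 0.5
        tform = (sktransform.AffineTransform(translation=center)
                 + sktransform.AffineTransform(rotation=angle, scale=scale)
                 + sktransform.AffineTransform(translation=-center + shift[::-1]))
        img = _warp(img, tform.inverse)
    return img
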