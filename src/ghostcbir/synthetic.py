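"""Deterministic synthetic fixtures: toy MRI-like slice datasets with patient
structure, and class-structured embedding galleries.

The image generator emulates the structure of a curated T1-CE brain-MRI slice
collection at desk scale: three tumor classes with stereotyped lesion
morphology, patients owning several correlated slices (one lesion per
patient, jittered between slices), and a noisy elliptical "head" background.

* class 0 (glioma-like): large irregular bright blob anywhere in the head;
* class 1 (meningioma-like): round rim-enhanced blob near the convexity
  (upper cortical border);
* class 2 (pituitary-like): small midline blob near the sella (center-low).

The embedding generator produces vectors = class mean + patient offset +
item noise, with queries drawn from held-out synthetic patients, so retrieval
behaviour can be studied as a function of class-mean separation without
training anything.  All randomness flows through one seeded generator per
call; identical specs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import SliceRecord
from .retrieval import EmbeddingGallery, build_gallery

__all__ = [
    "SyntheticDatasetSpec", "SyntheticEmbeddingSpec",
    "gen_synthetic_mri", "gen_embedding_gallery",
]

CLASS_NAMES = ("glioma", "meningioma", "pituitary")


@dataclass
class SyntheticDatasetSpec:
    patients_per_class: int = 6
    slices_per_patient: int = 6
    image_size: int = 48
    noise_sd: float = 8.0
    lesion_intensity: float = 200.0
    background_intensity: float = 90.0
    seed: int = 0

    def __post_init__(self):
        if min(self.patients_per_class, self.slices_per_patient, self.image_size) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class SyntheticEmbeddingSpec:
    n_classes: int = 3
    patients_per_class: int = 8
    slices_per_patient: int = 6
    dim: int = 960
    separation: float = 4.0      # class-mean distance scale
    patient_sd: float = 0.5      # shared per-patient offset (inter-slice correlation)
    noise_sd: float = 1.0        # per-slice noise
    query_patients_per_class: int = 2  # held out for queries
    seed: int = 0

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dimension must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.query_patients_per_class >= self.patients_per_class:
            raise ValueError("need at least one gallery patient per class")


# ---------------------------------------------------------------------------
# image fixtures
# ---------------------------------------------------------------------------

def _head_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2
    return ((yy - cy) ** 2 / (0.45 * size) ** 2
            + (xx - cx) ** 2 / (0.38 * size) ** 2) <= 1.0


def _blob(size, cy, cx, ry, rx, angle_wobble, rng) -> np.ndarray:
    """Soft elliptical blob mask in [0, 1] with optional angular irregularity."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    wobble = 1.0
    if angle_wobble > 0:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.3, 1.0, size=3) * angle_wobble
        wobble = 1.0 + sum(a * np.sin((k + 2) * theta + p)
                           for k, (a, p) in enumerate(zip(amps, phases)))
    r2 = (dy / ry) ** 2 + (dx / rx) ** 2
    return np.clip(1.2 * wobble - r2, 0.0, 1.0).clip(0, 1)


def _lesion_params(class_id: int, size: int, rng: np.random.Generator) -> dict:
    s = size
    if class_id == 0:    # large irregular blob, free position
        return dict(cy=rng.uniform(0.35, 0.65) * s, cx=rng.uniform(0.35, 0.65) * s,
                    ry=rng.uniform(0.16, 0.22) * s, rx=rng.uniform(0.16, 0.22) * s,
                    wobble=0.35, rim=0.0)
    if class_id == 1:    # round rim-enhanced blob near the convexity
        return dict(cy=rng.uniform(0.18, 0.30) * s, cx=rng.uniform(0.38, 0.62) * s,
                    ry=rng.uniform(0.10, 0.14) * s, rx=rng.uniform(0.10, 0.14) * s,
                    wobble=0.0, rim=1.0)
    # small midline blob, center-low
    return dict(cy=rng.uniform(0.55, 0.68) * s, cx=rng.uniform(0.47, 0.53) * s,
                ry=rng.uniform(0.05, 0.08) * s, rx=rng.uniform(0.05, 0.08) * s,
                wobble=0.0, rim=0.0)


def _render_slice(params: dict, spec: SyntheticDatasetSpec,
                  rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    head = _head_mask(s)
    img = np.where(head, spec.background_intensity, 0.0)
    # per-slice jitter of the patient's lesion
    jit = 0.02 * s
    cy = params["cy"] + rng.normal(0, jit)
    cx = params["cx"] + rng.normal(0, jit)
    ry = params["ry"] * (1 + rng.normal(0, 0.05))
    rx = params["rx"] * (1 + rng.normal(0, 0.05))
    core = _blob(s, cy, cx, ry, rx, params["wobble"], rng)
    lesion = core * (spec.lesion_intensity - spec.background_intensity)
    if params["rim"] > 0:
        ring = _blob(s, cy, cx, ry * 1.35, rx * 1.35, 0.0, rng) - core
        lesion = lesion * 0.55 + np.clip(ring, 0, 1) * (
            spec.lesion_intensity - spec.background_intensity) * params["rim"]
    img = img + np.where(head, lesion, 0.0)
    img = img + rng.normal(0, spec.noise_sd, size=img.shape) * head
    if params["rim"] > 0:
        mask = (_blob(s, cy, cx, ry * 1.35, rx * 1.35, 0.0, rng) > 0.3) & head
    else:
        mask = (core > 0.3) & head
    return np.clip(img, 0, 255).astype(np.uint8), mask


def gen_synthetic_mri(spec: SyntheticDatasetSpec, return_masks: bool = False):
    """Generate labelled slice records with patient structure (class-stereotyped
    lesion per patient, jittered across that patient's slices).

    With ``return_masks=True`` also returns the boolean lesion mask of each
    slice, aligned with the record list.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SliceRecord] = []
    masks: list[np.ndarray] = []
    for class_id, class_name in enumerate(CLASS_NAMES):
        for p in range(spec.patients_per_class):
            pid = f"{class_name[:3]}_p{p:02d}"
            params = _lesion_params(class_id, spec.image_size, rng)
            for sl in range(spec.slices_per_patient):
                pixels, mask = _render_slice(params, spec, rng)
                masks.append(mask)
                records.append(SliceRecord(
                    image_id=f"{pid}_s{sl:02d}",
                    patient_id=pid,
                    label=class_name,
                    pixels=pixels,
                ))
    return (records, masks) if return_masks else records


# ---------------------------------------------------------------------------
# embedding fixtures
# ---------------------------------------------------------------------------

def gen_embedding_gallery(spec: SyntheticEmbeddingSpec):
    """Class-structured embeddings split into a gallery and held-out queries.

    Returns ``(gallery, query_embeddings, query_labels, query_patient_ids)``.
    Vectors are class mean (random unit direction scaled by ``separation``)
    + a per-patient offset + per-slice noise; query patients never appear in
    the gallery.
    """
    rng = np.random.default_rng(spec.seed)
    means = rng.normal(size=(spec.n_classes, spec.dim))
    means /= np.linalg.norm(means, axis=1, keepdims=True)
    means *= spec.separation
    gal_emb, gal_labels, gal_pids = [], [], []
    q_emb, q_labels, q_pids = [], [], []
    for c in range(spec.n_classes):
        for p in range(spec.patients_per_class):
            pid = f"c{c}_p{p:02d}"
            offset = rng.normal(0, spec.patient_sd, size=spec.dim)
            is_query = p >= spec.patients_per_class - spec.query_patients_per_class
            for _ in range(spec.slices_per_patient):
                v = means[c] + offset + rng.normal(0, spec.noise_sd, size=spec.dim)
                if is_query:
                    q_emb.append(v)
                    q_labels.append(c)
                    q_pids.append(pid)
                else:
                    gal_emb.append(v)
                    gal_labels.append(c)
                    gal_pids.append(pid)
    gallery = build_gallery(np.array(gal_emb), np.array(gal_labels), np.array(gal_pids))
    return gallery, np.array(q_emb), np.array(q_labels), np.array(q_pids)
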