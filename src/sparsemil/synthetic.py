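"""Seeded generator of histopathology-like synthetic bags.

Emulates eyepiece-camera H&E images at desk scale: a bright pink tissue
texture inside a circular field of view on a dark surround, with the
texture's spatial frequency jittered to mimic unrecorded magnification
changes.  Positive images carry one or more planted "abnormal" patches —
clusters of dark-purple blobs standing in for hyperchromatic nuclei — and
the per-patch ground truth is recorded, so the MIL axiom (bag label = OR
over patch truths) holds by construction and attention maps can be scored
against known abnormal locations.

This is a deliberately simple stand-in: it reproduces the geometry and the
class structure of the real data, not its stain chemistry, focus blur, or
tissue morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .bags import Bag, ManifestRecord, patient_stratified_split, tile_patches, write_manifest

__all__ = [
    "SyntheticConfig",
    "SyntheticBagTruth",
    "render_field_of_view",
    "generate_bag",
    "generate_bags",
    "generate_dataset",
]

# base tissue and abnormality palettes (8-bit RGB)
_TISSUE_RGB = np.array([231.0, 178.0, 203.0])     # eosin pink
_ABNORMAL_RGB = np.array([72.0, 38.0, 112.0])     # hematoxylin dark purple


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real acquisition at 1/16 the pixel budget: 774-px
    images tiled into 81 patches of side 86, a positive fraction of 0.747,
    1-4 abnormal patches per positive image, and +/-20% magnification
    jitter.  ``fov_radius_fraction`` is relative to the image side; 0.5
    means the tissue disc spans the full cropped square, as in the real
    images.
    """

    image_side: int = 774
    patch_side: int = 86
    n_patients: int = 40
    images_per_patient: tuple = (2, 4)
    positive_fraction: float = 0.747
    abnormal_patches_per_positive: tuple = (1, 4)
    magnification_jitter: tuple = (0.8, 1.2)
    fov_radius_fraction: float = 0.5
    noise_sd: float = 8.0
    texture_cell_px: float = 12.0
    texture_amplitude: float = 14.0
    split_fractions: tuple = (0.64, 0.09, 0.27)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0.0 < self.fov_radius_fraction <= 0.71:
            raise ValueError("fov_radius_fraction must be in (0, 0.71]")


@dataclass
class SyntheticBagTruth:
    """A generated image, its bag label, and the per-patch ground truth."""

    image: np.ndarray            # side x side x 3 uint8
    label: int
    patch_truth: np.ndarray      # grid of 0/1, rows x cols
    patient_id: str = ""

    def __post_init__(self):
        assert self.label == int(self.patch_truth.any()), "MIL axiom violated"


def render_field_of_view(image: np.ndarray, radius_fraction: float) -> np.ndarray:
    """Black out (intensity 2) everything outside the centred disc."""
    if not 0.0 < radius_fraction <= 0.71:
        raise ValueError("radius_fraction must be in (0, 0.71]")
    h, w = image.shape[:2]
    yy, xx = np.ogrid[:h, :w]
    r = radius_fraction * min(h, w)
    outside = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2 > r * r
    out = image.copy()
    out[outside] = 2
    return out


def _tissue_texture(side: int, scale: float, cfg: SyntheticConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Smooth noise field whose spatial frequency tracks the magnification."""
    cell = max(2.0, cfg.texture_cell_px * scale)
    coarse_n = max(2, int(np.ceil(side / cell)) + 1)
    coarse = rng.normal(0.0, 1.0, size=(coarse_n, coarse_n))
    zoom = side / coarse_n
    return ndimage.zoom(coarse, zoom, order=1)[:side, :side]


def _stamp_abnormal_cell(cell_img: np.ndarray, rng: np.random.Generator) -> None:
    """Fill one patch-sized region with a dense cluster of dark nuclei blobs."""
    ps = cell_img.shape[0]
    n_blobs = rng.integers(25, 46)
    yy, xx = np.ogrid[:ps, :ps]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.1 * ps, 0.9 * ps, size=2)
        radius = rng.uniform(0.055 * ps, 0.095 * ps)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
        color = _ABNORMAL_RGB + rng.normal(0.0, 8.0, size=3)
        cell_img[blob] = 0.85 * color + 0.15 * cell_img[blob]


def generate_bag(label: int, config: SyntheticConfig,
                 rng: np.random.Generator) -> SyntheticBagTruth:
    """Render one synthetic image with ``label`` and its per-patch truth."""
    side, ps = config.image_side, config.patch_side
    n = side // ps
    if n < 1:
        raise ValueError("patch_side exceeds image_side")
    scale = rng.uniform(*config.magnification_jitter)
    tex = _tissue_texture(side, scale, config, rng)
    img = (_TISSUE_RGB[None, None, :]
           + config.texture_amplitude * tex[:, :, None]
           + rng.normal(0.0, config.noise_sd, size=(side, side, 3)))

    truth = np.zeros((n, n), dtype=np.int8)
    if label:
        lo, hi = config.abnormal_patches_per_positive
        k = int(rng.integers(lo, hi + 1))
        cells = _cells_inside_fov(config)
        if k > len(cells):
            raise ValueError(
                f"{k} abnormal patches requested but only {len(cells)} grid "
                f"cells lie inside the field of view")
        chosen = rng.choice(len(cells), size=k, replace=False)
        for ci in chosen:
            r, c = cells[ci]
            _stamp_abnormal_cell(img[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps], rng)
            truth[r, c] = 1

    img = np.clip(img, 0, 255).astype(np.uint8)
    img = render_field_of_view(img, config.fov_radius_fraction)
    return SyntheticBagTruth(image=img, label=int(label), patch_truth=truth)


def _cells_inside_fov(config: SyntheticConfig) -> list:
    """Grid cells whose centre sits safely inside the tissue disc."""
    side, ps = config.image_side, config.patch_side
    n = side // ps
    r = config.fov_radius_fraction * side
    centre = (side - 1) / 2
    cells = []
    for i in range(n):
        for j in range(n):
            cy, cx = (i + 0.5) * ps, (j + 0.5) * ps
            if (cy - centre) ** 2 + (cx - centre) ** 2 <= (r - 0.75 * ps) ** 2:
                cells.append((i, j))
    return cells


def _labels_by_count(n_images: int, positive_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Exactly round(n * fraction) positives, in seeded random order."""
    n_pos = int(round(n_images * positive_fraction))
    labels = np.zeros(n_images, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    return labels


def _plan_cohort(config: SyntheticConfig, rng: np.random.Generator,
                 n_images: int | None = None):
    """Patient ids and labels for the cohort; labels fixed by count rounding."""
    lo, hi = config.images_per_patient
    counts = rng.integers(lo, hi + 1, size=config.n_patients)
    if n_images is not None:  # trim/extend to an exact total when requested
        while counts.sum() < n_images:
            counts[rng.integers(0, config.n_patients)] += 1
        while counts.sum() > n_images:
            i = int(rng.integers(0, config.n_patients))
            if counts[i] > 1:
                counts[i] -= 1
    patient_of = np.repeat(np.arange(config.n_patients), counts)
    labels = _labels_by_count(len(patient_of), config.positive_fraction, rng)
    return patient_of, labels


def generate_bags(config: SyntheticConfig, n_images: int | None = None):
    """In-memory cohort: (bags, truths) with patient ids, no files written.

    Returns a list of :class:`~sparsemil.bags.Bag` (already tiled at the
    configured patch side) and the matching list of
    :class:`SyntheticBagTruth`.
    """
    rng = np.random.default_rng(config.seed)
    patient_of, labels = _plan_cohort(config, rng, n_images)
    bags, truths = [], []
    for i, (pat, lab) in enumerate(zip(patient_of, labels)):
        truth = generate_bag(int(lab), config, rng)
        truth.patient_id = f"P{pat:04d}"
        bag = tile_patches(truth.image, config.patch_side,
                           label=int(lab), patient_id=truth.patient_id)
        bags.append(bag)
        truths.append(truth)
    return bags, truths


def generate_dataset(config: SyntheticConfig, out_dir,
                     n_images: int | None = None) -> list[ManifestRecord]:
    """Write a full synthetic dataset: PNGs, manifest CSV, per-patch truth CSV.

    Splits are assigned patient-wise via :func:`patient_stratified_split`.
    Returns the manifest records.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    patient_of, labels = _plan_cohort(config, rng, n_images)
    records, truth_rows = [], []
    for i, (pat, lab) in enumerate(zip(patient_of, labels)):
        truth = generate_bag(int(lab), config, rng)
        rel = f"images/img_{i:04d}.png"
        Image.fromarray(truth.image).save(out_dir / rel)
        records.append(ManifestRecord(path=rel, label=int(lab),
                                      patient_id=f"P{pat:04d}"))
        n = truth.patch_truth.shape[0]
        for r in range(n):
            for c in range(n):
                truth_rows.append((rel, r, c, int(truth.patch_truth[r, c])))
    records = patient_stratified_split(records, config.split_fractions,
                                       seed=config.seed)
    write_manifest(records, out_dir / "manifest.csv")
    pd.DataFrame(truth_rows, columns=["path", "patch_row", "patch_col", "truth"]) \
        .to_csv(out_dir / "truth.csv", index=False)
    return records
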