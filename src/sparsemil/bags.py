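"""Bag construction: field-of-view cropping, patch tiling, manifests, splits.

A microscopy image shot through an eyepiece shows a bright circular tissue
field on a dark surround.  The pipeline crops the image to a square centred
on the bright region, tiles the square into equal non-overlapping patches
(the MIL instances), and tracks image-level labels and patient identity in
a CSV manifest so that train/val/test splits never share a patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Bag",
    "ManifestRecord",
    "NoTissueError",
    "ManifestError",
    "crop_field_of_view",
    "tile_patches",
    "assemble_patches",
    "read_manifest",
    "write_manifest",
    "patient_stratified_split",
]

SPLITS = ("train", "val", "test")
_LABEL_TOKENS = {"0": 0, "1": 1, "normal": 0, "abnormal": 1}


class NoTissueError(ValueError):
    """No pixel rises above the tissue threshold."""


class ManifestError(ValueError):
    """A manifest row violates the schema; the message carries row numbers."""


@dataclass
class Bag:
    """One image decomposed into L equal non-overlapping patch instances."""

    patches: np.ndarray          # L x ps x ps x 3
    label: int
    patient_id: str = ""
    grid_shape: tuple = (0, 0)

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows * cols and rows * cols != self.patches.shape[0]:
            raise ValueError("grid_shape inconsistent with number of patches")


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int
    patient_id: str
    split: str = ""


def crop_field_of_view(image: np.ndarray, threshold_fraction: float = 0.1) -> np.ndarray:
    """Square crop centred on the bright circular tissue field.

    Pixels whose grayscale intensity exceeds ``threshold_fraction`` of the
    maximum are declared tissue; the largest connected bright component's
    centroid becomes the crop centre, and the crop side is ``min(H, W)``
    clamped to the image bounds.  Idempotent on its own output.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    gray = image.mean(axis=2) if image.ndim == 3 else image.astype(float)
    mask = gray > threshold_fraction * gray.max()
    if not mask.any():
        raise NoTissueError("no pixel above the tissue intensity threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    cy, cx = ndimage.center_of_mass(mask)
    side = min(h, w)
    r0 = int(np.clip(round(cy - side / 2), 0, h - side))
    c0 = int(np.clip(round(cx - side / 2), 0, w - side))
    return image[r0:r0 + side, c0:c0 + side]


def tile_patches(image: np.ndarray, patch_side: int, label: int = 0,
                 patient_id: str = "") -> Bag:
    """Tile a square image into all non-overlapping ``patch_side`` squares.

    Patches are read row-major from the top-left corner; a remainder strip
    (when the side is not a multiple of ``patch_side``) is discarded.
    """
    image = np.asarray(image)
    side = min(image.shape[:2])
    if patch_side > side:
        raise ValueError(f"patch_side {patch_side} exceeds image side {side}")
    n = side // patch_side
    x = image[:n * patch_side, :n * patch_side]
    patches = (x.reshape(n, patch_side, n, patch_side, -1)
               .swapaxes(1, 2)
               .reshape(n * n, patch_side, patch_side, -1))
    return Bag(patches=patches, label=label, patient_id=patient_id, grid_shape=(n, n))


def assemble_patches(bag: Bag) -> np.ndarray:
    """Reassemble a bag's patches in grid order into the tiled image region."""
    rows, cols = bag.grid_shape
    ps = bag.patches.shape[1]
    return (bag.patches.reshape(rows, cols, ps, ps, -1)
            .swapaxes(1, 2)
            .reshape(rows * ps, cols * ps, -1))


# ------------------------------------------------------------------ manifest

def write_manifest(records, path) -> None:
    df = pd.DataFrame([{"path": r.path, "label": r.label,
                        "patient_id": r.patient_id, "split": r.split}
                       for r in records])
    df.to_csv(path, index=False)


def read_manifest(path) -> list[ManifestRecord]:
    """Read and validate a manifest CSV (header: path,label,patient_id,split)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"path", "label", "patient_id", "split"} - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    records, seen_paths, patient_splits = [], {}, {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        token = str(row.label).strip().lower()
        if token not in _LABEL_TOKENS:
            raise ManifestError(f"row {i}: unknown label {row.label!r}")
        if row.path in seen_paths:
            raise ManifestError(
                f"row {i}: duplicate path {row.path!r} (first at row {seen_paths[row.path]})")
        seen_paths[row.path] = i
        split = str(row.split).strip()
        if split and split not in SPLITS:
            raise ManifestError(f"row {i}: unknown split {split!r}")
        pid = str(row.patient_id)
        if split:
            prev = patient_splits.get(pid)
            if prev and prev != split:
                raise ManifestError(
                    f"row {i}: patient {pid!r} appears in both {prev!r} and {split!r}")
            patient_splits[pid] = split
        records.append(ManifestRecord(path=str(row.path), label=_LABEL_TOKENS[token],
                                      patient_id=pid, split=split))
    return records


def patient_stratified_split(records, fractions=(0.64, 0.09, 0.27),
                             seed: int = 0) -> list[ManifestRecord]:
    """Assign train/val/test splits patient-wise, balancing class ratios.

    Patients (never individual images) are dealt greedily, in a seeded
    random order, to the split whose running positive fraction would move
    closest to the global positive fraction, subject to per-split image
    quotas given by ``fractions``.  Deterministic for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != len(SPLITS) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 values summing to 1, got {fractions}")
    patients = {}
    for r in records:
        n, p = patients.get(r.patient_id, (0, 0))
        patients[r.patient_id] = (n + 1, p + r.label)
    if len(patients) < 3:
        raise ValueError(f"need >= 3 patients to split, got {len(patients)}")
    total = len(records)
    global_pos = sum(r.label for r in records) / total
    targets = [f * total for f in fractions]

    rng = np.random.default_rng(seed)
    order = sorted(patients)
    rng.shuffle(order)
    # large patients first: they are hardest to place without skewing ratios
    order.sort(key=lambda pid: -patients[pid][0])

    assigned = {s: (0, 0) for s in SPLITS}   # split -> (n_images, n_pos)
    where = {}
    for pid in order:
        n_p, pos_p = patients[pid]
        open_splits = [s for s, t in zip(SPLITS, targets)
                       if t > 0 and assigned[s][0] < t] or \
                      [s for s, t in zip(SPLITS, targets) if t > 0]
        def cost(s):
            n_s, pos_s = assigned[s]
            frac = (pos_s + pos_p) / (n_s + n_p)
            fill = (n_s + n_p) / max(targets[SPLITS.index(s)], 1e-9)
            # an empty split takes priority so small quotas cannot be starved
            return (n_s > 0, abs(frac - global_pos), fill)
        best = min(open_splits, key=cost)
        n_s, pos_s = assigned[best]
        assigned[best] = (n_s + n_p, pos_s + pos_p)
        where[pid] = best
    for s, t in zip(SPLITS, targets):
        if t > 0 and assigned[s][0] == 0:
            raise ValueError(f"split {s!r} received no images; adjust fractions")
        if t == 0 and fractions[SPLITS.index(s)] == 0:
            raise ValueError("zero fractions would leave a split empty")
    return [ManifestRecord(r.path, r.label, r.patient_id, where[r.patient_id])
            for r in records]
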