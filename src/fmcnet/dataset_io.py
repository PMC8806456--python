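"""Manifest loading, train/validation/test splitting and preprocessing.

The split follows the 80/10/10 protocol: records are shuffled with a seeded
permutation, stratified by label, and per-split counts come from
largest-remainder rounding with ties broken in (train, validation, test)
order, so counts are exact and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "val", "test")


class ManifestFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRecord:
    path: str
    label: int
    split: str | None = None


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if len(self.fractions) != 3 or not all(0 < f < 1 for f in self.fractions):
            raise ValueError(f"each split fraction must lie in (0,1): {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(self.fractions)}")


def load_manifest(path: str | Path) -> list[SampleRecord]:
    """Read a CSV manifest with at least ``path`` and ``label`` columns."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("path", "label"):
        if col not in df.columns:
            raise ManifestFormatError(f"manifest {path} is missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        try:
            label = int(row["label"])
        except (TypeError, ValueError):
            raise ManifestFormatError(
                f"row {i} of {path}: label {row['label']!r} is not an integer") from None
        if label not in (0, 1):
            raise ManifestFormatError(f"row {i} of {path}: label must be 0 or 1, got {label}")
        split = row["split"] if "split" in df.columns and pd.notna(row.get("split")) else None
        records.append(SampleRecord(path=str(row["path"]), label=label, split=split))
    return records


def largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer counts summing to n; ties broken by position order."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    by_frac = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in by_frac[:remainder]:
        counts[i] += 1
    return counts


def make_splits(records: list[SampleRecord], spec: SplitSpec) -> list[SampleRecord]:
    """Assign each record to train/val/test, stratified by label.

    Global per-split counts follow the largest-remainder rounding of the
    fractions over the full record count; within that constraint each
    label's records are apportioned by their own quotas (floors first, then
    remaining units to the splits still short, preferring the largest
    fractional remainder, ties in split order).
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 records to split, got {len(records)}")
    rng = np.random.default_rng(spec.seed)
    global_counts = largest_remainder_counts(len(records), spec.fractions)
    deficits = list(global_counts)

    label_indices = {}
    per_label_counts = {}
    for label in (0, 1):
        idx = [i for i, r in enumerate(records) if r.label == label]
        if not idx:
            continue
        label_indices[label] = idx
        quotas = [len(idx) * f for f in spec.fractions]
        counts = [int(np.floor(q)) for q in quotas]
        per_label_counts[label] = (quotas, counts)
        for s in range(3):
            deficits[s] -= counts[s]
    # distribute each label's leftover units into splits still below target
    for label, (quotas, counts) in per_label_counts.items():
        for _ in range(len(label_indices[label]) - sum(counts)):
            candidates = [s for s in range(3) if deficits[s] > 0]
            s_best = max(candidates, key=lambda s: (quotas[s] - counts[s], -s))
            counts[s_best] += 1
            deficits[s_best] -= 1

    assignment: dict[int, str] = {}
    for label, idx in label_indices.items():
        perm = rng.permutation(len(idx))
        _, counts = per_label_counts[label]
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            for j in perm[start:start + c]:
                assignment[idx[j]] = name
            start += c
    return [SampleRecord(r.path, r.label, assignment[i]) for i, r in enumerate(records)]


def split_counts(records: list[SampleRecord]) -> dict[str, int]:
    out = {name: 0 for name in SPLIT_NAMES}
    for r in records:
        if r.split in out:
            out[r.split] += 1
    return out


def save_manifest(records: list[SampleRecord], path: str | Path):
    pd.DataFrame([{"path": r.path, "label": r.label, "split": r.split}
                  for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image preprocessing

def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG as a float array scaled to [0,1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("I"), dtype=float)
    # 8- or 16-bit input; scale by the nominal maximum
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def preprocess(image: np.ndarray, target_size: int = 227, n_channels: int = 3,
               mean: float | None = None, sd: float | None = None) -> np.ndarray:
    """Resize, standardize and channel-replicate one grayscale image.

    Bilinear resize to ``target_size`` square, standardization by the
    supplied dataset statistics (zero-variance datasets fall back to mean
    centering), then replication to ``n_channels`` channels (HWC).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape != (target_size, target_size):
        img = resize(img, (target_size, target_size), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    if mean is None:
        mean = float(img.mean())
    if sd is None or sd == 0:
        if sd == 0:
            logger.warning("zero-variance standardization stats; falling back to mean centering")
        img = img - mean
    else:
        img = (img - mean) / sd
    return np.repeat(img[:, :, None], n_channels, axis=2)


def dataset_statistics(images: np.ndarray) -> tuple[float, float]:
    """Mean/sd of intensity over a stack of images (training split only)."""
    return float(np.mean(images)), float(np.std(images))


def build_input_tensors(images: np.ndarray, labels: np.ndarray,
                        splits: np.ndarray, target_size: int, n_channels: int = 3
                        ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Preprocess a full image stack into per-split network input tensors.

    Standardization statistics are computed on the training split only and
    applied to all splits, avoiding test-set leakage.
    """
    train_mask = splits == "train"
    if not train_mask.any():
        raise ValueError("no training samples in split assignment")
    mean, sd = dataset_statistics(images[train_mask])
    out = {}
    for name in SPLIT_NAMES:
        m = splits == name
        x = np.stack([preprocess(img, target_size, n_channels, mean, sd)
                      for img in images[m]]) if m.any() else \
            np.empty((0, target_size, target_size, n_channels))
        out[name] = (x, labels[m])
    return out
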