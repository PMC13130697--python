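"""Weak labelling, minority-class augmentation and train/validation splits.

Superpixels are labelled *disease* when at least a configurable fraction
(default 70%) of their area overlaps the expert's rough annotation of the
collagen band; the rule provides reliable labels from coarse region sweeps
without pixel-precise annotation.  Class imbalance is addressed by
oversampling the minority class with bounded uniform noise on the histogram
bins followed by renormalization.  Splits are row-level but parent-aware:
augmented rows always follow their real parent, so near-duplicates never
leak across the train/validation boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_types import LabelConfig, LabeledDataset  # noqa: F401  (re-export)
from .features import FeatureTable
from .io import AnnotationMask, GeometryError
from .segmentation import SuperpixelMap

__all__ = [
    "LabelConfig",
    "LabeledDataset",
    "DISEASE",
    "NORMAL",
    "overlap_fraction",
    "label_superpixels",
    "augment_minority",
    "split",
]

DISEASE = 1
NORMAL = 0


def overlap_fraction(
    spmap: SuperpixelMap, sp_id: int, mask: AnnotationMask
) -> float:
    """Fraction of a superpixel's area inside the annotation mask."""
    if not 0 <= sp_id < spmap.n_superpixels:
        raise ValueError(f"superpixel id {sp_id} out of range")
    if mask.shape != spmap.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match superpixel map "
            f"shape {spmap.shape}"
        )
    sel = spmap.labels == sp_id
    return float(mask.pixels[sel].mean())


def label_superpixels(
    spmap: SuperpixelMap,
    mask: AnnotationMask,
    features: FeatureTable,
    cfg: LabelConfig,
) -> LabeledDataset:
    """Label every non-background superpixel by annotation overlap.

    ``disease`` iff overlap_fraction >= cfg.overlap_threshold, else
    ``normal``; one row per feature-table row.
    """
    if mask.shape != spmap.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match superpixel map "
            f"shape {spmap.shape}"
        )
    frac = spmap.pixel_fraction(mask.pixels)
    labels = np.where(
        frac[features.superpixel_ids] >= cfg.overlap_threshold, DISEASE, NORMAL
    ).astype(np.int8)
    n = features.n_rows
    return LabeledDataset(
        features=features.matrix.copy(),
        labels=labels,
        image_ids=np.array([features.image_id] * n, dtype=object),
        superpixel_ids=features.superpixel_ids.copy(),
        origin=np.array(["real"] * n, dtype=object),
        parent_index=np.full(n, -1, dtype=np.int64),
        bins_per_channel=features.bins_per_channel,
    )


def _renormalize_blocks(matrix: np.ndarray, bins: int) -> np.ndarray:
    out = matrix.reshape(len(matrix), 3, bins)
    sums = out.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    return (out / sums).reshape(len(matrix), 3 * bins)


def _minority_target(n_minority: int, n_majority: int, cfg: LabelConfig) -> int:
    if cfg.minority_target == "match_majority":
        return n_majority
    if cfg.minority_target == "fixed_count":
        return int(cfg.minority_count)
    if cfg.minority_target == "fixed_factor":
        return int(round(n_minority * cfg.minority_factor))
    raise ValueError(f"unknown minority_target {cfg.minority_target!r}")


def augment_minority(ds: LabeledDataset, cfg: LabelConfig) -> LabeledDataset:
    """Oversample the minority class with bounded histogram noise.

    New rows are noisy copies of real minority rows: i.i.d. uniform noise in
    [noise_low, noise_high] per bin, clipped at zero, channel blocks
    renormalized to sum one.  Parents are drawn uniformly with replacement
    (seeded); originals are retained unchanged.
    """
    counts = ds.class_counts()
    n_dis, n_norm = counts[DISEASE], counts[NORMAL]
    if n_dis == 0 or n_norm == 0:
        raise ValueError("augmentation requires both classes present")
    minority = DISEASE if n_dis < n_norm else NORMAL
    n_min = min(n_dis, n_norm)
    target = _minority_target(n_min, max(n_dis, n_norm), cfg)
    if target < n_min:
        raise ValueError(
            f"minority target {target} below current count {n_min}"
        )
    need = target - n_min
    if need == 0:
        return ds
    rng = np.random.default_rng(cfg.rng_seed)
    pool = np.where(ds.labels == minority)[0]
    parents = rng.choice(pool, size=need, replace=True)
    noise = rng.uniform(
        cfg.noise_low, cfg.noise_high, size=(need, ds.features.shape[1])
    )
    new = np.clip(ds.features[parents] + noise, 0.0, None)
    new = _renormalize_blocks(new, ds.bins_per_channel)
    return LabeledDataset(
        features=np.vstack([ds.features, new]),
        labels=np.concatenate(
            [ds.labels, np.full(need, minority, dtype=np.int8)]
        ),
        image_ids=np.concatenate([ds.image_ids, ds.image_ids[parents]]),
        superpixel_ids=np.concatenate(
            [ds.superpixel_ids, ds.superpixel_ids[parents]]
        ),
        origin=np.concatenate(
            [ds.origin, np.array(["augmented"] * need, dtype=object)]
        ),
        parent_index=np.concatenate(
            [ds.parent_index, parents.astype(np.int64)]
        ),
        bins_per_channel=ds.bins_per_channel,
    )


def split(
    ds: LabeledDataset, cfg: LabelConfig
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded uniform row split of the real rows at ``train_fraction``.

    Augmented rows follow their parent into the same subset, so perturbed
    copies of a validation superpixel can never appear in training.
    """
    if ds.n_rows == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(cfg.rng_seed)
    real = np.where(ds.parent_index < 0)[0]
    perm = rng.permutation(len(real))
    n_train = int(round(cfg.train_fraction * len(real)))
    train_real = set(real[perm[:n_train]].tolist())
    in_train = np.zeros(ds.n_rows, dtype=bool)
    for i in range(ds.n_rows):
        p = ds.parent_index[i]
        in_train[i] = (i in train_real) if p < 0 else (p in train_real)
    return ds.subset(np.where(in_train)[0]), ds.subset(np.where(~in_train)[0])
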