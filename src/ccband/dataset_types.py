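"""Container types for labelled superpixel datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabelConfig", "LabeledDataset"]


@dataclass
class LabelConfig:
    """Labelling, augmentation and split parameters.

    overlap_threshold
        Minimum annotation-overlap fraction for the *disease* label (0.70).
    minority_target
        Balancing policy: ``match_majority`` (default), ``fixed_count``
        (uses ``minority_count``) or ``fixed_factor`` (``minority_factor``
        times the current minority count).
    noise_low, noise_high
        Bounds of the uniform per-bin augmentation noise (-0.15, +0.15).
    train_fraction
        Fraction of real rows assigned to training (0.80).
    """

    overlap_threshold: float = 0.70
    minority_target: str = "match_majority"
    minority_count: int = 0
    minority_factor: float = 1.0
    noise_low: float = -0.15
    noise_high: float = 0.15
    train_fraction: float = 0.80
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.noise_low >= self.noise_high:
            raise ValueError("noise_low must be < noise_high")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.minority_target not in (
            "match_majority",
            "fixed_count",
            "fixed_factor",
        ):
            raise ValueError(f"unknown minority_target {self.minority_target!r}")


@dataclass
class LabeledDataset:
    """Rows of (features, class, provenance) for classifier training.

    ``labels`` uses 1 for *disease* and 0 for *normal*.  ``origin`` is
    ``"real"`` or ``"augmented"``; augmented rows carry the row index of
    their real parent in ``parent_index`` (-1 for real rows).
    """

    features: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray
    superpixel_ids: np.ndarray
    origin: np.ndarray
    parent_index: np.ndarray
    bins_per_channel: int

    def __post_init__(self) -> None:
        n = len(self.features)
        for name in ("labels", "image_ids", "superpixel_ids", "origin", "parent_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if self.features.ndim != 2 or self.features.shape[1] != 3 * self.bins_per_channel:
            raise ValueError("feature width must equal 3 * bins_per_channel")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[int, int]:
        return {
            1: int((self.labels == 1).sum()),
            0: int((self.labels == 0).sum()),
        }

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row subset; parent indices are remapped (or -1 if parent absent)."""
        indices = np.asarray(indices)
        remap = {int(old): new for new, old in enumerate(indices)}
        parents = np.array(
            [
                remap.get(int(p), -1) if p >= 0 else -1
                for p in self.parent_index[indices]
            ],
            dtype=np.int64,
        )
        return LabeledDataset(
            features=self.features[indices],
            labels=self.labels[indices],
            image_ids=self.image_ids[indices],
            superpixel_ids=self.superpixel_ids[indices],
            origin=self.origin[indices],
            parent_index=parents,
            bins_per_channel=self.bins_per_channel,
        )

    @staticmethod
    def concatenate(parts: list["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        bins = parts[0].bins_per_channel
        if any(p.bins_per_channel != bins for p in parts):
            raise ValueError("bin counts differ between parts")
        offsets = np.cumsum([0] + [p.n_rows for p in parts[:-1]])
        parents = [
            np.where(p.parent_index >= 0, p.parent_index + off, -1)
            for p, off in zip(parts, offsets)
        ]
        return LabeledDataset(
            features=np.vstack([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            image_ids=np.concatenate([p.image_ids for p in parts]),
            superpixel_ids=np.concatenate([p.superpixel_ids for p in parts]),
            origin=np.concatenate([p.origin for p in parts]),
            parent_index=np.concatenate(parents),
            bins_per_channel=bins,
        )

    def to_frame(self) -> pd.DataFrame:
        """Columnar view: image_id, superpixel_id, origin, class, f_0..."""
        data = {
            "image_id": self.image_ids,
            "superpixel_id": self.superpixel_ids,
            "origin": self.origin,
            "class": np.where(self.labels == 1, "disease", "normal"),
        }
        frame = pd.DataFrame(data)
        feats = pd.DataFrame(
            self.features,
            columns=[f"f_{i}" for i in range(self.features.shape[1])],
        )
        return pd.concat([frame, feats], axis=1)
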