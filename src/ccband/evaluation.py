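"""Superpixel metrics, benchmark harnesses and the acceptability proxy.

Superpixel-level performance uses the standard 2x2 confusion counts with
*disease* as the positive class; pooled figures are micro-averages (summed
counts).  Two harnesses mirror the study design:

* ``split_validation`` -- one model trained under a seeded 80/20 row split
  of all superpixels (augmented rows following their parents), scored on
  the real validation rows: the protocol behind classifier-level accuracy /
  sensitivity / specificity figures.
* ``leave_one_out`` -- per image: train on all other images (standardizer
  and augmentation refitted per fold), predict the withheld image, apply
  the connected-component size filter, score.  A structural assertion per
  fold guarantees no test-image row, real or augmented, entered training.

Expert image-level acceptability scoring is replaced by an automated proxy
-- an invented surrogate, not the published human endpoint: a detection is
*acceptable* when the IoU between the final mask and the ground-truth band
reaches a threshold (default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import ClassifierModel, predict, train
from .config import PipelineConfig
from .dataset import LabeledDataset, augment_minority, label_superpixels, split
from .features import FeatureTable, extract_features
from .io import AnnotationMask, GeometryError, RgbImage
from .postprocess import DetectionResult, apply_postprocessing
from .preprocess import ReferenceDistribution, build_reference, preprocess_image
from .segmentation import AdjacencyGraph, SuperpixelMap, region_adjacency, slic_segment
from .synthetic import SyntheticSample

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvalReport",
    "AnnotatedImage",
    "PreparedImage",
    "confusion",
    "metrics",
    "acceptability_proxy",
    "prepare_image",
    "prepare_collection",
    "split_validation",
    "leave_one_out",
]


@dataclass
class ConfusionCounts:
    """2x2 counts with disease as the positive class."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
        )


@dataclass
class MetricSet:
    """Accuracy / sensitivity / specificity; ``None`` where undefined."""

    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def as_dict(self) -> dict[str, Optional[float]]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    """Tally the 2x2 confusion table from 0/1 class vectors."""
    t = np.asarray(truth).astype(np.int64)
    p = np.asarray(predicted).astype(np.int64)
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: {t.shape} truth vs {p.shape} predicted"
        )
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity and specificity; undefined ratios become None."""
    acc = (c.tp + c.tn) / c.total if c.total else None
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    return MetricSet(acc, sens, spec)


def acceptability_proxy(
    pred_mask: AnnotationMask,
    truth_mask: AnnotationMask,
    iou_threshold: float = 0.5,
) -> int:
    """1 iff IoU(prediction, truth) >= threshold; agreement on absence is 1."""
    if pred_mask.shape != truth_mask.shape:
        raise GeometryError(
            f"mask shapes differ: {pred_mask.shape} vs {truth_mask.shape}"
        )
    inter = np.logical_and(pred_mask.pixels, truth_mask.pixels).sum()
    union = np.logical_or(pred_mask.pixels, truth_mask.pixels).sum()
    iou = 1.0 if union == 0 else inter / union
    return int(iou >= iou_threshold)


# ---------------------------------------------------------------------------
# Pipeline plumbing


@dataclass
class AnnotatedImage:
    """An input micrograph with its rough annotation (and optional truth)."""

    image: RgbImage
    annotation: AnnotationMask
    truth: Optional[AnnotationMask] = None

    @classmethod
    def from_sample(cls, sample: SyntheticSample) -> "AnnotatedImage":
        return cls(
            image=sample.image,
            annotation=sample.rough_annotation,
            truth=sample.truth_band_mask,
        )


@dataclass
class PreparedImage:
    """Preprocessed image with its segmentation, features and adjacency."""

    image: RgbImage
    spmap: SuperpixelMap
    features: FeatureTable
    graph: AdjacencyGraph


def _derived_seed(master: int, index: int) -> int:
    state = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(state.generate_state(1)[0] % (2**31))


def prepare_image(
    image: RgbImage,
    cfg: PipelineConfig,
    ref: Optional[ReferenceDistribution],
) -> PreparedImage:
    """Preprocess, segment and featurise one image."""
    aligned = preprocess_image(image, cfg.preprocess, ref)
    spmap = slic_segment(aligned, cfg.slic)
    feats = extract_features(aligned, spmap, cfg.features)
    graph = region_adjacency(spmap, cfg.slic.adjacency_connectivity)
    return PreparedImage(aligned, spmap, feats, graph)


def prepare_collection(
    samples: Sequence[AnnotatedImage], cfg: PipelineConfig
) -> tuple[list[PreparedImage], list[LabeledDataset], ReferenceDistribution]:
    """Preprocess/segment/featurise/label a whole collection.

    The histogram-alignment reference is built from the corrected version of
    the configured reference image (default: lexicographically first image
    id), fixed once for the collection as preprocessing is fixed before any
    training.
    """
    if not samples:
        raise ValueError("empty image collection")
    ids = [s.image.image_id for s in samples]
    ref_id = cfg.preprocess.reference_image_id or sorted(ids)[0]
    try:
        ref_img = samples[ids.index(ref_id)].image
    except ValueError as exc:
        raise ValueError(f"reference image id {ref_id!r} not found") from exc
    ref = build_reference(
        preprocess_image(ref_img, cfg.preprocess, None),
        cfg.preprocess.alignment_quantiles,
    )
    prepared = [prepare_image(s.image, cfg, ref) for s in samples]
    rows = [
        label_superpixels(p.spmap, s.annotation, p.features, cfg.dataset)
        for s, p in zip(samples, prepared)
    ]
    return prepared, rows, ref


def detect(
    prepared: PreparedImage,
    model: ClassifierModel,
    cfg: PipelineConfig,
) -> DetectionResult:
    """Classify one prepared image and apply spatial post-processing.

    Background superpixels are never classified; they enter post-processing
    as *normal*.
    """
    labels, proba = predict(model, prepared.features.matrix)
    full = np.zeros(prepared.spmap.n_superpixels, dtype=np.int8)
    full[prepared.features.superpixel_ids] = labels
    full_p = np.zeros(prepared.spmap.n_superpixels)
    full_p[prepared.features.superpixel_ids] = proba
    return apply_postprocessing(
        full, prepared.spmap, prepared.graph, cfg.postprocess, full_p
    )


# ---------------------------------------------------------------------------
# Harnesses


@dataclass
class EvalReport:
    """Per-image and pooled evaluation results with run provenance."""

    per_image: list[dict]
    pooled_raw: MetricSet
    pooled_filtered: Optional[MetricSet]
    acceptability_mean: Optional[float]
    seed: int
    config_hash: str
    protocol: str

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "pooled_raw": self.pooled_raw.as_dict(),
            "pooled_filtered": (
                self.pooled_filtered.as_dict() if self.pooled_filtered else None
            ),
            "acceptability_mean": self.acceptability_mean,
            "per_image": self.per_image,
        }
        return json.dumps(payload, indent=1)


def split_validation(
    samples: Sequence[AnnotatedImage],
    cfg: PipelineConfig,
    seed: int = 0,
) -> tuple[EvalReport, ClassifierModel]:
    """Train/score one model under the seeded 80/20 superpixel-row split.

    Augmentation balances the classes before the split; augmented rows
    follow their parents, and only real validation rows are scored, so the
    reported metrics describe actual superpixels.
    """
    import dataclasses as _dc

    _, rows, _ = prepare_collection(samples, cfg)
    ds = LabeledDataset.concatenate(rows)
    lbl_cfg = _dc.replace(cfg.dataset, rng_seed=_derived_seed(seed, 0))
    ds = augment_minority(ds, lbl_cfg)
    train_ds, val_ds = split(ds, lbl_cfg)
    net_cfg = _dc.replace(cfg.network, init_seed=_derived_seed(seed, 1))
    model = train(train_ds, net_cfg)
    real = val_ds.parent_index < 0
    pred, _ = predict(model, val_ds.features[real])
    pooled = confusion(val_ds.labels[real], pred)
    report = EvalReport(
        per_image=[],
        pooled_raw=metrics(pooled),
        pooled_filtered=None,
        acceptability_mean=None,
        seed=seed,
        config_hash=cfg.config_hash(),
        protocol="split-80-20",
    )
    return report, model


def leave_one_out(
    samples: Sequence[AnnotatedImage],
    cfg: PipelineConfig,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-image-out evaluation with per-fold isolation.

    Each fold refits augmentation, standardizer and network on the other
    images only; the withheld image is scored after the size filter.  The
    absence of test rows (real or augmented) from training is asserted
    structurally in every fold.
    """
    import dataclasses as _dc

    if len(samples) < 2:
        raise ValueError("leave-one-out needs at least two images")
    for s in samples:
        if s.annotation is None:
            raise ValueError("every image needs an annotation")
    prepared, rows, _ = prepare_collection(samples, cfg)
    per_image: list[dict] = []
    pooled_raw = ConfusionCounts()
    pooled_filt = ConfusionCounts()
    flags: list[int] = []
    for i, (sample, prep) in enumerate(zip(samples, prepared)):
        test_id = sample.image.image_id
        train_rows = LabeledDataset.concatenate(
            [r for j, r in enumerate(rows) if j != i]
        )
        assert test_id not in set(train_rows.image_ids), "fold leakage"
        lbl_cfg = _dc.replace(cfg.dataset, rng_seed=_derived_seed(seed, 100 + i))
        train_aug = augment_minority(train_rows, lbl_cfg)
        aug_parents = train_aug.parent_index[train_aug.parent_index >= 0]
        assert not set(train_aug.image_ids[aug_parents]) & {test_id}
        net_cfg = _dc.replace(cfg.network, init_seed=_derived_seed(seed, 200 + i))
        model = train(train_aug, net_cfg)
        result = detect(prep, model, cfg)
        keep = prep.features.superpixel_ids
        truth_labels = rows[i].labels
        c_raw = confusion(truth_labels, result.raw_prediction[keep])
        c_filt = confusion(truth_labels, result.filtered_prediction[keep])
        pooled_raw += c_raw
        pooled_filt += c_filt
        flag = None
        if sample.truth is not None:
            flag = acceptability_proxy(
                result.mask, sample.truth, cfg.evaluation.iou_threshold
            )
            flags.append(flag)
        per_image.append(
            {
                "image_id": test_id,
                "raw": metrics(c_raw).as_dict(),
                "filtered": metrics(c_filt).as_dict(),
                "n_superpixels": int(prep.spmap.n_superpixels),
                "n_background": int(len(prep.features.background_ids)),
                "n_disease_truth": int(truth_labels.sum()),
                "surviving_components": [
                    len(comp) for comp in result.surviving
                ],
                "acceptable": flag,
            }
        )
    return EvalReport(
        per_image=per_image,
        pooled_raw=metrics(pooled_raw),
        pooled_filtered=metrics(pooled_filt),
        acceptability_mean=(float(np.mean(flags)) if flags else None),
        seed=seed,
        config_hash=cfg.config_hash(),
        protocol="leave-one-out",
    )
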