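"""Top-level Model/Results interface for collagen-band detection.

``CollagenBandModel`` is built from a collection of annotated micrographs
and a pipeline configuration; ``fit()`` runs the full training pipeline
(colour normalization, SLIC segmentation, histogram features, weak
labelling, minority augmentation, 80/20 split, network training) and
returns a ``CollagenBandResults`` carrying the trained classifier, the
alignment reference, validation metrics and per-stage counts.  The results
object predicts on new images, renders overlays, and serialises to a single
JSON bundle; ``leave_one_out()`` runs the image-level evaluation harness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classifier import ClassifierModel, predict as _predict_rows, train as _train
from .config import PipelineConfig
from .dataset import LabeledDataset, augment_minority, split
from .evaluation import (
    AnnotatedImage,
    EvalReport,
    MetricSet,
    _derived_seed,
    confusion,
    detect,
    leave_one_out as _loo,
    metrics,
    prepare_collection,
    prepare_image,
)
from .io import AnnotationMask, RgbImage, read_image, read_mask, write_overlay
from .postprocess import DetectionResult
from .preprocess import ReferenceDistribution
from .synthetic import SyntheticSample

__all__ = ["CollagenBandModel", "CollagenBandResults"]


class CollagenBandModel:
    """Detection model over a collection of annotated micrographs."""

    def __init__(
        self,
        samples: Sequence[AnnotatedImage],
        config: Optional[PipelineConfig] = None,
    ):
        if not samples:
            raise ValueError("need at least one annotated image")
        self.samples = list(samples)
        self.config = config or PipelineConfig()

    @classmethod
    def from_synthetic(
        cls,
        samples: Sequence[SyntheticSample],
        config: Optional[PipelineConfig] = None,
    ) -> "CollagenBandModel":
        return cls([AnnotatedImage.from_sample(s) for s in samples], config)

    @classmethod
    def from_directory(
        cls,
        image_dir: str | Path,
        mask_dir: str | Path,
        config: Optional[PipelineConfig] = None,
    ) -> "CollagenBandModel":
        """Pair images and rough-annotation masks by file stem."""
        config = config or PipelineConfig()
        image_dir, mask_dir = Path(image_dir), Path(mask_dir)
        samples = []
        paths = sorted(
            p
            for p in image_dir.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise FileNotFoundError(f"no images found in {image_dir}")
        for path in paths:
            mask_path = next(
                (
                    mask_dir / f"{path.stem}{ext}"
                    for ext in (".png", ".tif", ".tiff")
                    if (mask_dir / f"{path.stem}{ext}").exists()
                ),
                None,
            )
            if mask_path is None:
                raise FileNotFoundError(f"no mask for image {path.name}")
            image = read_image(path, config.synthetic.pixel_size_um)
            samples.append(
                AnnotatedImage(image, read_mask(mask_path, image))
            )
        return cls(samples, config)

    def fit(self, seed: Optional[int] = None) -> "CollagenBandResults":
        """Train the superpixel classifier under the 80/20 split protocol."""
        seed = self.config.rng_seed if seed is None else int(seed)
        prepared, rows, ref = prepare_collection(self.samples, self.config)
        ds = LabeledDataset.concatenate(rows)
        counts = {
            "images": len(self.samples),
            "superpixels": int(sum(p.spmap.n_superpixels for p in prepared)),
            "background_excluded": int(
                sum(len(p.features.background_ids) for p in prepared)
            ),
            "real_disease": int((ds.labels == 1).sum()),
            "real_normal": int((ds.labels == 0).sum()),
        }
        lbl_cfg = dataclasses.replace(
            self.config.dataset, rng_seed=_derived_seed(seed, 0)
        )
        ds_aug = augment_minority(ds, lbl_cfg)
        counts["augmented"] = int(ds_aug.n_rows - ds.n_rows)
        train_ds, val_ds = split(ds_aug, lbl_cfg)
        counts["train_rows"] = int(train_ds.n_rows)
        counts["validation_rows"] = int(val_ds.n_rows)
        net_cfg = dataclasses.replace(
            self.config.network, init_seed=_derived_seed(seed, 1)
        )
        classifier = _train(train_ds, net_cfg)
        real = val_ds.parent_index < 0
        pred, _ = _predict_rows(classifier, val_ds.features[real])
        val_metrics = metrics(confusion(val_ds.labels[real], pred))
        return CollagenBandResults(
            classifier=classifier,
            reference=ref,
            config=self.config,
            validation=val_metrics,
            counts=counts,
            seed=seed,
        )

    def leave_one_out(self, seed: Optional[int] = None) -> EvalReport:
        """Leave-one-image-out evaluation with strict fold isolation."""
        seed = self.config.rng_seed if seed is None else int(seed)
        return _loo(self.samples, self.config, seed)


@dataclass
class CollagenBandResults:
    """Fitted detector: classifier, alignment reference and diagnostics."""

    classifier: ClassifierModel
    reference: ReferenceDistribution
    config: PipelineConfig
    validation: MetricSet
    counts: dict
    seed: int

    def predict(self, image: RgbImage) -> DetectionResult:
        """Full detection on a new micrograph (preprocess through filter)."""
        prep = prepare_image(image, self.config, self.reference)
        return detect(prep, self.classifier, self.config)

    def predict_overlay(self, image: RgbImage, path: str | Path) -> DetectionResult:
        result = self.predict(image)
        write_overlay(image, result.mask, path)
        return result

    def summary(self) -> str:
        c = self.counts
        v = self.validation
        m = self.classifier

        def fmt(x: Optional[float]) -> str:
            return "undefined" if x is None else f"{x:.4f}"

        lines = [
            "Collagen-band detection model",
            "=" * 64,
            f"images                  {c['images']}",
            f"superpixels             {c['superpixels']} "
            f"({c['background_excluded']} background-excluded)",
            f"labelled rows           {c['real_disease']} disease / "
            f"{c['real_normal']} normal (+{c['augmented']} augmented)",
            f"train / validation      {c['train_rows']} / {c['validation_rows']}",
            "-" * 64,
            f"network                 "
            f"{m.n_features} -> "
            + " -> ".join(str(h) for h in m.config.hidden_sizes)
            + " -> 2 (tanh, softmax)",
            f"optimiser               L-BFGS, {m.n_iterations} iterations, "
            f"final loss {m.final_loss:.5f}",
            "-" * 64,
            f"validation accuracy     {fmt(v.accuracy)}",
            f"validation sensitivity  {fmt(v.sensitivity)}",
            f"validation specificity  {fmt(v.specificity)}",
            f"seed                    {self.seed}",
            f"config hash             {self.config.config_hash()}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "classifier": json.loads(self.classifier.to_json()),
            "reference": {
                "quantiles": self.reference.quantiles.tolist(),
                "source_image_id": self.reference.source_image_id,
            },
            "config": self.config.to_dict(),
            "validation": self.validation.as_dict(),
            "counts": self.counts,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CollagenBandResults":
        d = json.loads(Path(path).read_text())
        return cls(
            classifier=ClassifierModel.from_json(json.dumps(d["classifier"])),
            reference=ReferenceDistribution(
                np.asarray(d["reference"]["quantiles"]),
                d["reference"]["source_image_id"],
            ),
            config=PipelineConfig.from_dict(d["config"]),
            validation=MetricSet(**d["validation"]),
            counts=d["counts"],
            seed=d["seed"],
        )
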