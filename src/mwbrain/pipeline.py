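"""End-to-end cascade: generate -> split -> augment -> train MSegNet ->
superimpose -> train BINet (raw and segmented) -> report.

Superimposition hard-masks an image to the tumor region: pixels where
the mask is 1 keep their value in every channel, everything else is
zeroed, producing the "segmented" input variant for classification. By
default the masks used for superimposition come from the fold's own
trained MSegNet (the deployed cascade); ``use_gt_masks`` switches to
ground-truth masks as an upper bound. Every stochastic stage derives its
seed from the experiment seed, so a re-run with the same configuration
reproduces all output files bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize as _resize

from . import __version__
from .augmentation import AugmentationPolicy, iter_expanded
from .binet import BINet, BINetConfig, classify
from .evaluation import (
    classwise_metrics,
    confusion_matrix,
    fold_statistics,
    plot_confusion,
    segmentation_metrics,
    write_confusion,
)
from .msegnet import MSegNet, MSegNetConfig, segment
from .synthetic_data import LABELS, LabeledSample, PhantomSpec, generate_dataset
from .training import (
    TrainConfig,
    compute_stats,
    make_folds,
    train_model,
    zscore_normalize,
)

__all__ = [
    "ExperimentConfig",
    "superimpose",
    "resize_sample",
    "run_experiment",
]


def superimpose(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep image pixels where mask = 1 (all channels), zero elsewhere."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    return image * mask[..., None].astype(image.dtype)


def resize_sample(sample: LabeledSample, size: int) -> LabeledSample:
    """Resize image (bilinear) and mask (nearest) to size x size."""
    if sample.image.shape[0] == size:
        return sample
    image = _resize(sample.image, (size, size, 3), order=1, preserve_range=True,
                    anti_aliasing=False).astype(np.float32)
    mask = _resize(sample.mask, (size, size), order=0, preserve_range=True,
                   anti_aliasing=False).astype(np.uint8)
    return replace(sample, image=image, mask=mask)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of one cascaded experiment."""

    n_per_class: int = 100
    image_size: int = 256
    cls_input_size: int = 224
    seg_features: int = 32
    q_order: int = 3
    folds: int = 5
    run_folds: tuple[int, ...] | None = None  # 1-based subset; None = all
    use_gt_masks: bool = False
    seed: int = 0
    seg_policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    cls_policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    seg_train: TrainConfig = field(default_factory=TrainConfig.segmentation)
    cls_train: TrainConfig = field(default_factory=TrainConfig.classification)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("seg_policy", "cls_policy"):
            if key in d and isinstance(d[key], dict):
                d[key] = AugmentationPolicy(**{k: tuple(v) if isinstance(v, list) else v
                                               for k, v in d[key].items()})
        for key in ("seg_train", "cls_train"):
            if key in d and isinstance(d[key], dict):
                d[key] = TrainConfig(**d[key])
        if d.get("run_folds") is not None:
            d["run_folds"] = tuple(d["run_folds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seed(seed: int, fold: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{fold}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _normalized(samples: list[LabeledSample], stats) -> list[LabeledSample]:
    return [replace(s, image=zscore_normalize(s.image, stats)) for s in samples]


def _predict_masks(net: MSegNet, samples: list[LabeledSample], stats
                   ) -> list[np.ndarray]:
    return [segment(net, zscore_normalize(s.image, stats)).mask for s in samples]


def _cls_dataset(samples: list[LabeledSample], masks: list[np.ndarray] | None,
                 size: int) -> list[LabeledSample]:
    out = []
    for i, s in enumerate(samples):
        img = s.image if masks is None else superimpose(s.image, masks[i])
        out.append(resize_sample(replace(s, image=img), size))
    return out


def _augmented_list(originals, policy):
    return list(iter_expanded(originals, policy))


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute all stages per fold; returns the report summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phantom = PhantomSpec(image_size=config.image_size)
    dataset = generate_dataset(config.n_per_class, seed=config.seed, spec=phantom)
    folds = make_folds(dataset, k=config.folds, seed=config.seed)
    which = config.run_folds or tuple(f.fold_index for f in folds)

    seg_rows, raw_rows, segd_rows = [], [], []
    for fold in folds:
        if fold.fold_index not in which:
            continue
        fdir = out / f"fold{fold.fold_index}"
        fdir.mkdir(exist_ok=True)
        fit = fold.subset(dataset, "train")
        val = fold.subset(dataset, "validation")
        test = fold.subset(dataset, "test")
        stats = compute_stats(fit)

        # --- segmentation ---
        seg_cfg = replace(config.seg_train,
                          seed=_stage_seed(config.seed, fold.fold_index, "seg"))
        seg_policy = replace(config.seg_policy,
                             seed=_stage_seed(config.seed, fold.fold_index, "seg-aug"))
        aug = _augmented_list(fit, seg_policy)
        segnet = MSegNet(
            MSegNetConfig(initial_features=config.seg_features,
                          input_size=config.image_size),
            rng=np.random.default_rng(
                _stage_seed(config.seed, fold.fold_index, "seg-init")))
        seg_hist = train_model(segnet, _normalized(aug, stats), _normalized(val, stats),
                               seg_cfg, task="segmentation")
        seg_hist.to_csv(fdir / "msegnet_history.csv", index=False)
        segnet.save(fdir / "msegnet.npz")

        pred_test = _predict_masks(segnet, test, stats)
        seg_scores = segmentation_metrics(pred_test, [s.mask for s in test])
        seg_rows.append({"fold": fold.fold_index, "accuracy": seg_scores.accuracy,
                         "iou": seg_scores.iou, "dice": seg_scores.dice})

        # --- classification (raw and segmented variants) ---
        masks = {"fit": [s.mask for s in fit], "val": [s.mask for s in val],
                 "test": pred_test if not config.use_gt_masks
                 else [s.mask for s in test]}
        if not config.use_gt_masks:
            masks["fit"] = _predict_masks(segnet, fit, stats)
            masks["val"] = _predict_masks(segnet, val, stats)

        for variant in ("raw", "segmented"):
            use = None if variant == "raw" else masks
            cls_fit = _cls_dataset(fit, None if use is None else use["fit"],
                                   config.cls_input_size)
            cls_val = _cls_dataset(val, None if use is None else use["val"],
                                   config.cls_input_size)
            cls_test = _cls_dataset(test, None if use is None else use["test"],
                                    config.cls_input_size)
            cls_stats = compute_stats(cls_fit)
            cls_policy = replace(
                config.cls_policy,
                seed=_stage_seed(config.seed, fold.fold_index, f"cls-aug-{variant}"))
            cls_aug = _augmented_list(cls_fit, cls_policy)
            net = BINet(
                BINetConfig(q_order=config.q_order, input_size=config.cls_input_size),
                rng=np.random.default_rng(
                    _stage_seed(config.seed, fold.fold_index, f"cls-init-{variant}")))
            cls_cfg = replace(
                config.cls_train,
                seed=_stage_seed(config.seed, fold.fold_index, f"cls-{variant}"))
            hist = train_model(net, _normalized(cls_aug, cls_stats),
                               _normalized(cls_val, cls_stats), cls_cfg,
                               task="classification")
            hist.to_csv(fdir / f"binet_{variant}_history.csv", index=False)
            net.save(fdir / f"binet_{variant}.npz")

            rows, true, pred = [], [], []
            for s in cls_test:
                cp = classify(net, zscore_normalize(s.image, cls_stats))
                true.append(LABELS.index(s.label))
                pred.append(cp.predicted)
                rows.append({"id": s.sample_id,
                             **{f"p_{lab}": float(cp.probabilities[j])
                                for j, lab in enumerate(LABELS)},
                             "predicted": LABELS[cp.predicted], "true": s.label})
            pd.DataFrame(rows).to_csv(fdir / f"binet_{variant}_predictions.csv",
                                      index=False)
            cm = confusion_matrix(np.array(true), np.array(pred))
            write_confusion(cm, fdir / f"confusion_{variant}.csv")
            plot_confusion(cm, fdir / f"confusion_{variant}.png",
                           title=f"fold {fold.fold_index} ({variant})")
            metrics = classwise_metrics(cm)
            row = {"fold": fold.fold_index, **metrics.as_percent()}
            (raw_rows if variant == "raw" else segd_rows).append(row)

    pd.DataFrame(seg_rows).to_csv(out / "segmentation_metrics.csv", index=False)
    pd.DataFrame(raw_rows).to_csv(out / "classification_raw.csv", index=False)
    pd.DataFrame(segd_rows).to_csv(out / "classification_segmented.csv", index=False)

    summary: dict = {"folds_run": list(which),
                     "segmentation": {k: float(np.mean([r[k] for r in seg_rows]))
                                      for k in ("accuracy", "iou", "dice")}}
    for name, rows in (("raw", raw_rows), ("segmented", segd_rows)):
        summary[name] = {k: float(np.mean([r[k] for r in rows]))
                         for k in ("accuracy", "precision", "recall",
                                   "specificity", "f1")}
    if len(raw_rows) >= 2:
        fs = fold_statistics([r["accuracy"] for r in segd_rows],
                             [r["accuracy"] for r in raw_rows])
        summary["segmented_vs_raw"] = {"mean": fs.mean, "std": fs.std,
                                       "t": fs.t_stat, "p": fs.p_value,
                                       "degenerate": fs.degenerate}

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "versions": {"mwbrain": __version__, "numpy": np.__version__},
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
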