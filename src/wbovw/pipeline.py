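"""End-to-end evaluation: repeated stratified splits, training, metrics.

One experiment repeat draws a stratified 6:2:2 train/validation/test split,
preprocesses every ROI (wavelet denoising, masked histogram equalization),
extracts DoG keypoints and HOG descriptors, fits the GMM vocabulary on the
*training* descriptors only, encodes every image with the α weight-scaling
encoder, trains the BLS + SVM ensemble on the training codes (selecting λ
on validation unless fixed), and scores the held-out test split.  Repeats
differ only in their split/seed; reported metrics are per-repeat values
plus their mean (and best repeat), with FGR as the positive class.

Leakage policy: keypoint detection and description are unsupervised
per-image operations and are computed once per image; every *fitted*
object — vocabulary, classifiers, λ — sees training-split data only
(augmented copies included).  The report records which image ids entered
vocabulary fitting so the guarantee is checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, roc_curve

from .classifiers import EnsembleModel, fit_ensemble
from .encoding import DEFAULT_ALPHA, encode_corpus
from .hog_features import HogParams, describe_image
from .imaging_io import (
    AugmentConfig,
    GrayImage,
    RoiPatch,
    augment_with_mask,
    denoise_wavelet,
    equalize_hist,
    extract_roi,
    load_image,
    load_manifest,
)
from .scale_space import ScaleSpaceParams, detect_keypoints
from .vocabulary import fit_gmm

__all__ = [
    "SplitPlan",
    "Metrics",
    "EvalReport",
    "ExperimentConfig",
    "split_6_2_2",
    "compute_metrics",
    "f1_from_precision_recall",
    "roc_auc",
    "preprocess_case",
    "extract_descriptors",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint stratified train/validation/test id lists for one repeat."""

    train: list[str]
    val: list[str]
    test: list[str]
    repeat: int
    seed: int


@dataclass(frozen=True)
class Metrics:
    """Binary classification metrics with FGR (label 1) as positive."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray  # rows true, cols predicted, label order (0, 1)
    zero_division_flags: tuple[str, ...] = ()


@dataclass
class EvalReport:
    """Per-repeat and aggregate results of an experiment run."""

    per_repeat: list[dict]
    mean: dict
    best: dict
    config: dict
    degenerate_images: list[str]
    vocab_train_ids: list[list[str]]  # ids whose descriptors fed each vocab fit
    errors: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "per_repeat": self.per_repeat,
            "mean": self.mean,
            "best": self.best,
            "degenerate_images": self.degenerate_images,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def split_6_2_2(
    ids_with_labels: list[tuple[str, int]], seed: int, repeat: int = 0
) -> SplitPlan:
    """Stratified 60/20/20 split, the training set taking the remainder.

    Within each class, ⌊n/5⌋ ids go to validation and ⌊n/5⌋ to test; the
    rest train.  Deterministic per seed; requires ≥ 5 ids per class so that
    every part is non-empty.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for iid, lab in ids_with_labels:
        by_class[int(lab)].append(iid)
    train, val, test = [], [], []
    for lab in (0, 1):
        ids = by_class[lab]
        if len(ids) < 5:
            raise ValueError(f"class {lab} has {len(ids)} ids; need >= 5 for a 6:2:2 split")
        order = rng.permutation(len(ids))
        n_part = len(ids) // 5
        shuffled = [ids[i] for i in order]
        val.extend(shuffled[:n_part])
        test.extend(shuffled[n_part : 2 * n_part])
        train.extend(shuffled[2 * n_part :])
    return SplitPlan(train=train, val=val, test=test, repeat=repeat, seed=int(seed))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Accuracy, recall, precision, F1 and the 2×2 confusion matrix."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    flags = []
    if tp + fn == 0:
        recall, flags = 0.0, flags + ["recall"]
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision, flags = 0.0, flags + ["precision"]
    else:
        precision = tp / (tp + fp)
    return Metrics(
        accuracy=float((tp + tn) / cm.sum()),
        recall=float(recall),
        precision=float(precision),
        f1=f1_from_precision_recall(float(precision), float(recall)),
        confusion=cm,
        zero_division_flags=tuple(flags),
    )


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep and trapezoidal AUC.

    Tied scores cross their threshold simultaneously, which makes the
    trapezoidal area equal the Mann–Whitney pair-counting statistic with
    half credit for ties.  Requires both classes present.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def preprocess_case(img: GrayImage, ann) -> RoiPatch:
    """ROI crop → wavelet denoising → masked histogram equalization."""
    patch = extract_roi(img, ann)
    den = denoise_wavelet(patch.image)
    eq = equalize_hist(den, patch.mask)
    pixels = eq.pixels.copy()
    pixels[~patch.mask] = 0.0
    return RoiPatch(image=GrayImage(pixels), mask=patch.mask, annotation=patch.annotation)


def extract_descriptors(
    image: GrayImage,
    mask: np.ndarray | None,
    ssp: ScaleSpaceParams,
    hog: HogParams,
) -> np.ndarray:
    """Detect DoG keypoints and stack their HOG descriptors (may be 0×144)."""
    kps = detect_keypoints(image, ssp, mask=mask, window_side_fn=hog.window_side)
    return describe_image(image, kps, hog, mask=mask)


@dataclass
class ExperimentConfig:
    """Everything a run needs; defaults follow the method's operating point.

    ``lam=None`` selects the ensemble mixing weight on the validation split
    (ties toward smaller λ); a float fixes it.  ``max_fit_descriptors``
    bounds the random subsample of training descriptors used for the EM
    fit, which keeps vocabulary construction tractable without touching
    encoding (encoding always uses every keypoint).
    """

    k: int = 128
    alpha: float = DEFAULT_ALPHA
    lam: float | None = None
    repeats: int = 10
    master_seed: int = 0
    scale_space: ScaleSpaceParams = field(default_factory=ScaleSpaceParams)
    hog: HogParams = field(default_factory=HogParams)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    max_fit_descriptors: int = 20000
    gmm_max_iter: int = 100
    gmm_tol: float = 1e-3
    normalize_responsibilities: bool = True
    bls_params: dict = field(default_factory=dict)
    svm_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "alpha": self.alpha,
            "lam": self.lam,
            "repeats": self.repeats,
            "master_seed": self.master_seed,
            "n_octaves": self.scale_space.n_octaves,
            "intervals_per_octave": self.scale_space.intervals_per_octave,
            "base_sigma": self.scale_space.base_sigma,
            "contrast_threshold": self.scale_space.contrast_threshold,
            "augment": None if self.augment is None else self.augment.n_augments_per_image,
            "max_fit_descriptors": self.max_fit_descriptors,
            "normalize_responsibilities": self.normalize_responsibilities,
        }


def _metric_dict(m: Metrics, auc: float, lam: float, seed: int) -> dict:
    # no wall-clock fields: reports with equal seeds must be bit-identical
    return {
        "accuracy": m.accuracy,
        "recall": m.recall,
        "precision": m.precision,
        "f1": m.f1,
        "auc": auc,
        "confusion": m.confusion.tolist(),
        "lambda": lam,
        "seed": seed,
    }


def run_experiment(manifest_path: str | Path, config: ExperimentConfig) -> EvalReport:
    """Run the full pipeline for ``config.repeats`` stratified splits.

    Images are resolved as ``<image_id>.png`` (or ``.tif``/``.tiff``)
    relative to the manifest.  Returns per-repeat metrics, their mean over
    repeats and the best repeat.  A failed repeat is logged in
    ``report.errors`` and skipped rather than aborting the whole run.
    """
    manifest_path = Path(manifest_path)
    annotations = load_manifest(manifest_path)
    base_dir = manifest_path.parent
    cases: dict[str, RoiPatch] = {}
    labels: dict[str, int] = {}
    for ann in annotations:
        for ext in (".png", ".tif", ".tiff"):
            candidate = base_dir / f"{ann.image_id}{ext}"
            if candidate.exists():
                break
        else:
            raise FileNotFoundError(f"no image file found for id {ann.image_id!r}")
        cases[ann.image_id] = preprocess_case(load_image(candidate), ann)
        labels[ann.image_id] = ann.label

    # per-image feature extraction is unsupervised: compute once, reuse per repeat
    descriptors: dict[str, np.ndarray] = {}
    for iid, patch in cases.items():
        descriptors[iid] = extract_descriptors(
            patch.image, patch.mask, config.scale_space, config.hog
        )
    degenerate_images = sorted(iid for iid, V in descriptors.items() if V.shape[0] == 0)

    ids_with_labels = [(ann.image_id, ann.label) for ann in annotations]
    ss = np.random.SeedSequence(config.master_seed)
    repeat_seeds = ss.generate_state(config.repeats) % (2**31)

    per_repeat: list[dict] = []
    vocab_train_ids: list[list[str]] = []
    errors: list[str] = []
    for r in range(config.repeats):
        seed_r = int(repeat_seeds[r])
        try:
            plan = split_6_2_2(ids_with_labels, seed=seed_r, repeat=r)
            rng = np.random.default_rng(seed_r)

            train_mats = [descriptors[i] for i in plan.train]
            train_labels = [labels[i] for i in plan.train]
            if config.augment is not None:
                for iid in plan.train:
                    for aug_img, aug_mask in augment_with_mask(
                        cases[iid], config.augment, rng
                    ):
                        train_mats.append(
                            extract_descriptors(
                                aug_img, aug_mask, config.scale_space, config.hog
                            )
                        )
                        train_labels.append(labels[iid])

            pool = (
                np.vstack([V for V in train_mats if V.shape[0]])
                if any(V.shape[0] for V in train_mats)
                else np.zeros((0, config.hog.descriptor_length))
            )
            if pool.shape[0] < config.k:
                raise ValueError(
                    f"repeat {r}: {pool.shape[0]} training descriptors cannot "
                    f"support K={config.k}"
                )
            if pool.shape[0] > config.max_fit_descriptors:
                sel = rng.choice(pool.shape[0], config.max_fit_descriptors, replace=False)
                pool = pool[np.sort(sel)]
            vocab = fit_gmm(
                pool,
                K=config.k,
                seed=seed_r,
                max_iter=config.gmm_max_iter,
                tol=config.gmm_tol,
            )
            vocab_train_ids.append(list(plan.train))

            X_train, _ = encode_corpus(
                vocab, train_mats, config.alpha, config.normalize_responsibilities
            )
            y_train = np.asarray(train_labels)
            X_val, _ = encode_corpus(
                vocab,
                [descriptors[i] for i in plan.val],
                config.alpha,
                config.normalize_responsibilities,
            )
            y_val = np.asarray([labels[i] for i in plan.val])
            X_test, _ = encode_corpus(
                vocab,
                [descriptors[i] for i in plan.test],
                config.alpha,
                config.normalize_responsibilities,
            )
            y_test = np.asarray([labels[i] for i in plan.test])

            lam_grid = None if config.lam is None else np.asarray([config.lam])
            model: EnsembleModel = fit_ensemble(
                X_train,
                y_train,
                X_val,
                y_val,
                lam_grid=lam_grid,
                bls_params=config.bls_params,
                svm_params=config.svm_params,
                seed=seed_r,
            )
            y_pred = model.predict(X_test)
            scores = model.score_class1(X_test)
            metrics = compute_metrics(y_test, y_pred)
            _, auc = roc_auc(y_test, scores)
            per_repeat.append(_metric_dict(metrics, auc, model.lam, seed_r))
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover - defensive
            errors.append(f"repeat {r}: {exc}")

    if not per_repeat:
        raise RuntimeError("all repeats failed: " + "; ".join(errors))
    keys = ("accuracy", "recall", "precision", "f1", "auc")
    mean = {k: float(np.mean([m[k] for m in per_repeat])) for k in keys}
    mean["lambda"] = float(np.mean([m["lambda"] for m in per_repeat]))
    best = max(per_repeat, key=lambda m: m["accuracy"])
    return EvalReport(
        per_repeat=per_repeat,
        mean=mean,
        best=best,
        config=config.to_dict(),
        degenerate_images=degenerate_images,
        vocab_train_ids=vocab_train_ids,
        errors=errors,
    )
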