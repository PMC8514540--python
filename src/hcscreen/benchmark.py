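"""Default seeded segmentation benchmark with exact synthetic truth.

Twelve two-channel fields (~150 nuclei in total) are generated, the
pixel classifier is trained on the ground-truth masks of the first
four, and the full chain — features, forest, 0.5 threshold,
8-connected components, 200-px size filter — runs on the eight
held-out fields.  Object precision/recall/F1 (greedy IoU >= 0.5
matching) and the pooled pixel-level MCC are returned.

Training pixels are subsampled per class from the dense truth masks,
mirroring the sparse manual-annotation workflow and keeping the forest
fit fast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

from .classify import AnnotationMask, ClassifierModel, predict_proba, train
from .features import FeatureConfig, compute_features
from .quality import match_objects, object_metrics, pixel_mcc
from .scenes import GroundTruthScene, SceneParams, generate_scene
from .segment import binarize, filter_small, label_components


@dataclass
class BenchmarkResult:
    precision: float
    recall: float
    f1: float
    mcc: float
    n_tp: int
    n_fp: int
    n_fn: int
    n_gt_objects: int
    n_fields_test: int
    model: ClassifierModel


def default_benchmark_scenes(seed: int = 42, n_fields: int = 12,
                             nuclei_per_field: int = 13,
                             params: SceneParams | None = None
                             ) -> List[GroundTruthScene]:
    base = params or SceneParams()
    return [
        generate_scene(replace(base, n_nuclei=nuclei_per_field, seed=seed + i))
        for i in range(n_fields)
    ]


def run_segmentation_benchmark(seed: int = 42, forest_seed: int = 0,
                               n_fields: int = 12, n_train: int = 4,
                               nuclei_per_field: int = 13, n_trees: int = 100,
                               train_pixels_per_class: int = 4000,
                               iou_threshold: float = 0.5,
                               threshold: float = 0.5, min_area_px: int = 200,
                               connectivity: int = 8,
                               params: SceneParams | None = None
                               ) -> BenchmarkResult:
    """Train on ``n_train`` fields, score the rest; pooled object metrics."""
    scenes = default_benchmark_scenes(seed, n_fields, nuclei_per_field, params)
    config = FeatureConfig()
    stacks = [compute_features(s.dapi, config) for s in scenes]

    annotations = [
        AnnotationMask.from_ground_truth(
            scenes[i].true_labels, rng=forest_seed + i,
            max_per_class=train_pixels_per_class)
        for i in range(n_train)
    ]
    model = train(stacks[:n_train], annotations, n_trees=n_trees, seed=forest_seed)

    tp = fp = fn = 0
    gt_total = 0
    gt_pool, pred_pool = [], []
    for scene, stack in zip(scenes[n_train:], stacks[n_train:]):
        pmap = predict_proba(model, stack)
        mask = binarize(pmap, threshold)
        pred = filter_small(label_components(mask, connectivity), min_area_px)
        gt = filter_small(scene.true_labels, min_area_px)
        m = match_objects(gt, pred, iou_threshold)
        tp += m.n_tp
        fp += m.n_fp
        fn += m.n_fn
        gt_total += gt.n_labels
        gt_pool.append(gt.labels > 0)
        pred_pool.append(pred.labels > 0)

    from .quality import DetectionMatchResult

    metrics = object_metrics(DetectionMatchResult(
        pairs=[], n_tp=tp, n_fp=fp, n_fn=fn, iou_threshold=iou_threshold))
    import numpy as np

    mcc = pixel_mcc(np.concatenate([g.ravel() for g in gt_pool]),
                    np.concatenate([p.ravel() for p in pred_pool]))
    return BenchmarkResult(
        precision=metrics.precision, recall=metrics.recall, f1=metrics.f1,
        mcc=mcc, n_tp=tp, n_fp=fp, n_fn=fn, n_gt_objects=gt_total,
        n_fields_test=n_fields - n_train, model=model,
    )
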