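"""Two-class (nucleus vs background) per-pixel random-forest classifier.

Replaces an interactive annotate-and-retrain workflow with scriptable
whole-batch training: sparse pixel annotations in, a portable model
file out.  Only labeled pixels enter training; class imbalance is left
as-is to mirror the sparse-annotation setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, FeatureStack

#: annotation codes
UNLABELED = 0
NUCLEUS = 1
BACKGROUND = 2

MODEL_FORMAT_VERSION = 1


@dataclass
class AnnotationMask:
    """Per-pixel training labels: 0 unlabeled, 1 nucleus, 2 background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("annotation mask must be 2-D")
        bad = set(np.unique(self.labels)) - {UNLABELED, NUCLEUS, BACKGROUND}
        if bad:
            raise ValueError(f"annotation mask contains invalid codes {sorted(bad)}")

    @classmethod
    def from_ground_truth(cls, label_map, rng=None, max_per_class: int | None = None
                          ) -> "AnnotationMask":
        """Build a dense (or subsampled) annotation from a true label map.

        With ``max_per_class`` set, at most that many pixels per class are
        kept (uniformly at random, seeded via ``rng``) — emulating sparse
        manual annotation while keeping training tractable.
        """
        arr = np.asarray(getattr(label_map, "labels", label_map))
        ann = np.where(arr > 0, NUCLEUS, BACKGROUND).astype(np.uint8)
        if max_per_class is not None:
            rng = np.random.default_rng(rng)
            out = np.full(ann.shape, UNLABELED, dtype=np.uint8)
            for code in (NUCLEUS, BACKGROUND):
                idx = np.flatnonzero(ann.ravel() == code)
                if idx.size > max_per_class:
                    idx = rng.choice(idx, size=max_per_class, replace=False)
                out.ravel()[idx] = code
            ann = out
        return cls(ann)


@dataclass
class ClassifierModel:
    """Trained forest plus the feature contract it was fitted under."""

    forest: RandomForestClassifier
    feature_names: List[str]
    training_meta: dict = field(default_factory=dict)
    config_hash: str = ""


def train(stacks: Sequence[FeatureStack], annotations: Sequence[AnnotationMask],
          n_trees: int = 100, seed: int = 0) -> ClassifierModel:
    """Fit a random forest on the labeled pixels of the given fields.

    Deterministic for a fixed ``seed``.  Raises if either class has no
    labeled pixels overall, or if feature names differ across stacks.
    """
    if len(stacks) != len(annotations):
        raise ValueError("stacks and annotations must align pairwise")
    if not stacks:
        raise ValueError("at least one training field required")
    names = stacks[0].names
    for i, st in enumerate(stacks):
        if st.names != names:
            raise ValueError(f"feature names of stack {i} differ from stack 0")
        if st.values.shape[:2] != annotations[i].labels.shape:
            raise ValueError(f"stack {i} and its annotation mask have different shapes")

    xs, ys = [], []
    for st, ann in zip(stacks, annotations):
        labeled = ann.labels != UNLABELED
        xs.append(st.as_matrix()[labeled.ravel()])
        ys.append(ann.labels[labeled])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    for code, cname in ((NUCLEUS, "nucleus"), (BACKGROUND, "background")):
        if not np.any(y == code):
            raise ValueError(f"no labeled pixels for class '{cname}'")

    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, y == NUCLEUS)
    meta = {"n_trees": n_trees, "seed": seed, "n_training_pixels": int(len(y))}
    return ClassifierModel(forest=forest, feature_names=list(names),
                           training_meta=meta, config_hash=stacks[0].config_hash)


def predict_proba(model: ClassifierModel, stack: FeatureStack) -> np.ndarray:
    """Per-pixel nucleus probability map in [0, 1].

    The stack's feature names must match the model's, by name and order.
    """
    if stack.names != model.feature_names:
        missing = [n for n in model.feature_names if n not in stack.names]
        extra = [n for n in stack.names if n not in model.feature_names]
        raise ValueError(
            f"feature mismatch: missing {missing or 'none'}, extra {extra or 'none'}, "
            f"order must also match"
        )
    if model.config_hash and stack.config_hash and stack.config_hash != model.config_hash:
        raise ValueError("feature config hash mismatch between model and stack")
    proba = model.forest.predict_proba(stack.as_matrix())
    nucleus_col = list(model.forest.classes_).index(True)
    return proba[:, nucleus_col].reshape(stack.values.shape[:2])


def save_model(model: ClassifierModel, path) -> None:
    """Serialize to a single self-describing file."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "forest": model.forest,
            "feature_names": model.feature_names,
            "training_meta": model.training_meta,
            "config_hash": model.config_hash,
        },
        path,
    )


def load_model(path) -> ClassifierModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    return ClassifierModel(
        forest=payload["forest"],
        feature_names=payload["feature_names"],
        training_meta=payload["training_meta"],
        config_hash=payload.get("config_hash", ""),
    )
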