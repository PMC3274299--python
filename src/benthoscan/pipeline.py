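"""End-to-end orchestration: front end -> features -> classifier -> count.

Glue used by the CLI, the tests and the acceptance simulations.  Training
labels come from synthetic-scene ground truth: a segmented object is
"belonging" when its centroid falls within a small radius of a planted
animal centroid; a keypoint feature is "belonging" when its centre lies in
a planted animal mask (or, when only sidecar centroids are available,
within the same radius of one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, keypoints, preprocess, shape_features
from .config import RunConfig
from .scene_synthesis import SceneGroundTruth

__all__ = [
    "ModelBundle",
    "CountResult",
    "front_end_objects",
    "sift_features",
    "count_image",
    "train_from_ground_truth",
    "train_from_scenes",
]

#: An object centroid within this many pixels of a planted centroid is that animal.
LABEL_RADIUS = 20.0


@dataclass
class ModelBundle:
    """Trained classifier(s) plus the method they serve."""

    method: str
    plsda: classify.PlsdaModel | None = None
    ed_model: classify.EdClassModel | None = None


@dataclass
class CountResult:
    count: int
    objects: list = field(default_factory=list)
    features: list = field(default_factory=list)


def front_end_objects(img: np.ndarray, cfg: RunConfig) -> list[preprocess.DetectedObject]:
    """Segmentation front end plus FD computation for every surviving object."""
    objects = preprocess.run_front_end(
        img,
        median_window=cfg.median_window,
        median_passes=cfg.median_passes,
        tophat_size=cfg.tophat_size,
        tophat_shape=cfg.tophat_shape,
        percentile=cfg.percentile,
        min_area=cfg.min_area,
        max_area=cfg.max_area,
    )
    for obj in objects:
        shape_features.compute_fd(obj)
    return objects


def sift_features(img: np.ndarray, cfg: RunConfig) -> list[keypoints.KeypointFeature]:
    """Keypoints on the grey (channel-mean) conversion of the top-hat image."""
    filtered = preprocess.median_filter(img, cfg.median_window, cfg.median_passes)
    flattened = np.stack(
        [
            preprocess.top_hat(filtered[..., c], cfg.tophat_size, cfg.tophat_shape)
            for c in range(3)
        ],
        axis=-1,
    )
    grey = flattened.astype(float).mean(axis=-1)
    params = keypoints.SiftParams(
        n_octaves=cfg.n_octaves,
        levels_per_octave=cfg.levels_per_octave,
        peak_threshold=cfg.peak_threshold,
        edge_threshold=cfg.edge_threshold,
    )
    return keypoints.detect_keypoints(grey, params)


def count_image(img: np.ndarray, cfg: RunConfig, bundle: ModelBundle) -> CountResult:
    """Count animals in one image with the bundle's method."""
    method = bundle.method
    if method in ("fd_plsda", "fd_ed"):
        objects = front_end_objects(img, cfg)
        count = classify.count_munida(
            method, objects=objects, plsda=bundle.plsda, ed_model=bundle.ed_model
        )
        return CountResult(count=count, objects=objects)
    if method == "sift_plsda":
        feats = sift_features(img, cfg)
        count = classify.count_munida(
            method,
            features=feats,
            plsda=bundle.plsda,
            min_features=cfg.min_features,
            link_distance=cfg.link_distance,
        )
        return CountResult(count=count, features=feats)
    raise ValueError(f"unknown method {method!r}")


def _label_objects(objects, centroids: list[tuple[float, float]]) -> np.ndarray:
    """Boolean belonging label per object by centroid proximity."""
    labels = np.zeros(len(objects), dtype=bool)
    if not centroids:
        return labels
    pts = np.asarray(centroids, dtype=float)
    for i, obj in enumerate(objects):
        d = np.linalg.norm(pts - np.asarray(obj.centroid), axis=1)
        labels[i] = bool(d.min() <= LABEL_RADIUS)
    return labels


def train_from_ground_truth(
    scenes: list[tuple[np.ndarray, SceneGroundTruth]], cfg: RunConfig
) -> tuple[ModelBundle, classify.CalibrationReport | None]:
    """Fit the classifier for ``cfg.method`` from in-memory scenes with ground truth."""
    method = cfg.method
    if method in ("fd_plsda", "fd_ed"):
        tables, labels = [], []
        for img, gt in scenes:
            objects = front_end_objects(img, cfg)
            if not objects:
                continue
            tables.append(shape_features.build_feature_matrix(objects).to_numpy())
            labels.append(_label_objects(objects, gt.animal_centroids))
        X = np.vstack(tables)
        y = np.concatenate(labels)
        if method == "fd_plsda":
            model, report = classify.plsda_fit(X, y, n_lv=cfg.n_lv_fd, cv="none")
            return ModelBundle(method, plsda=model), report
        pos = X[y]
        ed_model = classify.ed_fit(
            pos[:, :3], pos[:, 3:], threshold_percentile=cfg.ed_threshold_percentile
        )
        return ModelBundle(method, ed_model=ed_model), None
    if method == "sift_plsda":
        desc, labels = [], []
        for img, gt in scenes:
            feats = sift_features(img, cfg)
            if not feats:
                continue
            if gt.animal_masks:
                union = np.logical_or.reduce(gt.animal_masks)
            else:
                union = np.zeros(img.shape[:2], dtype=bool)
            keypoints.label_features_by_mask(feats, union)
            desc.extend(f.descriptor for f in feats)
            labels.extend(f.in_animal for f in feats)
        X = np.asarray(desc, dtype=float)
        y = np.asarray(labels, dtype=bool)
        model, report = classify.plsda_fit(X, y, n_lv=cfg.n_lv_sift, cv="none")
        return ModelBundle(method, plsda=model), report
    raise ValueError(f"unknown method {method!r}")


def train_from_scenes(
    images: list[tuple[Path, np.ndarray]], cfg: RunConfig
) -> tuple[ModelBundle, classify.CalibrationReport | None]:
    """Fit from scene files whose JSON sidecars record planted centroids."""
    scenes = []
    for path, img in images:
        sidecar = Path(path).with_suffix(".json")
        gt = SceneGroundTruth()
        if sidecar.exists():
            raw = json.loads(sidecar.read_text())
            gt.animal_centroids = [tuple(p) for p in raw.get("animal_centroids", [])]
            gt.seed = raw.get("seed")
        if cfg.method == "sift_plsda" and gt.animal_centroids:
            # no masks in the sidecar: approximate membership by a disc
            # of LABEL_RADIUS around each planted centroid
            rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
            union = np.zeros(img.shape[:2], dtype=bool)
            for r, c in gt.animal_centroids:
                union |= (rows - r) ** 2 + (cols - c) ** 2 <= LABEL_RADIUS**2
            gt.animal_masks = [union]
        scenes.append((img, gt))
    return train_from_ground_truth(scenes, cfg)
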