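"""Scale-invariant keypoint detection and the feature-clustering counting rule.

Keypoints are difference-of-Gaussian scale-space extrema with 128-bin
gradient-orientation descriptors (4x4 spatial histogram x 8 orientations),
detected with :class:`skimage.feature.SIFT`.  The detector is configured
through :class:`SiftParams`, whose defaults mirror the counting pipeline's
operating point: 9 octaves, 3 levels per octave, a peak-selection threshold
of 3 (expressed on the 0-255 intensity scale) and a non-edge
principal-curvature threshold of 7.

Counting rule: features classified as animal are grouped by single-linkage
clustering with a fixed linking radius; every cluster holding more than six
features counts as one animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.feature import SIFT

__all__ = [
    "SiftParams",
    "KeypointFeature",
    "detect_keypoints",
    "label_features_by_mask",
    "count_animals_from_features",
]

DESCRIPTOR_LENGTH = 128


@dataclass(frozen=True)
class SiftParams:
    """Detector knobs; defaults are the pipeline's operating point.

    ``peak_threshold`` is on the 0-255 intensity scale of the input images
    (converted internally to the detector's normalized scale);
    ``edge_threshold`` bounds the ratio of principal curvatures.
    """

    n_octaves: int = 9
    levels_per_octave: int = 3
    peak_threshold: float = 3.0
    edge_threshold: float = 7.0

    def __post_init__(self) -> None:
        if min(self.n_octaves, self.levels_per_octave) < 1:
            raise ValueError("octave and level counts must be positive")
        if self.peak_threshold <= 0 or self.edge_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class KeypointFeature:
    """One scale-space keypoint with its descriptor and animal label."""

    position: tuple[float, float]  # (row, col), sub-pixel
    scale: float
    orientation: float  # radians
    descriptor: np.ndarray = field(repr=False)
    in_animal: bool | None = None


def detect_keypoints(img: np.ndarray, params: SiftParams | None = None) -> list[KeypointFeature]:
    """Detect scale-space keypoints on a grey image.

    Octaves beyond what the image size supports are skipped (the detector
    warns); a constant image yields no extrema and an empty list.
    """
    params = params or SiftParams()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if img.max() == img.min():
        return []

    # the detector works on [0, 1] images; rescale the peak threshold with it
    span = img.max() - img.min()
    scaled = (img - img.min()) / span
    detector = SIFT(
        upsampling=1,
        n_octaves=params.n_octaves,
        n_scales=params.levels_per_octave,
        c_dog=params.peak_threshold / 255.0,
        c_edge=params.edge_threshold,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # infeasible-octave downsizing notices
        try:
            detector.detect_and_extract(scaled)
        except RuntimeError:  # no extrema found
            return []
    return [
        KeypointFeature(
            position=(float(r), float(c)),
            scale=float(s),
            orientation=float(o),
            descriptor=np.asarray(d, dtype=float),
        )
        for (r, c), s, o, d in zip(
            detector.positions, detector.sigmas, detector.orientations, detector.descriptors
        )
    ]


def keypoints_to_csv(features: list[KeypointFeature], path) -> None:
    """Export keypoints as CSV: row, col, scale, orientation, 128 descriptor bins."""
    import pandas as pd

    rows = [
        {
            "row": f.position[0],
            "col": f.position[1],
            "scale": f.scale,
            "orientation": f.orientation,
            **{f"desc_{i:03d}": v for i, v in enumerate(f.descriptor)},
        }
        for f in features
    ]
    cols = ["row", "col", "scale", "orientation"] + [f"desc_{i:03d}" for i in range(128)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def label_features_by_mask(
    features: list[KeypointFeature], mask: np.ndarray
) -> list[KeypointFeature]:
    """Set ``in_animal`` from mask membership of each feature's rounded centre.

    A feature sitting exactly on a boundary pixel is inside: pixel
    membership decides.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for f in features:
        r = int(np.clip(round(f.position[0]), 0, h - 1))
        c = int(np.clip(round(f.position[1]), 0, w - 1))
        f.in_animal = bool(mask[r, c])
    return features


def count_animals_from_features(
    features: list[KeypointFeature],
    min_features: int = 7,
    link_distance: float = 500.0,
    method: str = "single",
) -> int:
    """Count animals as feature clusters with at least ``min_features`` members.

    Features are clustered on their pixel positions with the chosen linkage
    and cut at ``link_distance``; the default single linkage means two
    features belong together whenever a chain of pairwise distances below
    the radius connects them.  Clusters of fewer than ``min_features``
    (default 7, i.e. strictly more than 6) features are discarded as noise.
    """
    if method not in ("single", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(features)
    if n == 0:
        return 0
    if n == 1:
        return 1 if min_features <= 1 else 0
    pos = np.array([f.position for f in features], dtype=float)
    labels = fcluster(linkage(pos, method=method), t=link_distance, criterion="distance")
    _, sizes = np.unique(labels, return_counts=True)
    return int((sizes >= min_features).sum())
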