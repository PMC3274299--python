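"""Front end of the squat-lobster counting pipeline.

The raw seafloor photograph is denoised with a repeated median filter,
flattened with a white top-hat (which removes the uneven illumination and
large-scale sediment background while preserving small bright structures),
reduced to a per-pixel R-G chromatic distance map, segmented at the 95th
percentile of that map, and finally decomposed into connected objects that
pass a pixel-area gate.  Each surviving object carries the measurements the
downstream classifiers consume: area, centroid, outer contour and mean RGB.

Images are numpy arrays: RGB images ``(H, W, 3)`` uint8, grey maps ``(H, W)``
non-negative, masks ``(H, W)`` bool.  Coordinates are 0-based (row, col).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "DetectedObject",
    "DegenerateInputWarning",
    "median_filter",
    "top_hat",
    "channel_distance_map",
    "percentile_threshold",
    "extract_objects",
]

#: Pixel-area acceptance gate for segmented objects.
MIN_OBJECT_AREA = 200
MAX_OBJECT_AREA = 150_000

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class DegenerateInputWarning(UserWarning):
    """Raised (as a warning) when an input is constant where variation is assumed."""


@dataclass
class DetectedObject:
    """One segmented connected blob and its measurements.

    ``fd`` is filled in by :mod:`benthoscan.shape_features`; it is ``None``
    straight out of segmentation.
    """

    label: int
    area: int
    centroid: tuple[float, float]
    contour: np.ndarray  # closed polyline, (K, 2) float, first row == last row
    mean_rgb: tuple[float, float, float]
    fd: np.ndarray | None = field(default=None, repr=False)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def median_filter(img: np.ndarray, window: int = 7, passes: int = 3) -> np.ndarray:
    """Apply a ``window`` x ``window`` median filter ``passes`` times per channel.

    Borders are handled by edge replication.  The repeated pass wipes out
    impulse noise (floating debris, specular glints) without blurring object
    boundaries the way a linear filter would.
    """
    img = _check_rgb(img)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if passes < 0:
        raise ValueError(f"passes must be >= 0, got {passes}")
    out = img
    for _ in range(passes):
        out = np.stack(
            [ndi.median_filter(out[..., c], size=window, mode="nearest") for c in range(3)],
            axis=-1,
        )
    return out


def _footprint(elem_size: int, shape: str) -> np.ndarray:
    if shape == "disc":
        # flat disc of the given *diameter*
        return morphology.disk(elem_size // 2)
    if shape == "square":
        return np.ones((elem_size, elem_size), dtype=bool)
    raise ValueError(f"unknown structuring-element shape {shape!r}")


def top_hat(img_channel: np.ndarray, elem_size: int = 25, shape: str = "disc") -> np.ndarray:
    """White top-hat: original minus its morphological opening.

    Removes everything the structuring element fits inside of — the smooth
    illumination field and broad sediment features — and keeps bright
    structures narrower than ``elem_size``.  Output is non-negative and a
    constant image maps to all zeros.

    ``elem_size`` is the diameter of a flat disc (``shape='disc'``) or the
    side of a square (``shape='square'``).
    """
    img_channel = np.asarray(img_channel)
    if img_channel.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {img_channel.shape}")
    if elem_size < 3:
        raise ValueError(f"elem_size must be >= 3, got {elem_size}")
    if elem_size > min(img_channel.shape):
        raise ValueError(
            f"elem_size {elem_size} exceeds the image extent {img_channel.shape}"
        )
    return morphology.white_tophat(img_channel, footprint=_footprint(elem_size, shape))


def channel_distance_map(img: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance between the R and G channels, i.e. ``|R - G|``.

    Computed in widened integer arithmetic so uint8 subtraction cannot wrap.
    Squat lobsters are redder than the sediment, so this one-dimensional
    chromatic distance is the segmentation signal.
    """
    img = _check_rgb(img)
    r = img[..., 0].astype(np.int32)
    g = img[..., 1].astype(np.int32)
    return np.abs(r - g)


def percentile_threshold(grey_map: np.ndarray, q: float = 95.0) -> np.ndarray:
    """Binarize a grey map at its own ``q``-th percentile (strict ``>``).

    The percentile is the next-higher order statistic of the sorted pixel
    values (a sort-based percentile), so by construction at most
    ``(100 - q)%`` of pixels (plus any tie excess) come out true.  A
    constant map has nothing above its own percentile; it returns an empty
    mask and emits :class:`DegenerateInputWarning`.
    """
    grey_map = np.asarray(grey_map)
    if grey_map.ndim != 2:
        raise ValueError(f"expected a 2-D grey map, got shape {grey_map.shape}")
    if not 0.0 < q < 100.0:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    lo, hi = grey_map.min(), grey_map.max()
    if lo == hi:
        warnings.warn(
            "percentile_threshold: constant input map, returning empty mask",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.zeros(grey_map.shape, dtype=bool)
    thr = np.percentile(grey_map, q, method="higher")
    return grey_map > thr


def extract_objects(
    mask: np.ndarray,
    original: np.ndarray,
    min_area: int = MIN_OBJECT_AREA,
    max_area: int = MAX_OBJECT_AREA,
) -> list[DetectedObject]:
    """Label 8-connected components of ``mask`` and keep those inside the area gate.

    Components smaller than ``min_area`` are contingent noise (turbidity
    specks, debris); larger than ``max_area``, background excursions.  Mean
    RGB is measured on ``original``; the outer contour is a closed (row, col)
    polyline traced at the object boundary (holes are ignored).
    """
    mask = np.asarray(mask, dtype=bool)
    original = _check_rgb(original)
    if mask.shape != original.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {original.shape[:2]}"
        )
    labels, n = ndi.label(mask, structure=_EIGHT_CONNECTED)
    objects: list[DetectedObject] = []
    for prop in measure.regionprops(labels):
        if not (min_area <= prop.area <= max_area):
            continue
        objects.append(
            DetectedObject(
                label=int(prop.label),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                contour=_outer_contour(labels == prop.label),
                mean_rgb=tuple(
                    float(original[..., c][labels == prop.label].mean()) for c in range(3)
                ),
            )
        )
    return objects


def _outer_contour(obj_mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary polyline of a binary object, longest loop wins.

    The mask is zero-padded so border-touching objects still yield a closed
    loop; coordinates are shifted back to the original frame.
    """
    padded = np.pad(obj_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:  # pragma: no cover - non-empty masks always trace
        raise ValueError("no contour found for object mask")
    contour = max(contours, key=len) - 1.0
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour


def run_front_end(
    img: np.ndarray,
    median_window: int = 7,
    median_passes: int = 3,
    tophat_size: int = 25,
    tophat_shape: str = "disc",
    percentile: float = 95.0,
    min_area: int = MIN_OBJECT_AREA,
    max_area: int = MAX_OBJECT_AREA,
    return_intermediates: bool = False,
):
    """Full segmentation front end: filter, flatten, chroma map, threshold, extract.

    Returns the list of :class:`DetectedObject`; with
    ``return_intermediates=True`` also a dict of the intermediate images
    (filtered, top-hat, distance map, mask) for inspection.
    """
    filtered = median_filter(img, window=median_window, passes=median_passes)
    flattened = np.stack(
        [top_hat(filtered[..., c], elem_size=tophat_size, shape=tophat_shape) for c in range(3)],
        axis=-1,
    )
    ed_map = channel_distance_map(flattened)
    seg = percentile_threshold(ed_map, q=percentile)
    objects = extract_objects(seg, img, min_area=min_area, max_area=max_area)
    if return_intermediates:
        return objects, {
            "filtered": filtered,
            "tophat": flattened,
            "distance_map": ed_map,
            "mask": seg,
        }
    return objects
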