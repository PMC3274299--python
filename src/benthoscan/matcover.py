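"""Bacterial-mat coverage and box-counting fractal dimension.

White filamentous mats (*Beggiatoa* spp.) are bright, highly reflective
patches on a darker sediment background.  The pipeline estimates how much
of a fixed region of interest (ROI) they cover and how completely they fill
space across scales:

1. model the background with a broad Gaussian blur of the frame;
2. subtract it from the original within the ROI and sum the three channel
   residuals into one grey map (mats are brighter than background, so
   negative residuals are clipped to zero as noise);
3. enhance contrast by clipping the lowest 10% and highest 1% of in-ROI
   values to their nearest kept values and rescaling affinely to 0-255;
4. binarize at a fixed threshold of 150 and drop connected components
   smaller than 1000 pixels (the area factor);
5. report Percent Coverage = 100 x mat pixels / ROI pixels, and the
   box-counting Fractal Dimension of the mat mask: occupied-box counts on a
   power-of-2 ladder of box sizes, slope of ln(count) against ln(1/size).

The published kernel rule sets both the Gaussian kernel side and its sigma
to "10% of the image"; read as a length, this is 10% of the shorter image
side (rounded up to odd), which is the default when no explicit values are
given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .preprocess import DegenerateInputWarning, _EIGHT_CONNECTED

__all__ = [
    "MatParams",
    "MatResult",
    "gaussian_background",
    "subtract_and_sum",
    "clip_rescale",
    "binarize_and_clean",
    "percent_coverage",
    "fractal_dimension",
    "run_mat_pipeline",
]


@dataclass(frozen=True)
class MatParams:
    """Tunables of the mat pipeline; published operating point as defaults.

    ``hsize``/``sigma`` of ``None`` means "derive from the image": 10% of
    the shorter side, hsize rounded up to odd.
    """

    hsize: int | None = None
    sigma: float | None = None
    clip_low_fraction: float = 0.10
    clip_high_fraction: float = 0.01
    fixed_threshold: float = 150.0
    area_factor: int = 1000
    box_ladder: str = "pow2"  # or "legacy" (2,3,4,6,8,12,16,32,64)

    def __post_init__(self) -> None:
        if self.hsize is not None and (self.hsize < 3 or self.hsize % 2 == 0):
            raise ValueError(f"hsize must be odd and >= 3, got {self.hsize}")
        for frac in (self.clip_low_fraction, self.clip_high_fraction):
            if not 0.0 <= frac < 0.5:
                raise ValueError("clip fractions must lie in [0, 0.5)")
        if not 0.0 <= self.fixed_threshold <= 255.0:
            raise ValueError("fixed_threshold must lie in [0, 255]")

    def resolved(self, img_shape: tuple[int, ...]) -> "MatParams":
        """Fill image-dependent defaults for a given frame."""
        short = min(img_shape[:2])
        hsize = self.hsize
        if hsize is None:
            hsize = max(3, int(round(0.10 * short)) | 1)
        sigma = self.sigma if self.sigma is not None else 0.10 * short
        return replace(self, hsize=hsize, sigma=float(sigma))


@dataclass
class MatResult:
    """ROI-restricted mat mask with its coverage and fractal-dimension audit."""

    mat_mask: np.ndarray
    percent_coverage: float
    fractal_dimension: float | None
    box_counts: pd.DataFrame | None
    intermediates: dict = field(default_factory=dict, repr=False)


def _gauss_kernel_1d(hsize: int, sigma: float) -> np.ndarray:
    x = np.arange(hsize) - hsize // 2
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_background(img: np.ndarray, params: MatParams) -> np.ndarray:
    """Per-channel convolution with a normalized ``hsize`` x ``hsize`` Gaussian.

    The kernel is the separable product of two normalized 1-D Gaussians, so
    its weights sum to one and a constant image passes through unchanged.
    Edges are handled by reflection.
    """
    img = np.asarray(img)
    p = params.resolved(img.shape)
    if p.hsize % 2 == 0:
        raise ValueError("hsize must be odd")
    k = _gauss_kernel_1d(p.hsize, p.sigma)
    out = img.astype(np.float64)
    if out.ndim == 2:
        out = out[..., None]
    blurred = np.empty_like(out)
    for c in range(out.shape[2]):
        tmp = ndi.convolve1d(out[..., c], k, axis=0, mode="reflect")
        blurred[..., c] = ndi.convolve1d(tmp, k, axis=1, mode="reflect")
    blurred = blurred[..., 0] if img.ndim == 2 else blurred
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(blurred), 0, 255).astype(img.dtype)
    return blurred


def subtract_and_sum(img: np.ndarray, background: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Channel-wise (original - background), clipped at zero, summed over channels.

    Pixels outside the ROI are zeroed.  Mats are brighter than the modelled
    background, so only positive residuals carry signal.
    """
    img = np.asarray(img, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if img.shape != background.shape or roi.shape != img.shape[:2]:
        raise ValueError("img, background and roi shapes must match")
    residual = np.clip(img - background, 0.0, None)
    summed = residual.sum(axis=-1) if residual.ndim == 3 else residual
    summed[~roi] = 0.0
    return summed


def clip_rescale(grey_map: np.ndarray, params: MatParams, roi: np.ndarray) -> np.ndarray:
    """Percentile clip then affine rescale of the in-ROI values to 0-255.

    Values below the ``clip_low_fraction`` quantile (default 10%) and above
    the ``1 - clip_high_fraction`` quantile (default 99%) of the in-ROI
    distribution are set to those quantile values, then the ROI values are
    mapped affinely onto [0, 255].  A constant map cannot be rescaled:
    all-zero output with a degenerate-input warning.
    """
    grey_map = np.asarray(grey_map, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != grey_map.shape:
        raise ValueError("roi shape must match map shape")
    vals = grey_map[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    lo = np.quantile(vals, params.clip_low_fraction)
    hi = np.quantile(vals, 1.0 - params.clip_high_fraction)
    if hi <= lo:
        warnings.warn(
            "clip_rescale: constant map over ROI, returning zeros",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return np.zeros_like(grey_map)
    out = np.clip(grey_map, lo, hi)
    out = (out - lo) * (255.0 / (hi - lo))
    out[~roi] = 0.0
    return out


def binarize_and_clean(grey_map: np.ndarray, params: MatParams, roi: np.ndarray) -> np.ndarray:
    """Fixed threshold (strict ``>``) inside the ROI, then small-area elimination.

    8-connected components with fewer than ``area_factor`` pixels (strictly
    smaller than 1000 by default) are discarded.
    """
    grey_map = np.asarray(grey_map)
    roi = np.asarray(roi, dtype=bool)
    mask = (grey_map > params.fixed_threshold) & roi
    labels, n = ndi.label(mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= params.area_factor
    keep[0] = False
    return keep[labels]


def percent_coverage(mask: np.ndarray, roi: np.ndarray) -> float:
    """Percentage of ROI pixels covered by the mat mask."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return float(100.0 * (mask & roi).sum() / n_roi)


def _resize_pow2(mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resize to S x S, S the next power of 2 >= max side."""
    h, w = mask.shape
    s = 1 << int(np.ceil(np.log2(max(h, w))))
    rows = np.minimum((np.arange(s) * h) // s, h - 1)
    cols = np.minimum((np.arange(s) * w) // s, w - 1)
    return mask[np.ix_(rows, cols)]


def fractal_dimension(
    mask: np.ndarray, ladder: str = "pow2"
) -> tuple[float, pd.DataFrame]:
    """Box-counting fractal dimension of a binary mask.

    The mask is resized (nearest neighbour, preserving occupancy) to an
    S x S grid with S the next power of 2; for every box size on the ladder
    the number of boxes containing at least one foreground pixel is counted;
    the slope of the least-squares line through (ln(1/size), ln(count)) is
    the dimension.  A space-filling mask gives 2, a one-pixel line 1.

    ``ladder='pow2'`` uses sizes S, S/2, ..., 2 (quadrant subdivision);
    ``'legacy'`` uses the fixed ladder 2,3,4,6,8,12,16,32,64 for comparison
    with older manual-processing software.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("fractal dimension of an empty mask is undefined")
    sq = _resize_pow2(mask)
    s = sq.shape[0]
    if ladder == "pow2":
        sizes = [s >> k for k in range(int(np.log2(s))) if (s >> k) >= 2]
    elif ladder == "legacy":
        sizes = [b for b in (2, 3, 4, 6, 8, 12, 16, 32, 64) if b <= s]
    else:
        raise ValueError(f"unknown box ladder {ladder!r}")

    counts = []
    for box in sizes:
        n_boxes = -(-s // box)  # ceil; ragged margin only on the legacy ladder
        padded = np.zeros((n_boxes * box, n_boxes * box), dtype=bool)
        padded[:s, :s] = sq
        occ = padded.reshape(n_boxes, box, n_boxes, box).any(axis=(1, 3))
        counts.append(int(occ.sum()))

    table = pd.DataFrame({"box_size": sizes, "occupied_boxes": counts})
    order = np.argsort(table["box_size"].to_numpy())[::-1]
    occ_sorted = table["occupied_boxes"].to_numpy()[order]
    assert (np.diff(occ_sorted) >= 0).all(), "occupied boxes must not decrease as boxes shrink"
    x = np.log(1.0 / table["box_size"].to_numpy())
    ylog = np.log(table["occupied_boxes"].to_numpy())
    slope = float(np.polyfit(x, ylog, 1)[0])
    return slope, table


def run_mat_pipeline(
    img: np.ndarray,
    roi: np.ndarray,
    params: MatParams | None = None,
    keep_intermediates: bool = False,
) -> MatResult:
    """Full mat pipeline: background, subtraction, enhancement, threshold, measures."""
    params = (params or MatParams()).resolved(np.asarray(img).shape)
    roi = np.asarray(roi, dtype=bool)
    background = gaussian_background(img, params)
    summed = subtract_and_sum(img, background, roi)
    enhanced = clip_rescale(summed, params, roi)
    mask = binarize_and_clean(enhanced, params, roi)
    cov = percent_coverage(mask, roi)
    if mask.any():
        fd, table = fractal_dimension(mask, ladder=params.box_ladder)
    else:
        fd, table = None, None
    inter = (
        {"background": background, "summed": summed, "enhanced": enhanced}
        if keep_intermediates
        else {}
    )
    return MatResult(
        mat_mask=mask,
        percent_coverage=cov,
        fractal_dimension=fd,
        box_counts=table,
        intermediates=inter,
    )
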