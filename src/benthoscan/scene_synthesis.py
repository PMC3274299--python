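"""Synthetic benthic-scene generator with known ground truth.

Real cabled-observatory photographs suffer from three nuisance factors that
drive the design of the counting and coverage pipelines: uneven illumination
from the platform lights, a temporally variable sediment texture, and water
column turbidity.  This module emulates exactly those three factors — an
illumination field modelled as a tilted plane plus radial falloff, sediment
texture as band-limited (Gaussian-smoothed) white noise, and turbidity as
additive blurred haze common to all channels — and composites two kinds of
targets onto the background:

* crab-like silhouettes (an elongated body ellipse plus thin appendage
  strokes) whose chromatic signature lives in the R-G difference, which is
  the channel the segmentation front end thresholds on;
* bright filamentous mat patches whose true in-region coverage is controlled
  to within +/-0.02 by thresholding a smoothed noise field at a quantile.

Every generator records its ground truth (centroids, masks, realized
coverage, seed) so detection and coverage estimates can be scored exactly.
All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SceneGroundTruth",
    "PlacementError",
    "make_background",
    "plant_animals",
    "plant_mat",
    "write_scene",
]

#: Default sediment base colour (R, G, B); slightly warm grey-brown.
BASE_RGB = (120.0, 110.0, 95.0)
#: Sediment texture standard deviation in grey levels.
TEXTURE_AMPLITUDE = 10.0
#: Per-channel sensor noise standard deviation in grey levels.
SENSOR_NOISE = 2.0
#: Body ellipse aspect ratio (major over minor axis) of a synthetic animal.
ANIMAL_ASPECT = 2.5


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping animals."""


@dataclass
class SceneGroundTruth:
    """Everything a scorer needs to know about a synthetic scene."""

    animal_centroids: list[tuple[float, float]] = field(default_factory=list)
    animal_masks: list[np.ndarray] = field(default_factory=list)
    mat_mask: np.ndarray | None = None
    true_coverage_fraction: float | None = None
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "animal_centroids": [[float(r), float(c)] for r, c in self.animal_centroids],
            "true_coverage_fraction": (
                None if self.true_coverage_fraction is None else float(self.true_coverage_fraction)
            ),
            "n_animals": len(self.animal_centroids),
        }


def make_background(
    height: int,
    width: int,
    illum_gradient: float = 0.4,
    texture_scale: float = 4.0,
    turbidity: float = 0.15,
    seed: int = 0,
    n_chroma_patches: int = 4,
) -> np.ndarray:
    """Generate a sediment-textured RGB background.

    Parameters
    ----------
    height, width:
        Scene size in pixels, each >= 64.
    illum_gradient:
        Peak-to-peak amplitude of the smooth illumination field as a
        fraction of full range (0-1).  The field is a random tilted plane
        blended with a radial falloff about a random off-centre light
        position.
    texture_scale:
        Correlation length (Gaussian sigma, pixels) of the sediment texture.
        ``inf`` disables texture.
    turbidity:
        Amplitude (fraction of full range) of additive blurred haze applied
        equally to all channels.
    seed:
        Random seed; the output is byte-identical for equal seeds.
    n_chroma_patches:
        Number of chromatically tinted sediment patches (stained sediment,
        settled detritus) scattered over the frame.  They carry a weak
        reddish tint, so they segment as candidate objects that a trained
        classifier must reject — the persistent confounder of real seafloor
        frames.  Disabled, like the rest of the texture model, when
        ``texture_scale`` is infinite.
    """
    if height < 64 or width < 64:
        raise ValueError(f"height and width must be >= 64, got {height}x{width}")
    if not (0.0 <= illum_gradient <= 1.0 and 0.0 <= turbidity <= 1.0):
        raise ValueError("illum_gradient and turbidity must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    rows = np.linspace(-0.5, 0.5, height)[:, None]
    cols = np.linspace(-0.5, 0.5, width)[None, :]

    # planar tilt with random orientation + radial falloff about a random light centre
    theta = rng.uniform(0, 2 * np.pi)
    plane = rows * np.sin(theta) + cols * np.cos(theta)
    cr, cc = rng.uniform(-0.3, 0.3, size=2)
    radial = -np.hypot(rows - cr, cols - cc)
    illum = 0.6 * plane + 0.4 * radial
    span = illum.max() - illum.min()
    if span > 0:
        illum = (illum - illum.min()) / span - 0.5
    illum = illum * illum_gradient * 255.0

    if np.isfinite(texture_scale):
        texture = ndi.gaussian_filter(rng.standard_normal((height, width)), texture_scale)
        sd = texture.std()
        if sd > 0:
            texture = texture / sd * TEXTURE_AMPLITUDE
    else:
        texture = np.zeros((height, width))

    if turbidity > 0:
        haze = ndi.gaussian_filter(rng.standard_normal((height, width)), 12.0)
        sd = haze.std()
        if sd > 0:
            haze = haze / sd * (turbidity * 0.25 * 255.0)
    else:
        haze = np.zeros((height, width))

    common = illum + texture + haze
    img = np.empty((height, width, 3), dtype=np.float64)
    for c, base in enumerate(BASE_RGB):
        img[..., c] = base + common

    if np.isfinite(texture_scale) and n_chroma_patches > 0:
        rows_px, cols_px = np.mgrid[0:height, 0:width].astype(float)
        for _ in range(n_chroma_patches):
            cr_p = rng.uniform(20, height - 20)
            cc_p = rng.uniform(20, width - 20)
            rad_r = rng.uniform(8, 25)
            rad_c = rng.uniform(8, 25)
            tint = rng.uniform(15, 35)
            blob = ((rows_px - cr_p) / rad_r) ** 2 + ((cols_px - cc_p) / rad_c) ** 2 <= 1.0
            img[..., 0][blob] += tint * 0.5
            img[..., 1][blob] -= tint * 0.5

    if illum_gradient > 0 or np.isfinite(texture_scale) or turbidity > 0:
        img += rng.normal(0.0, SENSOR_NOISE, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _animal_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    area: float,
    angle: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Crab-like silhouette: returns ``(body, full)`` boolean masks.

    ``body`` is the elongated ellipse carrying the chromatic signature;
    ``full`` adds the thin appendage strokes (silhouette only).
    """
    h, w = shape
    b = np.sqrt(area / (np.pi * ANIMAL_ASPECT))  # semi-minor
    a = ANIMAL_ASPECT * b  # semi-major
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rows - centre[0], cols - centre[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = body.copy()

    # thin appendages: short strokes radiating from the body front
    n_legs = rng.integers(3, 6)
    for k in range(n_legs):
        leg_angle = angle + rng.uniform(-1.2, 1.2) + (np.pi if k % 2 else 0.0)
        start = np.array(centre) + (0.8 * a) * np.array([np.cos(leg_angle), np.sin(leg_angle)])
        length = rng.uniform(0.4, 0.9) * a
        t = np.linspace(0, 1, max(int(length) * 2, 8))
        pts_r = start[0] + t * length * np.cos(leg_angle)
        pts_c = start[1] + t * length * np.sin(leg_angle)
        ok = (pts_r >= 0) & (pts_r < h) & (pts_c >= 0) & (pts_c < w)
        # single-pixel strokes: appendages are thin relative to the 7x7
        # median window and vanish in filtering, as real ones do
        mask[pts_r[ok].astype(int), pts_c[ok].astype(int)] = True
    return body, mask


def plant_animals(
    img: np.ndarray,
    n: int,
    size_range: tuple[float, float] = (400.0, 1100.0),
    chroma_offset: float = 60.0,
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Composite ``n`` non-overlapping crab-like silhouettes onto ``img``.

    The silhouettes are darker than the sediment in G and B but carry a
    mean R-G offset of ``chroma_offset`` grey levels, which is the signal
    the segmentation front end is built to pick up.  Ground truth records
    each realized mask and its centroid.
    """
    img = np.asarray(img)
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out = img.astype(np.float64).copy()
    gt = SceneGroundTruth(seed=seed)
    if n == 0:
        return img.copy(), gt

    h, w = img.shape[:2]
    occupied = np.zeros((h, w), dtype=bool)
    margin = 10
    for _ in range(n):
        placed = False
        for _attempt in range(max_retries):
            area = rng.uniform(*size_range)
            a = ANIMAL_ASPECT * np.sqrt(area / (np.pi * ANIMAL_ASPECT))
            # keep the body inside the frame; appendages may clip at borders
            pad = int(a) + margin
            if 2 * pad >= min(h, w):
                pad = min(h, w) // 2 - 1
            centre = (rng.uniform(pad, h - pad), rng.uniform(pad, w - pad))
            angle = rng.uniform(0, np.pi)
            body, mask = _animal_mask((h, w), centre, area, angle, rng)
            grown = ndi.binary_dilation(mask, iterations=margin)
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place animal {len(gt.animal_centroids) + 1} of {n} "
                f"after {max_retries} retries"
            )
        occupied |= grown
        # chromatic signature decoupled from the illumination field: the
        # offset is split between a raised R and a lowered G about the local
        # background so mean(R-G) over the body equals chroma_offset; thin
        # appendages carry no chromatic mass (they darken in B only, like
        # the translucent legs of the real animal)
        r_bg, g_bg = out[..., 0][body].mean(), out[..., 1][body].mean()
        delta = chroma_offset - (r_bg - g_bg)
        out[..., 0][body] += delta * 0.5
        out[..., 1][body] -= delta * 0.5
        out[..., 2][mask] *= 0.8
        rr, cc = np.nonzero(mask)
        gt.animal_centroids.append((float(rr.mean()), float(cc.mean())))
        gt.animal_masks.append(mask)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), gt


#: Minimum filament density inside a mat patch; above the percolation point
#: of the contour band so the web stays connected.
MAT_DENSITY_FLOOR = 0.40
#: Correlation length (px) of the filament field: strands a couple of pixels wide.
MAT_FILAMENT_SCALE = 1.5
#: Correlation length (px) of the patch envelope that localizes sparse mats.
MAT_ENVELOPE_SCALE = 50.0
#: Grey value of saturated mat pixels (reflective white under the flash).
MAT_WHITE = 252.0
#: Illumination amplitude of mat-survey scenes (flash-dominated, even light).
MAT_SCENE_ILLUMINATION = 0.15


def plant_mat(
    img: np.ndarray,
    roi: np.ndarray,
    target_coverage: float,
    patch_scale: float = MAT_ENVELOPE_SCALE,
    seed: int = 0,
    filament_scale: float = MAT_FILAMENT_SCALE,
    density_floor: float = MAT_DENSITY_FLOOR,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Overlay a filamentous mat web inside ``roi`` with controlled coverage.

    Bacterial mats are lacy networks of thin white filaments, not solid
    blobs.  The mask is the contour band of a smoothed noise field —
    ``|field|`` below a quantile — which stays globally connected down to
    low densities; when the requested coverage is below ``density_floor``
    the web is confined to an envelope of patches (correlation length
    ``patch_scale``) at that floor density, so patches keep a realistic
    local filament density instead of thinning out uniformly.  Both
    thresholds are in-ROI quantiles, so realized coverage tracks the target
    within quantile discretization (well inside +/-0.02).  Mat pixels are
    set to saturated white, as reflective filaments photograph under flash.
    """
    img = np.asarray(img)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape[:2]:
        raise ValueError("roi shape must match image shape")
    if not roi.any():
        raise ValueError("ROI is empty")
    if not 0.0 <= target_coverage <= 1.0:
        raise ValueError("target_coverage must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    gt = SceneGroundTruth(seed=seed)
    h, w = roi.shape
    if target_coverage == 0.0:
        mat = np.zeros((h, w), dtype=bool)
    elif target_coverage == 1.0:
        mat = roi.copy()
    else:
        density = max(density_floor, target_coverage)
        envelope_fraction = target_coverage / density
        coarse = ndi.gaussian_filter(rng.standard_normal((h, w)), patch_scale)
        if envelope_fraction < 1.0:
            env = roi & (coarse > np.quantile(coarse[roi], 1.0 - envelope_fraction))
        else:
            env = roi.copy()
        fine = np.abs(ndi.gaussian_filter(rng.standard_normal((h, w)), filament_scale))
        mat = env & (fine < np.quantile(fine[env], density))

    out = img.astype(np.float64).copy()
    out[mat] = MAT_WHITE
    gt.mat_mask = mat
    gt.true_coverage_fraction = float(mat.sum() / roi.sum())
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), gt


def make_mat_scene(
    height: int,
    width: int,
    target_coverage: float,
    seed: int = 0,
    roi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, SceneGroundTruth]:
    """Background plus planted mat under the mat-survey conditions.

    Mat-survey frames are flash-dominated and evenly lit (the coverage ROI
    is placed in the well-illuminated part of the frame), so the background
    uses ``MAT_SCENE_ILLUMINATION`` rather than the harsher default of the
    animal scenes.  Returns ``(image, roi, ground_truth)``.
    """
    bg = make_background(height, width, illum_gradient=MAT_SCENE_ILLUMINATION, seed=seed)
    if roi is None:
        roi = np.ones((height, width), dtype=bool)
    img, gt = plant_mat(bg, roi, target_coverage, seed=seed)
    return img, roi, gt


def write_scene(path: str | Path, img: np.ndarray, gt: SceneGroundTruth) -> Path:
    """Write a scene PNG plus its JSON ground-truth sidecar (``<stem>.json``)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, img)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(gt.to_json_dict(), indent=1))
    return sidecar
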