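"""Fourier descriptors of object outlines and the RGBv+FD feature table.

A closed outline is resampled to 128 arc-length-equidistant points, read as
the complex sequence ``z_k = col_k + i * row_k`` and Fourier transformed.
Dropping the DC term makes the descriptor translation invariant, dividing by
the modulus of the first harmonic makes it scale invariant, and taking
magnitudes discards both the global phase (rotation) and the linear phase
ramp (starting point).  The 128-value vector packs the magnitudes of
harmonics +1..+64 followed by -1..-64; with a 128-point transform the +64
and -64 harmonics share the Nyquist bin, so its magnitude appears in both
halves.  The 60 lowest-frequency magnitudes (harmonics +/-1..+/-30) are the
named shape descriptors used for reporting.

Feature tables pair each object's 3 mean-RGB values with its 128 FD values,
giving the 131-column input of the discriminant classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DetectedObject

__all__ = [
    "FdVector",
    "N_CONTOUR_POINTS",
    "resample_contour",
    "fourier_descriptors",
    "compute_fd",
    "build_feature_matrix",
    "FEATURE_COLUMNS",
]

N_CONTOUR_POINTS = 128
N_DESCRIPTORS = 60

FEATURE_COLUMNS = ["mean_r", "mean_g", "mean_b"] + [f"fd_{i:03d}" for i in range(128)]


@dataclass(frozen=True)
class FdVector:
    """Normalized Fourier-descriptor magnitudes of one outline."""

    values: np.ndarray  # shape (128,)

    @property
    def descriptors(self) -> np.ndarray:
        """The 60 named low-frequency descriptors: harmonics +/-1 .. +/-30."""
        half = N_CONTOUR_POINTS // 2
        out = np.empty(N_DESCRIPTORS)
        out[0::2] = self.values[: N_DESCRIPTORS // 2]  # +1..+30
        out[1::2] = self.values[half : half + N_DESCRIPTORS // 2]  # -1..-30
        return out


def _as_closed(contour: np.ndarray) -> np.ndarray:
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2:
        raise ValueError(f"contour must be (K, 2), got shape {contour.shape}")
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    if len(np.unique(contour[:-1], axis=0)) < 3:
        raise ValueError("contour must have at least 3 distinct points")
    return contour


def resample_contour(contour: np.ndarray, n_points: int = N_CONTOUR_POINTS) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` equally spaced by arc length.

    Accepts the contour with or without the closing duplicate point and
    returns an ``(n_points, 2)`` array whose closure is implicit (the first
    point is kept as the starting point; the segment from the last sample
    back to the first closes the loop).
    """
    closed = _as_closed(contour)
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = seg.sum()
    if perimeter <= 0:
        raise ValueError("degenerate zero-length contour")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * (perimeter / n_points)
    rows = np.interp(targets, cum, closed[:, 0])
    cols = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([rows, cols])


def fourier_descriptors(contour: np.ndarray) -> FdVector:
    """Translation/scale/rotation/start-point-invariant descriptor of a contour.

    ``contour`` must already be resampled to 128 points (closing duplicate
    tolerated).  Raises on shorter input rather than resampling silently.
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) == N_CONTOUR_POINTS + 1 and np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if contour.shape != (N_CONTOUR_POINTS, 2):
        raise ValueError(
            f"contour must hold exactly {N_CONTOUR_POINTS} points, got {contour.shape}"
        )
    z = contour[:, 1] + 1j * contour[:, 0]
    zf = np.fft.fft(z)
    ref = np.abs(zf[1])
    if ref == 0:
        raise ValueError("degenerate contour: vanishing first harmonic")
    mag = np.abs(zf) / ref
    half = N_CONTOUR_POINTS // 2
    positive = mag[1 : half + 1]  # harmonics +1 .. +64
    negative = mag[N_CONTOUR_POINTS - 1 : half - 1 : -1]  # harmonics -1 .. -64 (Nyquist shared)
    return FdVector(values=np.concatenate([positive, negative]))


def compute_fd(obj: DetectedObject) -> DetectedObject:
    """Attach the FD vector to a detected object (in place) and return it."""
    resampled = resample_contour(obj.contour, N_CONTOUR_POINTS)
    obj.fd = fourier_descriptors(resampled).values
    return obj


def build_feature_matrix(objects: list[DetectedObject]) -> pd.DataFrame:
    """Assemble the classifier input table: columns mean_r, mean_g, mean_b, fd_000..fd_127.

    Row order preserves object order.  Objects missing their FD vector are
    reported by index rather than silently dropped.
    """
    rows = []
    for i, obj in enumerate(objects):
        if obj.fd is None:
            raise ValueError(f"object {i} (label {obj.label}) has no FD vector; run compute_fd")
        if obj.mean_rgb is None:
            raise ValueError(f"object {i} (label {obj.label}) has no mean RGB")
        rows.append(np.concatenate([np.asarray(obj.mean_rgb, dtype=float), obj.fd]))
    data = np.vstack(rows) if rows else np.empty((0, len(FEATURE_COLUMNS)))
    return pd.DataFrame(data, columns=FEATURE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table to CSV with full float64 round-trip precision."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, float_precision="round_trip")


def write_contour(contour: np.ndarray, path) -> None:
    """Dump a contour as plain ``row col`` text, one point per line (debugging aid)."""
    np.savetxt(path, np.asarray(contour, dtype=float), fmt="%.17g")


def read_contour(path) -> np.ndarray:
    """Read a contour written by :func:`write_contour`."""
    return np.loadtxt(path, ndmin=2)
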