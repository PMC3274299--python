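"""Discriminant classifiers for squat-lobster recognition.

Two class-modelling routes are provided:

* **PLSDA** — partial least squares regression of two complementary dummy
  class columns ("belonging" / "not belonging") on the mean-centred feature
  block, latent vectors extracted sequentially by NIPALS so that each
  maximizes the residual X-Y covariance.  Classification is by argmax of
  the predicted dummy pair.  Calibration quality is reported as RMSEC
  (root mean square of the dummy residuals over the calibration rows),
  cross-validated RMSECV, per-class sensitivity and specificity, and the
  percent correctly classified on the calibration and test rows.

* **Euclidean-distance class model** — an object belongs when its mean-RGB
  vector AND its Fourier-descriptor vector each lie within a calibrated
  distance threshold of the class centroid.  The two thresholds are
  independent and default to the 95th percentile of within-class training
  distances.

Calibration/test splitting uses the Kennard-Stone maximin algorithm so the
calibration set spans the feature space rather than sampling it randomly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlsdaModel",
    "CalibrationReport",
    "EdClassModel",
    "kennard_stone_split",
    "plsda_fit",
    "plsda_predict",
    "ed_fit",
    "ed_classify",
    "count_munida",
    "sensitivity_specificity",
]

CLASS_LABELS = ("belonging", "not_belonging")

#: Latent-vector counts of the two published operating points.
DEFAULT_N_LV_SIFT = 18
DEFAULT_N_LV_FD = 10


# ---------------------------------------------------------------------------
# Kennard-Stone calibration-set selection
# ---------------------------------------------------------------------------

def kennard_stone_split(
    X: np.ndarray | pd.DataFrame, train_fraction: float = 0.7
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic maximin split into calibration and test indices.

    The most mutually distant pair of rows seeds the calibration set; each
    following pick maximizes its minimum Euclidean distance to the rows
    already selected, until ``ceil(train_fraction * n)`` rows are chosen.
    Ties break towards the lowest row index, so the outcome is reproducible
    and (up to index relabelling) invariant to row order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(X), -1)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    n_train = int(np.ceil(train_fraction * n))

    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    # seed: the most distant pair, lowest indices on ties
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < n_train and remaining:
        cand = remaining[int(np.argmax(min_d2[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_d2 = np.minimum(min_d2, d2[cand])
    return np.array(sorted(selected[:n_train])), np.array(sorted(remaining))


# ---------------------------------------------------------------------------
# PLSDA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """Fitted PLSDA model: mean offsets, NIPALS structures, regression coefficients."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # (p, n_lv)
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (2, n_lv)
    n_lv: int
    regression_coefficients: np.ndarray  # (p, 2)
    class_labels: tuple[str, str] = CLASS_LABELS


@dataclass
class CalibrationReport:
    rmsec: float
    rmsecv: float | None
    sensitivity_pct: dict[str, float]
    specificity_pct: dict[str, float]
    correct_model_pct: float
    correct_test_pct: float | None = None


def _dummy_matrix(y: np.ndarray) -> np.ndarray:
    """Two complementary 1/0 columns, one per class in CLASS_LABELS order."""
    Y = np.zeros((len(y), 2))
    Y[:, 0] = y == CLASS_LABELS[0]
    Y[:, 1] = y == CLASS_LABELS[1]
    return Y


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_lv: int, tol: float = 1e-12, max_iter: int = 500):
    """Sequential NIPALS extraction of ``n_lv`` latent vectors from centred blocks."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Yc.shape[1], n_lv))
    X, Y = Xc.copy(), Yc.copy()
    extracted = 0
    for a in range(n_lv):
        # start u from the Y column of largest variance
        u = Y[:, np.argmax(np.var(Y, axis=0))].copy()
        if np.allclose(Y, 0) or np.allclose(X, 0):
            break
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t = X @ w
            tt = t @ t
            if tt == 0:
                break
            q = Y.T @ t / tt
            qn = np.linalg.norm(q)
            if qn == 0:
                break
            u = Y @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        else:  # pragma: no cover - convergence is immediate for rank-1 Y
            pass
        if norm == 0 or tt == 0:
            break
        p_load = X.T @ t / tt
        W[:, a], P[:, a], Q[:, a] = w, p_load, q
        X = X - np.outer(t, p_load)
        Y = Y - np.outer(t, q)
        extracted = a + 1
    return W[:, :extracted], P[:, :extracted], Q[:, :extracted], extracted


def _fit_core(Xc: np.ndarray, Yc: np.ndarray, n_lv: int):
    W, P, Q, extracted = _nipals(Xc, Yc, n_lv)
    if extracted == 0:
        raise ValueError("no latent vector could be extracted (degenerate X block)")
    # B maps centred X to centred Y: B = W (P'W)^-1 Q'
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return W, P, Q, extracted, B


def plsda_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | list,
    n_lv: int = DEFAULT_N_LV_FD,
    cv: str = "auto",
    seed: int = 0,
) -> tuple[PlsdaModel, CalibrationReport]:
    """Fit PLSDA on a feature table and binary class labels.

    ``y`` holds the strings of :data:`CLASS_LABELS` (or booleans, True =
    belonging).  ``n_lv`` beyond the rank of the centred X block is
    truncated with a warning.  ``cv`` selects the RMSECV scheme: leave-one-
    out below 500 rows, seeded 10-fold above (``'loo'``, ``'kfold'`` or
    ``'none'`` force a scheme).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype == bool:
        y = np.where(y, CLASS_LABELS[0], CLASS_LABELS[1])
    if set(np.unique(y)) != set(CLASS_LABELS):
        raise ValueError(f"y must contain both classes {CLASS_LABELS}")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    n, p = X.shape

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_lv > rank:
        warnings.warn(
            f"n_lv={n_lv} exceeds rank {rank} of the centred X block; truncating",
            UserWarning,
            stacklevel=2,
        )
        n_lv = rank
    Y = _dummy_matrix(y)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W, P, Q, extracted, B = _fit_core(Xc, Yc, n_lv)
    model = PlsdaModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P, y_loadings=Q,
        n_lv=extracted, regression_coefficients=B,
    )

    pred_classes, scores = plsda_predict(model, X)
    rmsec = float(np.sqrt(np.mean((scores - Y) ** 2)))
    rmsecv = _rmsecv(X, y, extracted, scheme=cv, seed=seed)
    if rmsecv is not None and rmsec > rmsecv:
        warnings.warn("RMSEC exceeds RMSECV; model may be under-fitted", UserWarning, stacklevel=2)

    sens, spec = sensitivity_specificity(y, pred_classes)
    report = CalibrationReport(
        rmsec=rmsec,
        rmsecv=rmsecv,
        sensitivity_pct=sens,
        specificity_pct=spec,
        correct_model_pct=float(100.0 * np.mean(pred_classes == y)),
    )
    return model, report


def _rmsecv(X: np.ndarray, y: np.ndarray, n_lv: int, scheme: str, seed: int) -> float | None:
    n = len(X)
    if scheme == "none":
        return None
    if scheme == "auto":
        scheme = "loo" if n < 500 else "kfold"
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(n), 10)
    else:
        raise ValueError(f"unknown cv scheme {scheme!r}")
    Y = _dummy_matrix(y)
    sq_sum, count = 0.0, 0
    for hold in folds:
        keep = np.setdiff1d(np.arange(n), hold)
        if len(set(y[keep])) < 2:
            continue
        Xk, Yk = X[keep], Y[keep]
        xm, ym = Xk.mean(axis=0), Yk.mean(axis=0)
        try:
            _, _, _, _, B = _fit_core(Xk - xm, Yk - ym, min(n_lv, len(keep) - 1))
        except ValueError:
            continue
        pred = ym + (X[hold] - xm) @ B
        sq_sum += np.sum((pred - Y[hold]) ** 2)
        count += pred.size
    return float(np.sqrt(sq_sum / count)) if count else None


def plsda_predict(
    model: PlsdaModel, X: np.ndarray | pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predict class per row: dummy scores from centred X, class by argmax."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.x_mean):
        raise ValueError(
            f"feature count {X.shape[1]} does not match training ({len(model.x_mean)})"
        )
    scores = model.y_mean + (X - model.x_mean) @ model.regression_coefficients
    classes = np.array([model.class_labels[i] for i in np.argmax(scores, axis=1)])
    return classes, scores


def sensitivity_specificity(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-class sensitivity (accepted members %) and specificity (rejected non-members %)."""
    sens, spec = {}, {}
    for cls in CLASS_LABELS:
        in_cls = y_true == cls
        sens[cls] = float(100.0 * np.mean(y_pred[in_cls] == cls)) if in_cls.any() else float("nan")
        out_cls = ~in_cls
        spec[cls] = float(100.0 * np.mean(y_pred[out_cls] != cls)) if out_cls.any() else float("nan")
    return sens, spec


# ---------------------------------------------------------------------------
# Euclidean-distance class model
# ---------------------------------------------------------------------------

@dataclass
class EdClassModel:
    """Centroid-plus-threshold class model with independent RGB and FD gates."""

    class_centroid_rgb: np.ndarray  # (3,)
    class_centroid_fd: np.ndarray  # (128,)
    threshold_rgb: float
    threshold_fd: float


def ed_fit(
    rgbv: np.ndarray, fd: np.ndarray, threshold_percentile: float = 95.0
) -> EdClassModel:
    """Calibrate the ED class model from within-class training vectors.

    Centroids are feature means; each threshold is the given percentile of
    the training samples' distances to their own centroid, so roughly that
    share of genuine members falls inside the gate.
    """
    rgbv = np.atleast_2d(np.asarray(rgbv, dtype=float))
    fd = np.atleast_2d(np.asarray(fd, dtype=float))
    c_rgb = rgbv.mean(axis=0)
    c_fd = fd.mean(axis=0)
    d_rgb = np.linalg.norm(rgbv - c_rgb, axis=1)
    d_fd = np.linalg.norm(fd - c_fd, axis=1)
    thr_rgb = float(np.percentile(d_rgb, threshold_percentile))
    thr_fd = float(np.percentile(d_fd, threshold_percentile))
    return EdClassModel(c_rgb, c_fd, max(thr_rgb, 1e-12), max(thr_fd, 1e-12))


def ed_classify(model: EdClassModel, rgbv: np.ndarray, fd: np.ndarray) -> str:
    """Belonging iff both the RGB and the FD distances fall within their thresholds."""
    rgbv = np.asarray(rgbv, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if rgbv.shape != model.class_centroid_rgb.shape:
        raise ValueError(f"rgbv length {rgbv.shape} != {model.class_centroid_rgb.shape}")
    if fd.shape != model.class_centroid_fd.shape:
        raise ValueError(f"fd length {fd.shape} != {model.class_centroid_fd.shape}")
    d_rgb = float(np.linalg.norm(rgbv - model.class_centroid_rgb))
    d_fd = float(np.linalg.norm(fd - model.class_centroid_fd))
    belongs = d_rgb <= model.threshold_rgb and d_fd <= model.threshold_fd
    return CLASS_LABELS[0] if belongs else CLASS_LABELS[1]


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_munida(
    method: str,
    objects=None,
    features=None,
    plsda: PlsdaModel | None = None,
    ed_model: EdClassModel | None = None,
    min_features: int = 7,
    link_distance: float = 500.0,
) -> int:
    """Count animals in one image with the chosen terminal branch.

    ``fd_plsda`` / ``fd_ed``: the count is the number of segmented objects
    classified as belonging (by PLSDA on the 131-column RGBv+FD table, or by
    the two-gate ED model).  ``sift_plsda``: keypoint features are
    classified by PLSDA on their 128 descriptor bins and the belonging ones
    grouped by the clustering rule of
    :func:`benthoscan.keypoints.count_animals_from_features`.
    """
    from .keypoints import count_animals_from_features
    from .shape_features import build_feature_matrix

    if method in ("fd_plsda", "fd_ed"):
        if objects is None:
            raise ValueError(f"method {method!r} needs detected objects")
        if not objects:
            return 0
        if method == "fd_plsda":
            if plsda is None:
                raise ValueError("fd_plsda needs a fitted PlsdaModel")
            table = build_feature_matrix(objects)
            classes, _ = plsda_predict(plsda, table.to_numpy())
            return int(np.sum(classes == CLASS_LABELS[0]))
        if ed_model is None:
            raise ValueError("fd_ed needs a fitted EdClassModel")
        return sum(
            1
            for o in objects
            if ed_classify(ed_model, np.asarray(o.mean_rgb), o.fd) == CLASS_LABELS[0]
        )
    if method == "sift_plsda":
        if features is None:
            raise ValueError("sift_plsda needs keypoint features")
        if plsda is None:
            raise ValueError("sift_plsda needs a fitted PlsdaModel")
        if not features:
            return 0
        desc = np.array([f.descriptor for f in features], dtype=float)
        classes, _ = plsda_predict(plsda, desc)
        kept = [f for f, c in zip(features, classes) if c == CLASS_LABELS[0]]
        return count_animals_from_features(
            kept, min_features=min_features, link_distance=link_distance
        )
    raise ValueError(f"unknown counting method {method!r}")
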