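"""Plain-text serialization of trained model bundles.

A bundle directory holds a ``manifest.json`` with scalar metadata (method,
latent-vector count, class labels, thresholds) and one ``.csv`` file per
array (mean vectors, weights, loadings, regression coefficients,
centroids).  Everything round-trips exactly through numpy's text I/O.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classify import EdClassModel, PlsdaModel
from .pipeline import ModelBundle

__all__ = ["save_model_bundle", "load_model_bundle"]

_FMT = "%.17g"  # round-trips float64 exactly


def _save_array(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(arr, dtype=float)), fmt=_FMT, delimiter=",")


def _load_array(path: Path, squeeze: bool = False) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr.ravel() if squeeze else arr


def save_model_bundle(directory: str | Path, bundle: ModelBundle) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"method": bundle.method}
    if bundle.plsda is not None:
        m = bundle.plsda
        manifest["plsda"] = {"n_lv": m.n_lv, "class_labels": list(m.class_labels)}
        _save_array(directory / "x_mean.csv", m.x_mean)
        _save_array(directory / "y_mean.csv", m.y_mean)
        _save_array(directory / "weights.csv", m.weights)
        _save_array(directory / "x_loadings.csv", m.x_loadings)
        _save_array(directory / "y_loadings.csv", m.y_loadings)
        _save_array(directory / "regression_coefficients.csv", m.regression_coefficients)
    if bundle.ed_model is not None:
        e = bundle.ed_model
        manifest["ed"] = {"threshold_rgb": e.threshold_rgb, "threshold_fd": e.threshold_fd}
        _save_array(directory / "centroid_rgb.csv", e.class_centroid_rgb)
        _save_array(directory / "centroid_fd.csv", e.class_centroid_fd)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_model_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    plsda = ed_model = None
    if "plsda" in manifest:
        meta = manifest["plsda"]
        plsda = PlsdaModel(
            x_mean=_load_array(directory / "x_mean.csv", squeeze=True),
            y_mean=_load_array(directory / "y_mean.csv", squeeze=True),
            weights=_load_array(directory / "weights.csv"),
            x_loadings=_load_array(directory / "x_loadings.csv"),
            y_loadings=_load_array(directory / "y_loadings.csv"),
            n_lv=int(meta["n_lv"]),
            regression_coefficients=_load_array(directory / "regression_coefficients.csv"),
            class_labels=tuple(meta["class_labels"]),
        )
    if "ed" in manifest:
        meta = manifest["ed"]
        ed_model = EdClassModel(
            class_centroid_rgb=_load_array(directory / "centroid_rgb.csv", squeeze=True),
            class_centroid_fd=_load_array(directory / "centroid_fd.csv", squeeze=True),
            threshold_rgb=float(meta["threshold_rgb"]),
            threshold_fd=float(meta["threshold_fd"]),
        )
    return ModelBundle(method=manifest["method"], plsda=plsda, ed_model=ed_model)
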