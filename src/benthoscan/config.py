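"""Run configuration: every tunable of every stage, with the published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Flat bundle of all pipeline parameters.

    The defaults reproduce the published operating point end to end:
    7x7 median filter applied three times, top-hat of dimension 25,
    95th-percentile segmentation, object area gate [200, 150000],
    SIFT 9 octaves / 3 levels / peak 3 / edge 7, clusters of more than 6
    features within 500 px, mat threshold 150 with area factor 1000 and
    10%/1% contrast clips.
    """

    # munida.preprocess
    median_window: int = 7
    median_passes: int = 3
    tophat_size: int = 25
    tophat_shape: str = "disc"
    percentile: float = 95.0
    min_area: int = 200
    max_area: int = 150_000
    # munida.sift
    n_octaves: int = 9
    levels_per_octave: int = 3
    peak_threshold: float = 3.0
    edge_threshold: float = 7.0
    min_features: int = 7
    link_distance: float = 500.0
    linkage: str = "single"
    # munida.classify
    train_fraction: float = 0.7
    n_lv_fd: int = 10
    n_lv_sift: int = 18
    ed_threshold_percentile: float = 95.0
    # mat
    mat_hsize: int | None = None
    mat_sigma: float | None = None
    clip_low_fraction: float = 0.10
    clip_high_fraction: float = 0.01
    fixed_threshold: float = 150.0
    area_factor: int = 1000
    box_ladder: str = "pow2"
    # evaluate
    match_radius: float = 50.0
    # run
    method: str = "fd_plsda"
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys in the file are rejected so typos cannot silently fall
    back to defaults.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        # accept either a flat mapping or the documented sections
        for key, val in raw.items():
            if isinstance(val, dict):
                values.update(val)
            else:
                values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
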