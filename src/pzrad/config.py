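"""Run configuration.

A :class:`RunConfig` carries every tunable of the pipeline: the channel
configuration, window sizes, GLCM levels, CFS stopping patience, Bayesian
optimization budget and bounds, and the master seed.  Defaults follow the
study design the pipeline implements: a 9 x 9 feature window, 3 x 3 median
filter, 10-fold cross-validation, 30 optimization evaluations, and
hyperparameter bounds [1e-4, 1e3].
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

#: scalar channels per configuration; DTI inclusion handled separately
CHANNEL_CONFIGS: dict[str, tuple[str, ...]] = {
    "T2": ("t2w",),
    "DWI": ("dwi_highb", "adc"),
    "T2+DWI": ("t2w", "dwi_highb", "adc"),
    "T2+DTI": ("t2w",),
    "T2+DWI+DTI": ("t2w", "dwi_highb", "adc"),
}

#: expected feature-matrix column counts (57 per scalar channel + 20 DTI)
EXPECTED_FEATURE_COUNTS: dict[str, int] = {
    "T2": 57,
    "DWI": 114,
    "T2+DWI": 171,
    "T2+DTI": 77,
    "T2+DWI+DTI": 191,
}


@dataclass
class RunConfig:
    """All pipeline parameters for one run."""

    channel_config: str = "T2+DWI+DTI"
    window: int = 9                 # sliding window for first-order and GLCM
    glcm_levels: int = 32
    first_order_bins: int = 64
    median_window: int = 3
    standardize_channels: tuple[str, ...] = ("t2w",)
    median_filter_channels: tuple[str, ...] = ("t2w",)
    cfs_patience: int = 5
    bo_iterations: int = 30
    bo_folds: int = 10
    bo_bounds: tuple[float, float] = (1e-4, 1e3)
    max_train_voxels: int = 1600    # per-fold training subsample cap (0 = off)
    min_lesion_volume_cc: float = 0.25
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.channel_config not in CHANNEL_CONFIGS:
            raise ValueError(
                f"unknown channel configuration {self.channel_config!r}; "
                f"expected one of {sorted(CHANNEL_CONFIGS)}"
            )
        lo, hi = self.bo_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid hyperparameter bounds {self.bo_bounds}")

    @property
    def scalar_channels(self) -> tuple[str, ...]:
        return CHANNEL_CONFIGS[self.channel_config]

    @property
    def include_dti(self) -> bool:
        return "DTI" in self.channel_config

    @property
    def expected_feature_count(self) -> int:
        return EXPECTED_FEATURE_COUNTS[self.channel_config]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["standardize_channels"] = list(self.standardize_channels)
        d["median_filter_channels"] = list(self.median_filter_channels)
        d["bo_bounds"] = list(self.bo_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("standardize_channels", "median_filter_channels", "bo_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
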