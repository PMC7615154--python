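"""Run configuration: one serializable object that every stage reads.

A ``RunConfig`` round-trips through YAML (load -> save -> load identical)
and hashes to a short hex digest recorded with every output, so any config
change is visible in the artifacts it produced.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    ``design`` holds ScreenDesign overrides; ``optics`` holds image
    geometry/noise overrides; stage seeds are derived from ``seed`` unless
    set explicitly in ``stage_seeds``.
    """

    seed: int = 0
    stage_seeds: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    effects: dict = field(
        default_factory=lambda: {"delivery_multiplier": 1.5, "feature_shift": 1.5}
    )
    simulate: dict = field(
        default_factory=lambda: {"noise_cv": 0.15, "n_cells_per_well": 9, "render_images": True}
    )
    segmentation: dict = field(
        default_factory=lambda: {
            "smoothing_sigma": 2.0,
            "min_area_px": 40,
            "max_expansion_px": 15.0,
            "n_zones": 4,
        }
    )
    spots: dict = field(
        default_factory=lambda: {"sigma_range": [1.0, 5.0], "threshold_c": 5.0, "min_distance": 3}
    )
    normalization: dict = field(default_factory=lambda: {"method": "ratio", "n_sd": 3.0})
    ml: dict = field(
        default_factory=lambda: {
            "train_fraction": 0.8,
            "n_features": 10,
            "smote_k": 5,
            "rfe_step": 0.1,
        }
    )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed: explicit override or a stable
        offset from the global seed (kept below 2**31)."""
        if stage in self.stage_seeds:
            return int(self.stage_seeds[stage])
        offset = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:2], "big")
        return (int(self.seed) * 1009 + offset) % (2**31)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
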