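"""YAML configuration loading for the command-line pipeline.

The file is a flat mapping of sections; every key is optional and
defaults to the library defaults.  Example::

    seed: 7
    scenario:
      rows: 100
      cols: 100
      noise_sd: 0.15
    crop:
      lai_init: 0.3
      tt_senescence: 900
    dtw:
      band_radius_r: 3
      local_distance: absolute
    weights: row
    output_dir: out/
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .crop import CropParams, PSOConfig
from .dtw import DTWConfig
from .errors import InvalidInputError
from .scenes import ScenarioConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    crop_params: CropParams = field(default_factory=CropParams)
    dtw: DTWConfig = field(default_factory=DTWConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    weight_scheme: str = "row"
    output_dir: Path = Path("out")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config {path} must be a YAML mapping")
    seed = int(raw.get("seed", 0))
    crop = CropParams(**raw.get("crop", {}))
    scenario_kwargs = dict(raw.get("scenario", {}))
    scenario_kwargs.setdefault("seed", seed)
    scenario = ScenarioConfig(crop_params=crop, **scenario_kwargs)
    dtw = DTWConfig(**raw.get("dtw", {}))
    pso_kwargs = dict(raw.get("pso", {}))
    pso_kwargs.setdefault("seed", seed)
    pso = PSOConfig(**pso_kwargs)
    return PipelineConfig(
        seed=seed,
        scenario=scenario,
        crop_params=crop,
        dtw=dtw,
        pso=pso,
        weight_scheme=raw.get("weights", "row"),
        output_dir=Path(raw.get("output_dir", "out")),
    )
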