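"""Run configuration: one YAML file, stage-namespaced keys.

Defaults mirror the analysis parameters used throughout: 3x background
filter, ROUT Q = 0.2%, differential FDR < 0.01, Euclidean clustering with
silhouette-selected k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "KNOWN_STAGES"]

KNOWN_STAGES = ("simulate", "quant", "kinetics", "exchange", "stress",
                "sasa", "occupancy")

_DEFAULTS: dict[str, dict] = {
    "simulate": {"experiment": "kinetics", "noise_cv": 0.10,
                 "n_biological": None},
    "quant": {"input": None, "no_label_condition": None,
              "background_factor": 3.0, "treated": None, "control": None},
    "kinetics": {"conditions": None, "k": "auto", "k_max": 10,
                 "linkage": "complete", "no_chase_conditions": None,
                 "pulse_condition": None, "chase_condition": None},
    "exchange": {"q": 0.2, "subunits": None},
    "stress": {"treated": None, "control": None, "fdr": 0.01,
               "normalize": True},
    "sasa": {"pdb": None, "groups": None, "probe": 1.4, "n_points": 960},
    "occupancy": {"input": None, "k": "auto"},
}


@dataclass
class RunConfig:
    """Validated configuration for :func:`riboswap.pipeline.run_pipeline`."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not self.stages:
            raise ValueError("no stages selected")
        self.out_dir = Path(self.out_dir)
        merged: dict[str, dict] = {}
        for stage in KNOWN_STAGES:
            merged[stage] = dict(_DEFAULTS[stage])
            for key, value in (self.params.get(stage) or {}).items():
                if key not in merged[stage]:
                    raise ValueError(
                        f"unknown parameter {key!r} for stage {stage!r}")
                merged[stage][key] = value
        self.params = merged
        self._check_paths()

    def _check_paths(self) -> None:
        needs_file = {
            "quant": ["input"], "sasa": ["pdb", "groups"],
            "occupancy": ["input"],
        }
        for stage, keys in needs_file.items():
            if stage not in self.stages:
                continue
            for key in keys:
                value = self.params[stage][key]
                if value is None:
                    continue  # may be produced by an earlier stage
                if not Path(value).exists():
                    raise FileNotFoundError(
                        f"{stage}.{key}: {value} does not exist")

    def __getitem__(self, stage: str) -> dict:
        return self.params[stage]


def load_config(path) -> RunConfig:
    """Read a YAML run configuration.

    Top-level keys: ``stages`` (list), ``out_dir``, ``seed`` and one
    mapping per stage with that stage's parameters.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    stages = raw.pop("stages", None)
    if not stages:
        raise ValueError("config must list the stages to run")
    out_dir = raw.pop("out_dir", "riboswap_run")
    seed = int(raw.pop("seed", 0))
    unknown = set(raw) - set(KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return RunConfig(stages=list(stages), out_dir=out_dir, seed=seed,
                     params=raw)
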