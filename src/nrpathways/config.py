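"""Pipeline configuration: explicit seeds, chemistry, scenarios, guidelines, costs.

Configs are plain YAML mappings mirroring :class:`PipelineConfig`; unknown keys
raise a warning rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .costs import CostScenario


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, with explicit seeds."""

    n_lat: int = 10
    n_lon: int = 14
    n_level: int = 1
    seed: int = 0
    total_nh3: float = 4.4   # Tg N yr-1
    total_nox: float = 3.7   # Tg N yr-1
    total_pop: float = 4.5e8
    # chemistry surrogate
    a_tot: float = 5.0
    n_tot: float = 1.4
    p_ox: float = 2.0
    s_fix: float = 0.025
    eps: dict = field(default_factory=lambda: {"Jan": 0.9, "Apr": 0.8, "Jul": 0.3, "Oct": 0.8})
    sharpness: float | None = 25.0
    # scenarios
    levels: tuple = (0.3, 0.6, 0.8, 1.0)
    # health
    gemm_params_file: str | None = None
    n_draws: int = 10_000
    # metrics
    annual_guideline: float = 5.0
    daily_guideline: float = 15.0
    daily_cv: float = 0.35
    # costs: list of [species, region, reduction, annual_cost]; None = defaults
    cost_anchors: list | None = None
    outdir: str = "runs/default"

    def __post_init__(self) -> None:
        if self.annual_guideline <= 0 or self.daily_guideline <= 0:
            raise ValueError("guidelines must be positive")
        if self.gemm_params_file is not None and not Path(self.gemm_params_file).exists():
            raise FileNotFoundError(
                f"GEMM parameter file not found: {self.gemm_params_file}"
            )

    def cost_anchor_scenarios(self) -> list[CostScenario] | None:
        if self.cost_anchors is None:
            return None
        return [CostScenario(sp, reg, float(r), float(c)) for sp, reg, r, c in self.cost_anchors]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}", stacklevel=2)
        kwargs = {k: v for k, v in d.items() if k in known}
        if "levels" in kwargs:
            kwargs["levels"] = tuple(kwargs["levels"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                d = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ValueError(f"malformed config file {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
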