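"""Pipeline configuration with study-protocol defaults.

Every tunable that the assessment protocol fixes has that value as its
default: 10 km (map-unit) thinning distance, 50/50 train-test split,
|r| >= 0.8 correlation cut, RM grid (0.1, 0.5, 1, 2) x feature classes
"lqpth", evaluation error 5%, binarization error 20%, human-footprint
cutoff > 10, risk weights 0.7/0.3 with scale 10, and risk bands
3-14 / 15-28 / 29+.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .grid import ConfigurationError

__all__ = ["PipelineConfig", "ScenarioConfig"]


@dataclass
class ScenarioConfig:
    """One future scenario: per-variable uniform trend plus poleward gradient."""

    name: str
    additive: float = 0.0
    multiplicative: float = 1.0
    gradient: float = 0.0
    noise_sd: float = 0.05


def _default_scenarios() -> list[ScenarioConfig]:
    # a severity ladder standing in for RCP 2.6 / 4.5 / 6.0 / 8.5
    return [
        ScenarioConfig("rcp26", additive=0.2, gradient=0.2),
        ScenarioConfig("rcp45", additive=0.4, gradient=0.4),
        ScenarioConfig("rcp60", additive=0.6, gradient=0.6),
        ScenarioConfig("rcp85", additive=0.9, gradient=0.9),
    ]


@dataclass
class PipelineConfig:
    # synthetic landscape
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "local-planar"
    n_vars: int = 4
    corr_length: float = 5.0
    gradient_weight: float = 0.5
    n_presence: int = 150
    n_presence_congener: int = 200
    congener_breadth_scale: float = 2.0
    congener_optimum_shift: float = 1.0
    n_protected_areas: int = 8
    pa_size_range: tuple = (3.0, 8.0)
    scenarios: list = field(default_factory=_default_scenarios)

    # preprocessing
    thin_distance: float = 10.0
    split_fraction: float = 0.5
    correlation_threshold: float = 0.8

    # calibration
    rms: tuple = (0.1, 0.5, 1.0, 2.0)
    feature_classes: str = "lqpth"
    eval_error: float = 0.05
    proc_iterations: int = 100
    proc_sample_fraction: float = 0.5
    omission_cut: float = 0.05
    daicc_cut: float = 2.0
    n_bootstrap: int = 5

    # postprocessing / threats / risk
    binarize_error: float = 0.2
    hfp_cut: float = 10.0
    w_loss: float = 0.7
    w_contact: float = 0.3
    risk_scale: float = 10.0
    risk_low: tuple = (3.0, 14.0)
    risk_moderate: tuple = (15.0, 28.0)
    risk_high_min: float = 29.0

    seed: int = 0
    outdir: str = "enmrisk_run"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigurationError("at least one scenario is required")
        self.scenarios = [
            s if isinstance(s, ScenarioConfig) else ScenarioConfig(**s)
            for s in self.scenarios
        ]
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must be in (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pa_size_range"] = list(self.pa_size_range)
        d["rms"] = list(self.rms)
        d["risk_low"] = list(self.risk_low)
        d["risk_moderate"] = list(self.risk_moderate)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("pa_size_range", "rms", "risk_low", "risk_moderate"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Stable hash of the analysis configuration (output location
        excluded) for run manifests."""
        d = self.to_dict()
        d.pop("outdir", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
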