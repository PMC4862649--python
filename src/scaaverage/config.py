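"""Pipeline configuration: defaults, YAML round-trip and validation.

The configuration mirrors the three pipeline steps.  Defaults define the
package's reference conditions: 1000 process-uncertainty iterations,
triangle growth marginals at a 10% CV (bounds 1.96 sd from the median),
both natural-mortality models, a 95% catch-biomass plusgroup rule, the
full 18-configuration assessment grid and dip-test filtering at the 5%
level with a 2000-sample uniform bootstrap.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .growth import (
    DEFAULT_CORRELATION,
    DEFAULT_CV,
    DEFAULT_K_MEDIAN,
    DEFAULT_LINF_MEDIAN,
    DEFAULT_T0_MAX,
    DEFAULT_T0_MIN,
    DEFAULT_TAIL_DF,
    DEFAULT_Z,
    CopulaSpec,
    TriangleMarginal,
    default_marginals,
)

__all__ = ["GrowthSettings", "MortalitySettings", "SlicingSettings",
           "ScaaSettings", "EnsembleSettings", "PathSettings", "PipelineConfig"]


@dataclass
class GrowthSettings:
    linf_median: float = DEFAULT_LINF_MEDIAN
    linf_cv: float = DEFAULT_CV
    k_median: float = DEFAULT_K_MEDIAN
    k_cv: float = DEFAULT_CV
    t0_min: float = DEFAULT_T0_MIN
    t0_max: float = DEFAULT_T0_MAX
    z: float = DEFAULT_Z
    correlation: list = field(default_factory=lambda: DEFAULT_CORRELATION.tolist())
    tail_df: float = DEFAULT_TAIL_DF

    def marginals(self) -> tuple[TriangleMarginal, TriangleMarginal, TriangleMarginal]:
        return default_marginals(
            self.linf_median, self.linf_cv, self.k_median, self.k_cv,
            self.t0_min, self.t0_max, self.z,
        )

    def copula(self) -> CopulaSpec:
        return CopulaSpec(correlation=np.array(self.correlation), tail_df=self.tail_df)


@dataclass
class MortalitySettings:
    models: list = field(default_factory=lambda: ["constant", "gislason"])
    constant_value: float = 0.4
    jensen_window: list = field(default_factory=lambda: [15.0, 60.0])


@dataclass
class SlicingSettings:
    plusgroup_threshold: float = 0.95
    representative: str = "midpoint"  # or "lower"

    def __post_init__(self) -> None:
        if not (0 < self.plusgroup_threshold <= 1):
            raise ValueError("plusgroup threshold must be in (0, 1]")


@dataclass
class ScaaSettings:
    grid: str = "full"  # "full" (18 configs) or "reduced" (2x2 fast subset)
    fbar_range: list = field(default_factory=lambda: [1, 3])
    survey_timing: list = field(default_factory=lambda: [0.75, 0.75, 0.875])
    n_estimation_draws: int = 1
    compute_covariance: bool = True
    maxiter: int = 500
    weight_length_a: float = 6.59e-5
    weight_length_b: float = 3.01721


@dataclass
class EnsembleSettings:
    alpha: float = 0.05
    n_boot: int = 2000
    n_select: int | None = None  # None -> minimum variant size
    quantiles: list = field(default_factory=lambda: [0.10, 0.50, 0.90])
    min_iterations: int = 10


@dataclass
class PathSettings:
    catch: str | None = None
    surveys: list = field(default_factory=list)
    maturity: str | None = None
    outdir: str = "results"


@dataclass
class PipelineConfig:
    growth: GrowthSettings = field(default_factory=GrowthSettings)
    mortality: MortalitySettings = field(default_factory=MortalitySettings)
    slicing: SlicingSettings = field(default_factory=SlicingSettings)
    scaa: ScaaSettings = field(default_factory=ScaaSettings)
    ensemble: EnsembleSettings = field(default_factory=EnsembleSettings)
    paths: PathSettings = field(default_factory=PathSettings)
    n_iterations: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = dict(
            growth=GrowthSettings, mortality=MortalitySettings, slicing=SlicingSettings,
            scaa=ScaaSettings, ensemble=EnsembleSettings, paths=PathSettings,
        )
        kwargs = {}
        for name, typ in sections.items():
            kwargs[name] = typ(**raw.get(name, {}))
        for scalar in ("n_iterations", "seed"):
            if scalar in raw:
                kwargs[scalar] = raw[scalar]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
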