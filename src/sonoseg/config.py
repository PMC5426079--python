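"""Configuration dataclasses for the segmentation pipeline.

Defaults reproduce the published operating point of the method: a swarm of
200 particles run for up to 200 generations with acceleration coefficients
c1 = c2 = 0.5 and inertia decaying linearly from 1.0 to 0.2, searching
k in [100, 4000] and alpha in [0.001, 4.000]; objective weights
(a, b, c) = (0.3, 0.3, 0.4); a 5x5 elliptical kernel for morphology; and
180 rays for the radial-error metric.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessConfig:
    """Parameters of the crop + enhancement chain.

    All stages can be disabled individually, which is mainly useful for
    ablation tests; with every ``enable_*`` flag off the pipeline reduces
    to the ROI crop.
    """

    bilateral_diameter: int = 9          # window size, pixels
    bilateral_sigma_color: float = 75.0  # intensity units on the 0-255 scale
    bilateral_sigma_space: float = 75.0  # pixels
    meanshift_spatial_radius: int = 10   # pixels
    meanshift_range_radius: float = 20.0  # intensity units
    meanshift_pyramid_levels: int = 2
    enable_bilateral: bool = True
    enable_equalize: bool = True
    enable_meanshift: bool = True

    def __post_init__(self) -> None:
        if self.bilateral_diameter <= 0:
            raise ValueError("bilateral_diameter must be positive")
        if self.bilateral_sigma_color <= 0 or self.bilateral_sigma_space <= 0:
            raise ValueError("bilateral sigmas must be positive")
        if self.meanshift_spatial_radius <= 0 or self.meanshift_range_radius <= 0:
            raise ValueError("mean-shift radii must be positive")
        if self.meanshift_pyramid_levels < 0:
            raise ValueError("pyramid levels must be >= 0")


@dataclass
class SwarmConfig:
    """Particle-swarm settings for the (k, alpha) search."""

    n_p: int = 200
    t_max: int = 200
    c1: float = 0.5
    c2: float = 0.5
    w_max: float = 1.0
    w_min: float = 0.2
    k_bounds: tuple[float, float] = (100.0, 4000.0)
    alpha_bounds: tuple[float, float] = (0.001, 4.000)
    patience: int = 4
    seed: int = 0
    init: str = "grid"  # "grid" (deterministic) or "random"

    def __post_init__(self) -> None:
        if self.n_p < 2:
            raise ValueError("swarm size must be >= 2")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if not (self.k_bounds[0] < self.k_bounds[1]):
            raise ValueError("k_bounds must be ordered")
        if not (self.alpha_bounds[0] < self.alpha_bounds[1]):
            raise ValueError("alpha_bounds must be ordered")
        if self.init not in ("grid", "random"):
            raise ValueError("init must be 'grid' or 'random'")


@dataclass
class ObjectiveWeights:
    """Non-negative weights of the three objective terms (V_B, V_W, G_A)."""

    a: float = 0.3
    b: float = 0.3
    c: float = 0.4

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("weights must be non-negative")
        if self.a + self.b + self.c <= 0:
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass
class PipelineConfig:
    """Full end-to-end configuration, parseable from YAML or JSON."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pso: SwarmConfig = field(default_factory=SwarmConfig)
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    connectivity: int = 4
    # Within-class variance form: "divide" (arctan(var)/P, default) or
    # "multiply" (arctan(var)*P), kept selectable for sensitivity checks.
    vw_form: str = "divide"
    keep_central_component: bool = True
    apply_morphology: bool = True
    n_rays: int = 180
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.vw_form not in ("divide", "multiply"):
            raise ValueError("vw_form must be 'divide' or 'multiply'")
        if self.n_rays < 4:
            raise ValueError("n_rays must be >= 4")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pre = d.pop("preprocess", {})
        pso = d.pop("pso", {})
        w = d.pop("weights", {})
        if isinstance(pso, dict):
            for key in ("k_bounds", "alpha_bounds"):
                if key in pso and isinstance(pso[key], list):
                    pso[key] = tuple(pso[key])
        return cls(
            preprocess=PreprocessConfig(**pre) if isinstance(pre, dict) else pre,
            pso=SwarmConfig(**pso) if isinstance(pso, dict) else pso,
            weights=ObjectiveWeights(**w) if isinstance(w, dict) else w,
            **d,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
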