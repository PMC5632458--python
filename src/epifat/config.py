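"""Pipeline configuration.

Defaults are the cross-validated optima of the study: morphology disk
diameters ``ms1 = 40`` and ``ms2 = 20``, alpha-cut level ``alpha = 0.7``,
ring half-width ``epsilon = 20`` px, and referent-ellipse axis bounds
``(200, 450)`` px — all calibrated on 512-wide slices.  For other matrix
sizes :meth:`PipelineConfig.scaled_for_width` rescales every pixel-valued
parameter by ``width / 512``.

YAML round-trip is supported; unknown keys are rejected on load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PreprocessConfig",
    "ClusteringConfig",
    "EllipseConfig",
    "PostfilterConfig",
    "PipelineConfig",
]

REFERENCE_GRID = 512


@dataclass
class PreprocessConfig:
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    ms1: int = 40
    ms2: int = 20
    threshold_method: str = "otsu"
    tone_method: str = "stretch"  # "stretch" | "clahe"


@dataclass
class ClusteringConfig:
    R: int = 5
    stride: int = 2
    C: int = 5
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    rng_seed: int = 0
    pondered_mean: str = "normalized"  # "normalized" | "as_printed" (literal study formula)


@dataclass
class EllipseConfig:
    loading: float | None = None  # None -> 1e-6 * trace/2
    B_l: float = 200.0
    B_u: float = 450.0
    optimizer_tol: float = 1e-12
    orientation_mode: str = "weighted_average"  # | "weighted_coords" (literal study formula)


@dataclass
class PostfilterConfig:
    alpha: float = 0.7
    epsilon: float = 20.0
    closure_size: int = 20
    distance_mode: str = "corrected"  # | "as_printed"


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    ellipse: EllipseConfig = field(default_factory=EllipseConfig)
    postfilter: PostfilterConfig = field(default_factory=PostfilterConfig)

    def scaled_for_width(self, image_width: int) -> "PipelineConfig":
        """Rescale pixel-valued parameters to a non-512 matrix size.

        Disk diameters, the ring half-width and the axis bounds scale by
        ``width / 512``; dimensionless parameters (alpha, C, m, R, stride)
        are untouched.  The identity for 512-wide images.
        """
        f = image_width / REFERENCE_GRID
        if f == 1.0:
            return self
        pp = dataclasses.replace(
            self.preprocess,
            ms1=max(1, round(self.preprocess.ms1 * f)),
            ms2=max(1, round(self.preprocess.ms2 * f)),
        )
        el = dataclasses.replace(
            self.ellipse, B_l=self.ellipse.B_l * f, B_u=self.ellipse.B_u * f
        )
        po = dataclasses.replace(
            self.postfilter,
            epsilon=self.postfilter.epsilon * f,
            closure_size=max(1, round(self.postfilter.closure_size * f)),
        )
        return dataclasses.replace(self, preprocess=pp, ellipse=el, postfilter=po)

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        section_types = {
            "preprocess": PreprocessConfig,
            "clustering": ClusteringConfig,
            "ellipse": EllipseConfig,
            "postfilter": PostfilterConfig,
        }
        for name, typ in section_types.items():
            if name in data:
                sub = dict(data[name] or {})
                valid = {f.name for f in dataclasses.fields(typ)}
                bad = set(sub) - valid
                if bad:
                    raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
                for key in ("clip_percentiles",):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = typ(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
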