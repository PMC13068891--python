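"""Run configuration: one flat key-value schema binding every tunable.

The config file is flat YAML (scalars and short lists only); unknown keys
are errors so typos in scientific configs fail fast.  Every run echoes its
fully resolved configuration as sorted JSON into the output directory, which
together with the single seed suffices to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .blending import BlendMode, BlendParams
from .fixtures import FixtureConfig
from .lesions import TransformConfig
from .pipeline import ProtocolConfig
from .regions import RegionConfig, RelevanceCriteria

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass(frozen=True)
class RunConfig:
    """Flat view of every documented tunable with its default."""

    seed: int = 0
    log_level: str = "WARNING"

    # region proposal
    spatial_bandwidth: float = 16.0
    range_bandwidth: float = 0.12
    ms_max_iter: int = 300
    ms_max_samples: int = 1500
    min_luminance: float = 0.15
    max_luminance: float = 0.92
    min_area_fraction: float = 0.05
    n_segments: int = 64
    compactness: float = 10.0
    slic_iterations: int = 10

    # blending
    alpha: float = 0.8
    blend_mode: str = "gradient_mix"
    solver_tol: float = 1e-6
    max_solver_iter: int = 10000
    sum_gradients: bool = False

    # lesion geometry
    rotation_angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    flip_probability: float = 0.5
    max_lesion_fraction: float = 0.5

    # mixers
    mixup_beta: float = 0.2

    # protocol
    test_fraction: float = 0.2
    n_folds: int = 5
    synthesis_ratio: float = 1.0
    resize_height: int = 224
    resize_width: int = 224
    alpha_sweep: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    # fixtures
    fixture_height: int = 224
    fixture_width: int = 224
    texture_scale: float = 12.0
    vignette_strength: float = 0.35
    specular_count: int = 3
    lesion_irregularity: float = 0.3

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must be a flat key-value mapping")
        raw.update(overrides)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - names)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name not in mapping:
                continue
            v = mapping[f.name]
            if isinstance(v, list):
                v = tuple(v)
            coerced[f.name] = v
        try:
            return cls(**coerced)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    # ---- typed views ------------------------------------------------------

    def region_config(self) -> RegionConfig:
        return RegionConfig(
            spatial_bandwidth=self.spatial_bandwidth,
            range_bandwidth=self.range_bandwidth,
            ms_max_iter=self.ms_max_iter,
            ms_max_samples=self.ms_max_samples,
            criteria=RelevanceCriteria(
                min_luminance=self.min_luminance,
                max_luminance=self.max_luminance,
                min_area_fraction=self.min_area_fraction,
            ),
            n_segments=self.n_segments,
            compactness=self.compactness,
            slic_iterations=self.slic_iterations,
        )

    def blend_params(self, alpha: float | None = None, mode: str | None = None) -> BlendParams:
        try:
            blend_mode = BlendMode(mode if mode is not None else self.blend_mode)
        except ValueError as exc:
            raise ConfigError(f"blend_mode: {exc}") from exc
        return BlendParams(
            alpha=self.alpha if alpha is None else alpha,
            mode=blend_mode,
            solver_tol=self.solver_tol,
            max_solver_iter=self.max_solver_iter,
            sum_gradients=self.sum_gradients,
        )

    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(
            test_fraction=self.test_fraction,
            n_folds=self.n_folds,
            synthesis_ratio=self.synthesis_ratio,
            resize_to=(self.resize_height, self.resize_width),
            alpha_sweep=self.alpha_sweep,
        )

    def transform_config(self) -> TransformConfig:
        return TransformConfig(
            flip_probability=self.flip_probability, angles=self.rotation_angles
        )

    def fixture_config(self, seed: int | None = None) -> FixtureConfig:
        return FixtureConfig(
            image_size=(self.fixture_height, self.fixture_width),
            texture_scale=self.texture_scale,
            vignette_strength=self.vignette_strength,
            specular_count=self.specular_count,
            lesion_irregularity=self.lesion_irregularity,
            seed=self.seed if seed is None else seed,
        )

    # ---- reproducibility echo --------------------------------------------

    def echo(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.json"
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=list) + "\n")
        return path
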