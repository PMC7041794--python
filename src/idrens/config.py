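"""Pipeline configuration: a single YAML-serializable object whose
(config, seed) pair reproduces a run bit-for-bit.  Unknown keys are
rejected fail-fast."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from idrens.descriptors import CTERM_REGION
from idrens.sampler import InteractionFlags, SamplerParams
from idrens.sequences import VARIANT_NAMES

PRESETS = ("desk", "paper-counts")


@dataclass(frozen=True)
class PipelineConfig:
    variants: tuple[str, ...] = ("WT", "E50A", "MM")
    preset: str = "desk"
    #: desk preset: paper step counts divided by this (configuration counts
    #: per run are unchanged).
    desk_divisor: int = 100
    n_runs: int = 20
    droplet_radius: float = 56.0
    temperature: float = 298.0
    ionic_strength: float = 0.020
    helix_propensity_overrides: dict = field(default_factory=dict)
    cterm_region: tuple[int, int] = CTERM_REGION
    histogram_bins: int = 30
    heterogeneity_pairs: int = 10_000
    plate_noise_sd: float = 6.0
    plate_replicates: int = 3
    anova_alpha: float = 0.05
    anova_control: str = "WT"
    nps_noise_sd: float = 0.02
    outdir: str = "runs/latest"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}, got {self.preset!r}")
        unknown = set(self.variants) - set(VARIANT_NAMES)
        if unknown:
            raise ValueError(f"unknown variants in config: {sorted(unknown)}")
        if "WT" not in self.variants:
            raise ValueError("config must include the WT variant (comparison reference)")

    def sampler_params(self, base_seed: int,
                       interactions: InteractionFlags | None = None) -> SamplerParams:
        kwargs = dict(
            n_runs=self.n_runs,
            droplet_radius=self.droplet_radius,
            temperature=self.temperature,
            ionic_strength=self.ionic_strength,
            helix_propensity_overrides=dict(self.helix_propensity_overrides),
            base_seed=base_seed,
        )
        if interactions is not None:
            kwargs["interactions"] = interactions
        if self.preset == "desk":
            return SamplerParams.desk_scale(divisor=self.desk_divisor, **kwargs)
        return SamplerParams.paper_counts(**kwargs)

    def to_dict(self) -> dict:
        return {
            "variants": list(self.variants),
            "preset": self.preset,
            "desk_divisor": self.desk_divisor,
            "n_runs": self.n_runs,
            "droplet_radius": self.droplet_radius,
            "temperature": self.temperature,
            "ionic_strength": self.ionic_strength,
            "helix_propensity_overrides": dict(self.helix_propensity_overrides),
            "cterm_region": list(self.cterm_region),
            "histogram_bins": self.histogram_bins,
            "heterogeneity_pairs": self.heterogeneity_pairs,
            "plate_noise_sd": self.plate_noise_sd,
            "plate_replicates": self.plate_replicates,
            "anova_alpha": self.anova_alpha,
            "anova_control": self.anova_control,
            "nps_noise_sd": self.nps_noise_sd,
            "outdir": self.outdir,
            "base_seed": self.base_seed,
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        if "variants" in data:
            data["variants"] = tuple(data["variants"])
        if "cterm_region" in data:
            data["cterm_region"] = tuple(data["cterm_region"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
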