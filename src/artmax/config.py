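"""Run configuration: schema-validated parameters for the CLI.

The config file is YAML (flat key/value); unknown keys are rejected so a
typo cannot silently fall back to a default. Every command logs the full
resolved configuration, so any output is reproducible from its log.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .art import VigilanceConfig
from .hierarchy import DEFAULT_SHARPNESS


class RunConfig(BaseModel):
    """All tunable parameters of a run, with validated defaults."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # hierarchy
    target_height: int = 140
    sharpness: float = DEFAULT_SHARPNESS
    # vigilance learning
    rho: float = 0.9
    top_p: int = 5
    patch_sizes: tuple[int, ...] = (4, 8, 12, 16)
    new_per_mismatch: int = 1
    max_prototypes: Optional[int] = None
    site_policy: str = "random"
    n_site_candidates: int = 8
    # classifier / evaluation
    svm_c: float = 1.0
    n_runs: int = 20
    # synthetic benchmark
    n_faces: int = 60
    n_distractors: int = 60
    n_train_per_class: int = 60
    noise_levels: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    # stability experiment
    m_per_step: int = 2

    @field_validator("noise_levels")
    @classmethod
    def _levels_in_range(cls, v):
        for lv in v:
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"noise level must be in [0, 1], got {lv}")
        return v

    @field_validator("rho")
    @classmethod
    def _rho_in_range(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {v}")
        return v

    def vigilance(self, seed: int | None = None) -> VigilanceConfig:
        """The learning-loop slice of this config."""
        return VigilanceConfig(
            rho=self.rho, top_p=self.top_p,
            patch_sizes=tuple(self.patch_sizes),
            new_per_mismatch=self.new_per_mismatch,
            seed=self.seed if seed is None else seed,
            max_prototypes=self.max_prototypes,
            site_policy=self.site_policy,
            n_site_candidates=self.n_site_candidates,
            sharpness=self.sharpness)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError("config file must be a YAML mapping")
        return cls(**doc)
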