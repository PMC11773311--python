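"""Schema-validated pipeline configuration.

One YAML (or JSON) file drives the whole pipeline; unknown keys are
rejected and a seed is mandatory because every generation stage is
stochastic. CLI flags override config keys (CLI wins).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .sequences import CLOSING_PAIRS


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConstructConfig(_StrictModel):
    handle5: str = "ACGCAGUCAG"
    handle3: str = "GACUGACGUC"
    stem: str = "GCAGUCCGAUGC"
    donor_tags: dict[str, str] = Field(default={"A": "AAGGCC", "B": "CCUUAA"})
    acceptor_tags: dict[str, str] = Field(default={"a": "GGAAUU", "b": "UUCCGG"})


class GeneratorConfig(_StrictModel):
    n_molecules: int = Field(default=1_000_000, gt=0)
    read_depth: int = Field(default=200_000, gt=0)
    control_depth: int = Field(default=200_000, gt=0)
    concentration_nM: float = Field(default=5.0, gt=0)
    reference_concentration_nM: float = Field(default=250.0, gt=0)
    target_splinted_share: float = Field(default=0.44, gt=0, lt=0.5)
    efficiency_noise_sd: float = Field(default=0.25, ge=0)
    k_loop: float = Field(default=0.25, gt=0)
    k_hyd: float = Field(default=1.0, ge=0)
    w_gc: float = Field(default=3.0, gt=0)
    w_au: float = Field(default=1.0, gt=0)
    error_rate: float = Field(default=0.0, ge=0, lt=1)
    library_bias: str = Field(default="default", pattern="^(default|uniform)$")


class ReferenceConfig(_StrictModel):
    n_entries: int = Field(default=600, gt=0)
    uncg_weight: float = Field(default=30.0, gt=0)
    gnra_weight: float = Field(default=15.0, gt=0)
    dup_fraction: float = Field(default=0.2, ge=0, lt=1)


class ThresholdConfig(_StrictModel):
    top_k: int = Field(default=40, ge=0, le=256)
    max_mismatch: int = Field(default=0, ge=0)
    pseudocount: float = Field(default=0.5, ge=0)
    dedup_identity: float = Field(default=0.90, gt=0, le=1)
    dedup_coverage: float = Field(default=0.70, gt=0, le=1)


class PipelineConfig(_StrictModel):
    """Everything a reproducible end-to-end run needs."""

    seed: int
    outdir: str = "loopseq_out"
    closing_pairs: list[str] = Field(default_factory=lambda: list(CLOSING_PAIRS))
    construct_spec: ConstructConfig = Field(default_factory=ConstructConfig)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    reference: ReferenceConfig = Field(default_factory=ReferenceConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    top_patterns: list[str] = Field(default_factory=lambda: ["UNNG", "CNNG", "GNNA"])
    bottom_patterns: list[str] = Field(default_factory=lambda: ["RNNY", "ANNR", "CNNU"])

    @field_validator("closing_pairs")
    @classmethod
    def _pairs_known(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(CLOSING_PAIRS)
        if unknown:
            raise ValueError(f"unknown closing pair(s): {sorted(unknown)}")
        if not v:
            raise ValueError("closing_pairs must not be empty")
        return v

    @model_validator(mode="after")
    def _seed_bounds(self) -> "PipelineConfig":
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be a non-negative 31-bit integer")
        return self

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        import hashlib

        data = self.model_dump()
        data.pop("outdir", None)
        payload = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a YAML/JSON config file.

    Raises pydantic.ValidationError with field-level messages on schema
    violations (unknown keys, out-of-range thresholds, missing seed).
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PipelineConfig.model_validate(data)


def demo_config(seed: int = 7, outdir: str = "loopseq_out") -> PipelineConfig:
    """Small, fast demonstration configuration (single reaction, low depth)."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        closing_pairs=["C:G"],
        generator=GeneratorConfig(
            n_molecules=200_000, read_depth=30_000, control_depth=60_000
        ),
        reference=ReferenceConfig(n_entries=250),
    )


def write_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
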