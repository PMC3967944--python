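"""Run configuration: validated YAML in, fully serialized metadata out."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ProtocolOverrides(BaseModel):
    rest_duration: float = 50.0  # s
    max_beats_slow: int = 1000
    max_beats_fast: int = 1000
    steady_tolerance: float = 1.0e-3
    apd_fraction: float = Field(0.90, gt=0.0, lt=1.0)
    stim_amplitude: float | None = None
    stim_duration: float | None = None


class RunConfig(BaseModel):
    """Everything needed to reproduce one full-population analysis."""

    model_id: str
    rates_hz: tuple[float, float] = (0.2, 2.0)  # (slow, fast)
    n_trials: int = Field(300, ge=1)
    sigma_log: float | None = Field(None, gt=0)  # None = model default
    v_sd_mV: float = Field(2.0, ge=0)
    seed: int = Field(0, ge=0, lt=2**31)
    classification_threshold: float = Field(0.01, gt=0)
    display_threshold: float = Field(0.03, gt=0)
    protocol: ProtocolOverrides = ProtocolOverrides()
    output_dir: Path = Path("ratedep_run")

    @field_validator("rates_hz")
    @classmethod
    def _ordered(cls, v):
        if not v[0] < v[1]:
            raise ValueError("rates must be (slow, fast) with slow < fast")
        return v

    @model_validator(mode="after")
    def _known_model(self):
        from .models import available_models

        if self.model_id not in available_models():
            raise ValueError(
                f"unknown model {self.model_id!r}; available: {available_models()}"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def resolved_sigma(self) -> float:
        from .models import get_model

        return (
            self.sigma_log
            if self.sigma_log is not None
            else get_model(self.model_id).default_sigma_log
        )

    def protocols(self):
        from .pacing import PacingProtocol

        slow_hz, fast_hz = self.rates_hz
        ov = self.protocol
        common = dict(
            rest_duration=ov.rest_duration,
            steady_tolerance=ov.steady_tolerance,
            apd_fraction=ov.apd_fraction,
            stim_amplitude=ov.stim_amplitude,
            stim_duration=ov.stim_duration,
        )
        return (
            PacingProtocol(1000.0 / slow_hz, max_beats=ov.max_beats_slow, **common),
            PacingProtocol(1000.0 / fast_hz, max_beats=ov.max_beats_fast, **common),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            self.model_dump(mode="json"), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_consensus_name_map() -> dict[str, dict[str, str]]:
    """The versioned cross-model parameter name mapping."""
    path = Path(__file__).parent / "data" / "consensus_names.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)
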