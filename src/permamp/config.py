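"""Run configuration: validated, serialisable settings for CLI workflows."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .peptide import CANONICAL_AA


class RunConfig(BaseModel):
    """Settings shared by the CLI commands; echoed as JSON next to outputs."""

    parent_sequence: str | None = None
    parent_name: str = "parent"
    n_terminus: str = "free"
    c_terminus: str = "free"
    names: dict[int, str] = Field(default_factory=dict)
    scale: str = "fauchere-pliska"
    censor_substitute: float = 100.0
    hc10_threshold: float = 10.0
    hc10_cap: float = 108.7
    seed: int = 0
    out_dir: Path = Path(".")

    @field_validator("parent_sequence")
    @classmethod
    def _check_sequence(cls, v: str | None) -> str | None:
        if v is not None:
            for pos, aa in enumerate(v, start=1):
                if aa not in CANONICAL_AA:
                    raise ValueError(f"non-canonical residue {aa!r} at position {pos}")
        return v

    @field_validator("censor_substitute", "hc10_threshold", "hc10_cap")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def echo(self, path: str | Path) -> None:
        """Write the resolved configuration so every output is auditable."""
        payload = self.model_dump(mode="json")
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
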