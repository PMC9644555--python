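"""Run configuration: every stage parameter with its default, serialisable,
hashed into output provenance so equal hashes imply equal numeric results."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    min_reads: int = 1000
    prevalence_threshold: float = 0.10
    n_bootstraps: int = 1000
    beta: float = 2.0
    clip_negative_r: bool = False
    exclusion_threshold: float = 0.1
    max_exclusion_rounds: int = 10
    inner_iterations: int = 20
    min_sizes: list = field(default_factory=lambda: list(range(3, 41)))
    min_modules: int = 10
    height_fraction: float = 0.5
    zero_prop_max: float = 0.10
    r_min: float = 0.2
    q_max: float = 0.05
    n_permutations: int = 100
    seed: int | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
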