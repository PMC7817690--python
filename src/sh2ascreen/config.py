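"""Run configuration shared by the command-line stages.

Defaults are the printed thresholds of the source analyses; everything the
source leaves open defaults to the decision documented in the owning module
and is echoed into each run's provenance record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    tau_pos: float = 1.5
    tau_neg: float = 0.5
    alpha: float = 0.05
    delta_psi: float = 0.1
    fc_border: float = 1.19
    fc_pseudocount: float = 0.1
    k_cta: int = 40
    min_count_recurrent: int = 5
    min_group: int = 10
    min_per_group_psi: int = 5
    trim_m: float = 0.30
    trim_a: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.tau_neg <= self.tau_pos:
            raise ValidationError("need 0 <= tau_neg <= tau_pos")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.delta_psi <= 1:
            raise ValidationError("delta_psi must be in (0, 1]")
        if self.fc_border <= 1:
            raise ValidationError("fc_border must exceed 1")
        if self.fc_pseudocount < 0:
            raise ValidationError("fc_pseudocount must be >= 0")
        if min(self.k_cta, self.min_count_recurrent, self.min_group,
               self.min_per_group_psi) < 1:
            raise ValidationError("count thresholds must be >= 1")
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise ValidationError("trim fractions must be in [0, 0.5)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
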