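"""Run configuration with the method's standard defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """Configuration of a QDR run and its evaluation.

    Defaults are the method's standard operating point: 2 resorption
    passes, overlap-population threshold 1e-4, 10 angstrom pair cutoff sum,
    and the valid-grid-point rules (density < 1e-4 e/bohr^3, 2 A inner and
    5 A outer radius cutoffs).
    """

    passes: int = 2
    op_threshold: float = 1.0e-4
    cutoff_sum_angstrom: float = 10.0
    cg_tol: float = 1.0e-10
    esp_terms: tuple[str, ...] = ("charges",)
    rho_max: float = 1.0e-4
    inner_angstrom: float = 2.0
    outer_angstrom: float = 5.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.passes < 0:
            raise ValidationError("passes must be >= 0")
        if self.op_threshold < 0 or self.cutoff_sum_angstrom <= 0:
            raise ValidationError("op_threshold/cutoff must be nonnegative/positive")
        if not (0 < self.inner_angstrom < self.outer_angstrom):
            raise ValidationError("need 0 < inner < outer radius cutoffs")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["esp_terms"] = list(self.esp_terms)
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "esp_terms" in doc:
            doc["esp_terms"] = tuple(doc["esp_terms"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg
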