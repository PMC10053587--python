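"""Declarative pipeline configuration.

Defaults reproduce the published search settings: BLASTP-style thresholds
(E <= 1e-6, identity >= 30%, coverage >= 70% both sides), BLOSUM62 with
gap open 11 / extend 1 and the matching gapped Karlin–Altschul constants,
the Kyte–Doolittle transmembrane criterion for cpcL (window 19, mean
>= 1.6, C-terminal 60 residues), a 1 kb operon gap for cluster detection,
and alpha levels 0.05 / 0.01 for the composition comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .align import ScoringScheme
from .errors import ValidationError
from .orthology import Thresholds


@dataclass(frozen=True)
class PipelineConfig:
    evalue_max: float = 1e-6
    identity_min: float = 0.30
    coverage_min: float = 0.70
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_K: float = 0.041
    hydro_window: int = 19
    hydro_threshold: float = 1.6
    cterm_span: int = 60
    cluster_max_gap: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.01)
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.identity_min <= 1 and 0 <= self.coverage_min <= 1):
            raise ValidationError("identity/coverage thresholds must be in [0, 1]")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        if self.hydro_window % 2 == 0 or self.hydro_window < 1:
            raise ValidationError("hydro_window must be a positive odd integer")
        if self.cluster_max_gap < 0:
            raise ValidationError("cluster_max_gap must be non-negative")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix_name,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            lam=self.ka_lambda,
            K=self.ka_K,
        )

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.evalue_max, self.identity_min, self.coverage_min)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["alphas"] = list(self.alphas)
        return yaml.safe_dump(data, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "alphas" in data:
            data["alphas"] = tuple(data["alphas"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
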