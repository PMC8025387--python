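"""Pipeline configuration: thresholds, seeds and covariate choices.

Every printed analysis threshold lives here with its default: detection-p
masking at 0.01, the 5% missingness filters, epigenome-wide alpha 9e-8,
the phi > 0.4 & p < 0.05 co-treatment exclusion, SNP pruning r^2 < 0.3,
mediator pruning r^2 < 0.05, and the 0.05 FDR level.  Unknown keys are
rejected so config typos cannot silently change an analysis, and all
randomness flows from the single top-level seed through per-stage derived
seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np

__all__ = ["PipelineConfig", "stage_seed"]


@dataclass
class PipelineConfig:
    detection_p: float = 0.01
    missing_frac: float = 0.05
    ewas_alpha: float = 9e-8
    phi_cut: float = 0.4
    phi_p: float = 0.05
    snp_r2: float = 0.3
    mediator_r2: float = 0.05
    fdr_q: float = 0.05
    n_draws: int = 1000
    seed: int = 0
    n_genetic_pcs: int = 3
    k_max_meth_pcs: int = 10
    min_group: int = 10
    # simulation knobs forwarded to SimulationConfig when simulating
    simulation: dict = field(default_factory=dict)
    # optional input paths for running on real files instead of simulating
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = {
            "detection_p": (0, 1),
            "missing_frac": (0, 1),
            "ewas_alpha": (0, 1),
            "phi_cut": (0, 1),
            "phi_p": (0, 1),
            "snp_r2": (0, 1),
            "mediator_r2": (0, 1),
            "fdr_q": (0, 1),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.n_draws < 100:
            raise ValueError("n_draws must be at least 100")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)
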