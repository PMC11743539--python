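"""Run configuration and deterministic seed derivation.

A single master seed in :class:`StudyConfig` governs every stochastic stage
(null ensembles, permutation shuffles, simulation).  Each stage derives its
own child generator from the master seed and the stage name, so re-running
any stage in isolation reproduces the numbers the full pipeline produced.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

NULL_MODELS = ("degree_preserving", "erdos_renyi_gnm")
THRESHOLD_MODES = ("signed", "absolute")


@dataclass
class StudyConfig:
    """Analysis parameters for a full connectome-topology run.

    Defaults follow the study design this package implements: a proportional
    sparsity sweep from 10% to 50% in 1% steps, 1,000 group-label
    permutations, and Benjamini–Hochberg FDR at q = 0.05.
    """

    sparsity_lo: float = 0.10
    sparsity_hi: float = 0.50
    sparsity_step: float = 0.01
    n_permutations: int = 1000
    fdr_q: float = 0.05
    nbs_primary_p: float = 0.001
    n_null_realizations: int = 100
    null_model: str = "degree_preserving"
    seed: int = 0
    threshold_mode: str = "signed"

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity_lo <= self.sparsity_hi <= 1.0):
            raise ValueError(
                f"require 0 < sparsity_lo <= sparsity_hi <= 1, got "
                f"[{self.sparsity_lo}, {self.sparsity_hi}]"
            )
        if self.sparsity_step <= 0:
            raise ValueError(f"sparsity_step must be > 0, got {self.sparsity_step}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if not (0.0 < self.nbs_primary_p < 1.0):
            raise ValueError(f"nbs_primary_p must be in (0, 1), got {self.nbs_primary_p}")
        if self.n_null_realizations < 1:
            raise ValueError("n_null_realizations must be >= 1")
        if self.null_model not in NULL_MODELS:
            raise ValueError(f"null_model must be one of {NULL_MODELS}")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"threshold_mode must be one of {THRESHOLD_MODES}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a config from YAML or JSON (decided by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def child_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a stage-specific seed sequence from the master seed.

    The stage name is hashed (CRC-32) into the entropy pool, so distinct
    stages get statistically independent streams while each stream remains
    a pure function of ``(master_seed, stage)``.
    """
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator (see :func:`child_seed`)."""
    return np.random.default_rng(child_seed(master_seed, stage))
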