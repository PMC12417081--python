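"""Run configuration, YAML round-tripping, and the single-seed policy.

One user-facing seed derives every per-stage seed through a stable splitter
(:func:`stage_seed`), so individual stages can be re-run in isolation and
still reproduce the full pipeline bit-for-bit on one CPU thread.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import yaml


@dataclass
class RunConfig:
    # pseudo-spot sampling
    lam: float = 5.0
    NK: int = 4
    n_pseudo: int = 50000
    size_sampler: str = "poisson"
    # graph construction
    graph_size: int = 200
    n_graphs: int = 250
    k: int = 6
    # preprocessing
    min_genes: int = 100
    library_target: Union[float, str] = "median"
    # model
    n_components: int = 8
    hidden: int = 512
    embed: int = 512
    head_hidden: int = 256
    disc_hidden: int = 256
    alpha: float = 1.0
    hard_assignment: bool = False
    # training
    epochs: int = 20
    lr: float = 0.001
    w_mse: float = 1000.0
    w_sample: float = 1000.0
    w_entropy: float = 10.0
    entropy_sign: int = 1
    disable_recon: bool = False
    disable_domain: bool = False
    disable_sample: bool = False
    disable_entropy: bool = False
    shuffle_graphs: bool = False
    clip_factor: Optional[float] = 3.0   # adaptive gradient clipping; null disables
    # evaluation
    exclude_types: List[str] = field(default_factory=list)
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.n_pseudo < self.graph_size * self.n_graphs:
            raise ValueError("n_pseudo must cover n_graphs x graph_size")
        if self.entropy_sign not in (1, -1):
            raise ValueError("entropy_sign must be +1 or -1")

    # ------------------------------------------------------------- round-trip
    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed (< 2^31) from the single run seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))
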