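"""Run configuration and reproducible seed derivation.

The package is driven from Python (see the examples directory); RunConfig
captures everything a run needs — model names, task scope, seed, grid and
optimizer overrides — and persists alongside outputs so any result can be
regenerated from its config + seed.  A master seed deterministically derives
per-participant and per-restart substreams, so partial reruns reproduce
exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from avci.engine import GridSpec


def derive_seed(master_seed: int, *keys) -> int:
    """A child seed (< 2**31) deterministically derived from a master seed and
    a sequence of integer keys (participant index, restart index, ...)."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunConfig:
    """Persisted configuration of a pipeline run."""

    command: str = "simulate"
    model_names: list = field(default_factory=lambda: ["Exp-GaussianLaplace-PM"])
    tasks: list | None = None
    data_path: str | None = None
    seed: int = 0
    n_starts: int = 3
    budget: int | None = None
    metric: str = "bic"
    grid_overrides: dict = field(default_factory=dict)
    out_dir: str = "results"

    def grids(self) -> GridSpec:
        return GridSpec(**self.grid_overrides)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
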