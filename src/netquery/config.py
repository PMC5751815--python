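"""Run configuration with file/flag/default precedence."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a querying run.

    Defaults follow the method as published: K = 20 candidates screened per
    extension step, teleportation alpha = 0.5, pruning mass 0.5, a 10%
    minimum relative conductance drop, and specific-hit threshold
    m_t = 0.5. The seed size limit is max_size_factor times the query size
    (rounded up).
    """

    s_t: float = 0.0
    K: int = 20
    alpha: float = 0.5
    mass: float = 0.5
    min_rel_drop: float = 0.10
    max_size_factor: float = 1.5
    power_tol: float = 1e-10
    power_max_iter: int = 10000
    ppr_tol: float = 1e-12
    m_t: float = 0.5
    seed: int = 0
    verbosity: int = 0

    def max_size(self, query_size: int) -> int:
        import math
        return math.ceil(self.max_size_factor * query_size)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def resolve(
        cls,
        config_file: str | Path | None = None,
        overrides: dict | None = None,
    ) -> "RunConfig":
        """Build a config with precedence: override > file > default."""
        values: dict = {}
        if config_file is not None:
            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            values.update(loaded)
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
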