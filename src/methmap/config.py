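"""Run configuration: analysis thresholds, seeds, and file paths.

The defaults are the thresholds used throughout the analysis: 5x minimum
strand-specific coverage in at least three replicates per group, FDR 5%,
500 bp DMR merge gap, 5 Mbp cis window on the genetic map, MAPQ 20 and a
Q20 3' quality-trim cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    min_coverage: int = 5
    min_replicates: int = 3
    fdr: float = 0.05
    dmr_gap: int = 500
    cis_window: int = 5_000_000
    min_mapq: int = 20
    quality_trim: int = 20
    n_permutations: int = 10_000
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "min_coverage",
            "min_replicates",
            "fdr",
            "dmr_gap",
            "cis_window",
            "min_mapq",
            "quality_trim",
            "n_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def provenance_block(config: RunConfig) -> str:
    """Config + seed + version summary written to the log at run start."""
    from . import __version__

    lines = [f"methmap {__version__}"]
    for key, value in sorted(config.to_dict().items()):
        lines.append(f"  {key}: {value}")
    return "\n".join(lines)
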