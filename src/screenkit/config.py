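"""Pipeline configuration.

A flat key/value document (YAML) holds every analysis cut-off used by the
pipeline.  Command-line flags override file values; the resolved config is
echoed into the output directory so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis cut-offs and run parameters.

    Defaults reproduce the study conditions: a pooled-screen resistance
    hit needs linear fold change >= 2 and permutation p < 0.005; a core
    resistance gene recurs in at least 4 screens; an arrayed-screen
    translocation hit needs a >20% increase in the Nuc:Cyt ratio over the
    non-targeting control.

    Parameters
    ----------
    fc_cutoff
        Linear fold-change cut-off for pooled-screen hit calling.
    p_cutoff
        Permutation p-value cut-off for pooled-screen hit calling.
    recurrence_min
        Minimum number of screens a gene must be a hit in to be core.
    rra_alpha
        Guide-level p threshold below which a guide contributes to the
        alpha-RRA gene score.
    n_permutations
        Number of permutations for the alpha-RRA null distribution.
    yap_hit_threshold
        Fractional Nuc:Cyt increase over NTC calling a translocation hit
        (0.20 means "> 20% increase").
    fdr_method
        Multiple-testing correction; only Benjamini-Hochberg supported.
    seed
        Seed for every stochastic step; no global random state is used.
    """

    fc_cutoff: float = 2.0
    p_cutoff: float = 0.005
    recurrence_min: int = 4
    rra_alpha: float = 0.05
    n_permutations: int = 10_000
    yap_hit_threshold: float = 0.20
    fdr_method: str = "benjamini_hochberg"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0:
            raise ConfigError(f"fc_cutoff must be positive, got {self.fc_cutoff}")
        if not 0 < self.p_cutoff < 1:
            raise ConfigError(f"p_cutoff must be in (0,1), got {self.p_cutoff}")
        if self.recurrence_min < 1:
            raise ConfigError(f"recurrence_min must be >= 1, got {self.recurrence_min}")
        if not 0 < self.rra_alpha < 1:
            raise ConfigError(f"rra_alpha must be in (0,1), got {self.rra_alpha}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.yap_hit_threshold <= 0:
            raise ConfigError("yap_hit_threshold must be positive")
        if self.fdr_method != "benjamini_hochberg":
            raise ConfigError(f"unsupported fdr_method {self.fdr_method!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat YAML config; keyword arguments override file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a flat key/value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, out_dir: str | Path) -> Path:
        """Write the resolved config as JSON into ``out_dir`` for provenance."""
        out = Path(out_dir) / "config_resolved.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return out
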