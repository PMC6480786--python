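"""Analysis configuration: thresholds for recurrence, differential expression,
survival horizon and permutation tests.

Defaults follow the study design this package implements: a gene is
"recurrently" altered when at least ``recurrence_fraction`` of samples within a
cancer type carry the alteration in at least ``min_cancers`` cancer types;
tumour-vs-normal differential expression passes at a 1.5-fold change and
p < 0.05; quartile-contrast DEG calling uses |log2FC| > 1.5 and p < 0.01; the
survival ROC horizon is 5 years (1825 days).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


@dataclass
class AnalysisConfig:
    recurrence_fraction: float = 0.20
    min_cancers: int = 7
    de_fc_linear: float = 1.5
    de_p: float = 0.05
    deg_log2fc: float = 1.5
    deg_p: float = 0.01
    horizon_days: float = 1825.0
    n_permutations: int = 9999
    seed: int = 0
    deletion_mode: str = "any"  # {"any", "deep_only"}
    p_adjust_for_filters: str = "bh"  # {"raw", "bh"}
    assume_log2: bool = True  # expression inputs are consumed as-is, on log2 scale

    def __post_init__(self) -> None:
        errs = []
        if not 0 < self.recurrence_fraction <= 1:
            errs.append("recurrence_fraction must be in (0, 1]")
        if self.min_cancers < 1:
            errs.append("min_cancers must be >= 1")
        if self.de_fc_linear <= 0:
            errs.append("de_fc_linear must be positive")
        if not 0 < self.de_p < 1:
            errs.append("de_p must be in (0, 1)")
        if self.deg_log2fc <= 0:
            errs.append("deg_log2fc must be positive")
        if not 0 < self.deg_p < 1:
            errs.append("deg_p must be in (0, 1)")
        if self.horizon_days <= 0:
            errs.append("horizon_days must be positive")
        if self.n_permutations < 1:
            errs.append("n_permutations must be >= 1")
        if self.deletion_mode not in ("any", "deep_only"):
            errs.append("deletion_mode must be 'any' or 'deep_only'")
        if self.p_adjust_for_filters not in ("raw", "bh"):
            errs.append("p_adjust_for_filters must be 'raw' or 'bh'")
        if errs:
            raise ConfigError("; ".join(errs))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key:value file.

    Absent keys take their defaults; ``path=None`` returns the defaults.
    Unknown keys and out-of-range values raise :class:`ConfigError` naming the
    offending key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a key: value mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    try:
        return AnalysisConfig(**values)
    except ConfigError as exc:
        raise ConfigError(f"invalid config ({path or 'overrides'}): {exc}") from None
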