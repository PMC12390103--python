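"""Pipeline configuration: every stage parameter in one flat record.

Serializes to a flat ``key = value`` text file; unknown keys are rejected
so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Raised on unknown keys or out-of-domain parameter values."""


@dataclass
class PipelineConfig:
    # toxin ORF screen
    min_aa: int = 30
    max_aa: int = 90
    all_starts: bool = False
    # transmembrane surrogate (Kyte-Doolittle)
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_gap: int = 5
    # homology exclusion (opt-in; empty exclusion set retains everything)
    homology_score_threshold: float = 50.0
    homology_identity_threshold: float = 0.35
    # operon proximity rule
    operon_max_gap: int = 100
    keep_operon_flagged: bool = False
    # signal scanning
    window_pad: int = 300
    promoter_threshold: float = 12.0
    promoter_max_mismatches: int = 1
    tss_offset: int = 7
    spacer_min: int = 15
    spacer_max: int = 19
    terminator_min_score: float = 18.0
    # assembly
    group_tolerance: int = 5
    min_isoform_length: int = 40
    organism_prefix: str = "TIA_"
    toxin_prefix: str = "TOX_"
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not 1 <= self.min_aa <= self.max_aa:
            raise ConfigError("need 1 <= min_aa <= max_aa")
        if self.tm_window < 1 or self.tm_min_gap < 0:
            raise ConfigError("tm_window must be >= 1 and tm_min_gap >= 0")
        if not 0 < self.spacer_min <= self.spacer_max:
            raise ConfigError("need 0 < spacer_min <= spacer_max")
        if self.window_pad < 0 or self.group_tolerance < 0:
            raise ConfigError("window_pad and group_tolerance must be >= 0")
        if self.min_isoform_length < 1:
            raise ConfigError("min_isoform_length must be >= 1")
        if not 0.0 <= self.homology_identity_threshold <= 1.0:
            raise ConfigError("homology_identity_threshold must lie in [0, 1]")
        if self.topology not in ("linear", "circular"):
            raise ConfigError("topology must be linear or circular")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
                ftype = fields[key].type
                try:
                    if ftype == "bool":
                        if value.lower() not in ("true", "false", "1", "0"):
                            raise ValueError(f"not a boolean: {value!r}")
                        kwargs[key] = value.lower() in ("true", "1")
                    elif ftype == "int":
                        kwargs[key] = int(value)
                    elif ftype == "float":
                        kwargs[key] = float(value)
                    else:
                        kwargs[key] = value
                except ValueError as exc:
                    raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")
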