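"""Analysis configuration: every calibrated threshold in one place.

Defaults follow the conventions of comparative plant karyotype studies:
Levan arm-ratio class boundaries, the Stebbins arm-ratio cut-off of 2.0,
the pericentromeric/interstitial di cut-off, and the terminal-detection
tolerance at the telomere.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    #: Levan class upper bounds (left-open intervals); AR = 1.00 exactly is M.
    levan_m_max: float = 1.70
    levan_sm_max: float = 3.00
    levan_st_max: float = 7.00
    #: Stebbins intrachromosomal cut-off: a pair counts as asymmetric if AR > this.
    stebbins_ar_threshold: float = 2.0
    #: marker position: di <= this (and not terminal) is pericentromeric.
    pcen_max_di: float = 28.0
    #: marker position: end_frac >= this counts as reaching the telomere (TER).
    ter_min_end_frac: float = 0.98
    #: count satellite length inside its arm for RL/AR/CI.
    include_satellite: bool = True
    #: decimals for table-style report output.
    round_dp: int = 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


DEFAULT_CONFIG = AnalysisConfig()
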