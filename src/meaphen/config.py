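"""A single human-editable configuration holding every pipeline threshold.

Defaults equal the platform-standard analysis parameters (burst ISI
thresholds, merge gap, activity filters, network-event participation,
permutation count) and the package's documented generator presets.  The
config round-trips through YAML so a run is fully described by one file
plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .burst import BurstParams
from .dose import SteadyStateParams
from .features import QCParams
from .netsync import SyncParams
from .stats import StatsParams
from .synth import DrugEffectModel, GeneratorParams


@dataclass(frozen=True)
class SimulationParams:
    """Shape of a simulated study: plate layout and recording schedule."""

    n_wells_per_genotype: int = 24
    duration: float = 900.0  # s, 15 min per day
    divs: tuple[int, ...] = (15, 18, 21, 24, 27)


@dataclass
class AnalysisConfig:
    burst: BurstParams = field(default_factory=BurstParams)
    sync: SyncParams = field(default_factory=SyncParams)
    qc: QCParams = field(default_factory=QCParams)
    stats: StatsParams = field(default_factory=StatsParams)
    steady: SteadyStateParams = field(default_factory=SteadyStateParams)
    sim: SimulationParams = field(default_factory=SimulationParams)
    wt: GeneratorParams = field(default_factory=lambda: _preset("WT"))
    k78r: GeneratorParams = field(default_factory=lambda: _preset("K78R"))
    drug_effect: DrugEffectModel = field(default_factory=DrugEffectModel)

    def to_yaml(self, path) -> None:
        data = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        for name, payload in data.items():
            if name not in _SECTIONS:
                raise ValueError(f"unknown config section {name!r}")
            klass = _SECTIONS[name]
            valid = {f.name for f in fields(klass)}
            unknown = set(payload) - valid
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            if "divs" in payload:
                payload["divs"] = tuple(payload["divs"])
            setattr(cfg, name, klass(**payload))
        return cfg

    def override(self, section: str, **kwargs) -> "AnalysisConfig":
        """A copy with some fields of one section replaced."""
        new = AnalysisConfig(**{n: getattr(self, n) for n in _SECTIONS})
        setattr(new, section, replace(getattr(self, section), **kwargs))
        return new


def _preset(label: str) -> GeneratorParams:
    from .synth import genotype_preset

    return genotype_preset(label)


_SECTIONS = {
    "burst": BurstParams,
    "sync": SyncParams,
    "qc": QCParams,
    "stats": StatsParams,
    "steady": SteadyStateParams,
    "sim": SimulationParams,
    "wt": GeneratorParams,
    "k78r": GeneratorParams,
    "drug_effect": DrugEffectModel,
}
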