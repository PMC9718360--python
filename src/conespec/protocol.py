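"""The fixed spectral stimulus protocol shared by real and synthetic datasets.

Nine wavelengths (330–650 nm, 40-nm steps) are each presented at seven
irradiances descending in 0.5 log-unit steps from a per-wavelength maximum
(3 log units of range).  The 63 ladder conditions, one extra recorded
condition slot (by default a repeat of the brightest 650-nm flash), and six
stability replicates delivered later in the run make up 70 averaged
responses; with 4 sweeps averaged per response the protocol delivers
280 raw stimuli in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = ["Condition", "StimulusProtocol", "default_protocol"]

DEFAULT_WAVELENGTHS = (330, 370, 410, 450, 490, 530, 570, 610, 650)

# max log10 irradiance (quanta um^-2 s^-1) per wavelength
DEFAULT_MAX_LOG_IRRADIANCE = {
    330: 5.2,
    370: 5.7,
    410: 5.7,
    450: 6.1,
    490: 6.4,
    530: 6.3,
    570: 6.4,
    610: 6.3,
    650: 7.2,
}

# the six ladder conditions re-presented late in the run as a stability check
DEFAULT_REPLICATE_CONDITIONS = (
    (330, 5.2),
    (410, 5.7),
    (490, 6.4),
    (530, 6.3),
    (570, 6.4),
    (650, 7.2),
)


@dataclass(frozen=True)
class Condition:
    """One averaged-response slot in the protocol."""

    wavelength_nm: float
    log_irradiance: float
    role: str = "unique"  # "unique" | "extra" | "replicate"
    sweep_count: int = 4

    @property
    def is_replicate(self) -> bool:
        return self.role == "replicate"


@dataclass(frozen=True)
class StimulusProtocol:
    wavelengths: tuple = DEFAULT_WAVELENGTHS
    max_log_irradiance: dict = field(
        default_factory=lambda: dict(DEFAULT_MAX_LOG_IRRADIANCE)
    )
    n_steps: int = 7
    step: float = 0.5
    n_sweep_averages: int = 4
    flash_ms: tuple = (280, 300)
    extra_condition: tuple = (650, 7.2)
    replicate_conditions: tuple = DEFAULT_REPLICATE_CONDITIONS

    def __post_init__(self):
        for wl in self.wavelengths:
            if wl not in self.max_log_irradiance:
                raise ValueError(f"no maximal irradiance for wavelength {wl}")
        ladder = {
            (wl, round(i, 6))
            for wl in self.wavelengths
            for i in self.irradiance_grid(wl)
        }
        for wl, irr in self.replicate_conditions:
            if (wl, round(irr, 6)) not in ladder:
                raise ValueError(f"replicate condition {(wl, irr)} not in ladder")
        wl, irr = self.extra_condition
        if (wl, round(irr, 6)) not in ladder:
            raise ValueError(f"extra condition {(wl, irr)} not in ladder")

    def irradiance_grid(self, wl) -> list[float]:
        """Descending ladder of ``n_steps`` log irradiances at wavelength ``wl``."""
        if wl not in self.max_log_irradiance:
            raise KeyError(f"wavelength {wl} not in protocol")
        top = self.max_log_irradiance[wl]
        return [round(top - self.step * j, 10) for j in range(self.n_steps)]

    def conditions(self) -> list[Condition]:
        """All 70 averaged-response slots: ladder, extra slot, stability replicates."""
        out = [
            Condition(wl, irr, "unique", self.n_sweep_averages)
            for wl in self.wavelengths
            for irr in self.irradiance_grid(wl)
        ]
        wl, irr = self.extra_condition
        out.append(Condition(wl, irr, "extra", self.n_sweep_averages))
        for wl, irr in self.replicate_conditions:
            out.append(Condition(wl, irr, "replicate", self.n_sweep_averages))
        return out

    @property
    def n_unique_conditions(self) -> int:
        """Recorded unique-condition slots (ladder plus the extra slot)."""
        return len(self.wavelengths) * self.n_steps + 1

    @property
    def n_averaged_responses(self) -> int:
        return self.n_unique_conditions + len(self.replicate_conditions)

    @property
    def n_raw_stimuli(self) -> int:
        return self.n_averaged_responses * self.n_sweep_averages

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        d = json.loads(text)
        d["wavelengths"] = tuple(d["wavelengths"])
        d["max_log_irradiance"] = {int(k): v for k, v in d["max_log_irradiance"].items()}
        d["flash_ms"] = tuple(d["flash_ms"])
        d["extra_condition"] = tuple(d["extra_condition"])
        d["replicate_conditions"] = tuple(tuple(c) for c in d["replicate_conditions"])
        return cls(**d)


def default_protocol() -> StimulusProtocol:
    """The standard 9-wavelength x 7-irradiance protocol (70 averaged responses)."""
    return StimulusProtocol()
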