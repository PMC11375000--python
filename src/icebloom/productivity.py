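"""Potential net primary production from 14C incubation counts.

A sample spiked with NaH14CO3 fixes labelled carbon in proportion to its
photosynthetic rate; after subtracting the immediately-filtered blank and
normalising by the total added activity, the carbon fixation rate is

    NPP = [DIC] * (DPM_sample - DPM_0%) * 1.05 / (DPM_100% * t)

where the 1.05 corrects for biological fractionation against 14C relative
to 12C. Dark-control fixation is subtracted from the (duplicate-averaged)
light incubations to yield net potential NPP. Rates are reported in
ug C L-1 d-1; negative net rates are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

import numpy as np

__all__ = [
    "IncubationRecord",
    "NppResult",
    "npp_from_incubation",
    "net_npp",
    "chl_specific_npp",
    "CARBON_UG_PER_UMOL",
    "FRACTIONATION",
]

#: Molar mass of carbon, ug per umol.
CARBON_UG_PER_UMOL = 12.011
#: Correction for fractionation against 14C relative to 12C.
FRACTIONATION = 1.05


@dataclass(frozen=True)
class IncubationRecord:
    """One scintillation-counted incubation bottle."""

    dpm_sample: float        # DPM of the incubated, filtered sample
    dpm_blank: float         # DPM_0%: immediately-filtered blank
    dpm_total: float         # DPM_100%: total added spike activity
    dic: float               # umol C L-1
    duration_days: float     # incubation duration t (d)
    light: bool = True       # False for the dark control
    volume_l: float = 0.5
    source: str = "water"    # water | ice-bottom

    def __post_init__(self) -> None:
        if min(self.dpm_sample, self.dpm_blank) < 0 or self.dpm_total <= 0:
            raise ValueError("DPM counts must be >= 0 and DPM_100% > 0")
        if self.duration_days <= 0:
            raise ValueError("incubation duration must be > 0")
        if self.dic <= 0:
            raise ValueError("DIC must be > 0")


@dataclass(frozen=True)
class NppResult:
    """Net potential NPP for one sampling event (ug C L-1 d-1)."""

    gross: float             # duplicate-mean light rate
    dark: float              # dark-control rate (nan if missing)
    net: float               # gross - dark (nan if dark missing)
    duplicate_spread: float  # max - min over light duplicates
    below_blank: bool        # any light DPM_sample < DPM_0%
    missing_dark: bool = False


def npp_from_incubation(record: IncubationRecord) -> float:
    """Carbon fixation rate of one bottle, ug C L-1 d-1.

    Linear in (DPM_sample - DPM_0%) and in DIC; may be negative when the
    sample counted below its blank (reported as-is).
    """
    rate_umol = (record.dic * (record.dpm_sample - record.dpm_blank)
                 * FRACTIONATION / (record.dpm_total * record.duration_days))
    return rate_umol * CARBON_UG_PER_UMOL


def net_npp(light_records, dark_record: IncubationRecord | None) -> NppResult:
    """Duplicate-mean light rate minus the dark-control rate.

    With no dark control the gross rate is still reported, flagged
    ``missing_dark`` and with net undefined (nan).
    """
    light_records = list(light_records)
    if not light_records:
        raise ValueError("need at least one light incubation")
    if any(not r.light for r in light_records):
        raise ValueError("dark record passed among light records")
    rates = [npp_from_incubation(r) for r in light_records]
    gross = mean(rates)
    spread = max(rates) - min(rates)
    below = any(r.dpm_sample < r.dpm_blank for r in light_records)
    if dark_record is None:
        return NppResult(gross=gross, dark=float("nan"), net=float("nan"),
                         duplicate_spread=spread, below_blank=below,
                         missing_dark=True)
    if dark_record.light:
        raise ValueError("dark_record is flagged as a light incubation")
    dark = npp_from_incubation(dark_record)
    return NppResult(gross=gross, dark=dark, net=gross - dark,
                     duplicate_spread=spread, below_blank=below)


def chl_specific_npp(net_npp_value: float, chl: float) -> float:
    """Chl-a-normalised production, ug C (ug Chl-a)-1 d-1."""
    if chl <= 0:
        raise ValueError("Chl-a concentration must be > 0")
    return net_npp_value / chl


def split_event(records) -> tuple[list[IncubationRecord], IncubationRecord | None]:
    """Split one sampling event's records into (light duplicates, dark)."""
    light = [r for r in records if r.light]
    dark = [r for r in records if not r.light]
    if len(dark) > 1:
        raise ValueError("expected at most one dark control per event")
    return light, (dark[0] if dark else None)
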