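"""Scenario and analysis configuration.

A single :class:`ScenarioConfig` describes one synthetic field campaign
(what the generators emit); :class:`AnalysisConfig` collects every constant
the analysis stages use (quality thresholds, averaging bounds, window
lengths), so sensitivity runs need no code changes. Both round-trip through
a single YAML file.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Nominal light-chain sensor depths below the ice surface (m).
DEFAULT_SENSOR_DEPTHS: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 9, 14, 21, 32, 50)


@dataclass(frozen=True)
class LeadEvent:
    """An open-water lead locally amplifying under-ice light at one site."""

    site: str
    start: dt.date
    duration_days: int
    amplification: float = 10.0

    def covers(self, day: dt.date) -> bool:
        return self.start <= day < self.start + dt.timedelta(days=self.duration_days)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic under-ice campaign.

    Defaults emulate a high-Arctic late-winter drift: a flat picophytoplankton
    baseline of 0.015 ug Chl-a / L that starts growing exponentially at
    ``onset_day`` with net accumulation rate ``r_post``; snow-attenuated,
    ice-attenuated light decaying exponentially in the water column; modest
    multiplicative sensor noise.
    """

    seed: int = 0
    latitude: float = 86.0
    start: dt.date = dt.date(2020, 2, 1)
    end: dt.date = dt.date(2020, 4, 30)
    baseline_chl: float = 0.015          # ug L-1
    onset_day: dt.date = dt.date(2020, 3, 27)
    r_post: float = 0.06                 # d-1, post-onset accumulation rate
    sigma_log: float = 0.10              # lognormal noise scale
    chl_replicates: int = 2              # underway replicates per day
    kappa_w: float = 0.05                # m-1, water attenuation
    kappa_snow: float = 14.1             # m-1, snow attenuation
    ice_transmissivity: float = 0.01
    shading_s: float = 0.3               # near-surface shading amplitude
    shading_ell: float = 2.0             # m, shading decay length
    sensor_depths: tuple[float, ...] = DEFAULT_SENSOR_DEPTHS
    surface_scale: float = 400.0         # clear-sky midday PAR scale
    cadence_minutes: int = 10            # light-chain sampling cadence
    lead_events: tuple[LeadEvent, ...] = ()
    snow_depths: dict[str, float] = field(
        default_factory=lambda: {"hh": 0.20, "gg": 0.19, "ee": 0.21}
    )
    ice_thickness: float = 1.8           # m

    def __post_init__(self) -> None:
        if self.r_post < 0:
            raise ValueError("r_post must be >= 0")
        if not 0 < self.kappa_w <= 0.06:
            raise ValueError("kappa_w must be in (0, 0.06]")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.baseline_chl <= 0:
            raise ValueError("baseline_chl must be > 0")
        if not 0 <= self.shading_s < 1:
            raise ValueError("shading_s must be in [0, 1)")
        depths = tuple(self.sensor_depths)
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("sensor_depths must be strictly increasing")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.snow_depths)


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants of the analysis chain (all exposed for sensitivity runs)."""

    sigma_max: float = 1.0          # umol m-2 s-1, fit-residual rejection
    kappa_max: float = 0.06         # m-1, attenuation rejection
    area_factor: float = 1.33       # snow-heterogeneity correction
    kappa_snow: float = 14.1        # m-1
    z_min: float = 3.0              # m, mixed-layer averaging bounds
    z_max: float = 50.0
    window_hours: float = 24.0      # temporal averaging window
    roc_interval_days: int = 5      # rate-of-change window
    roc_run_days: int = 5           # required positive-run length
    accumulation_interval_days: int = 7
    junction_depth: float = 21.0    # m, exponential/linear splice depth
    exclude_leads: bool = True


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def scenario_to_dict(scenario: ScenarioConfig, analysis: AnalysisConfig) -> dict:
    return {"scenario": _encode(scenario), "analysis": _encode(analysis)}


def save_config(path, scenario: ScenarioConfig, analysis: AnalysisConfig | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario, analysis or AnalysisConfig()), fh)


def _parse_date(v):
    return v if isinstance(v, dt.date) else dt.date.fromisoformat(v)


def load_config(path) -> tuple[ScenarioConfig, AnalysisConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sc = dict(raw.get("scenario", {}))
    for key in ("start", "end", "onset_day"):
        if key in sc:
            sc[key] = _parse_date(sc[key])
    if "sensor_depths" in sc:
        sc["sensor_depths"] = tuple(sc["sensor_depths"])
    if "lead_events" in sc:
        sc["lead_events"] = tuple(
            LeadEvent(
                site=e["site"],
                start=_parse_date(e["start"]),
                duration_days=int(e["duration_days"]),
                amplification=float(e.get("amplification", 10.0)),
            )
            for e in sc["lead_events"]
        )
    scenario = ScenarioConfig(**sc)
    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return scenario, analysis


def config_hash(scenario: ScenarioConfig, analysis: AnalysisConfig) -> str:
    """Stable sha256 of the full configuration (for run manifests)."""
    blob = json.dumps(scenario_to_dict(scenario, analysis), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
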