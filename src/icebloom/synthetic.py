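"""Synthetic field-campaign generators.

Everything the analysis pipeline consumes can be generated here with the
statistical structure the analysis assumes: incident surface PAR from a
low-precision astronomical solar-position model, snow-depth fields by ice
surface class, under-ice light-chain profiles (snow + ice transmissivity,
exponential water-column decay, a near-surface shading deficit, lognormal
sensor noise, optional lead amplification), a flat-then-exponential Chl-a
series, and 14C incubation DPM counts constructed by inverting the
production equation — so every estimator in the package has a generator
round trip.

All randomness flows through :func:`numpy.random.default_rng` seeded from
the scenario, so identical configurations are bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .config import ScenarioConfig, LeadEvent
from .light_profiles import IrradianceProfile
from .productivity import CARBON_UG_PER_UMOL, FRACTIONATION, IncubationRecord
from .snow_optics import SSL_THICKNESS, SnowOpticsModel, snow_transmissivity

SECONDS_PER_DAY = 86400.0

#: Per-class truncated-normal snow-depth parameters (mean, sd) in metres,
#: truncated at the 3 cm surface scattering layer. Level ice carries the
#: thinnest snow; deformation traps drifting snow.
SNOW_CLASS_PARAMS = {
    "level": (0.20, 0.03),
    "rubble": (0.28, 0.06),
    "deformed": (0.33, 0.10),
}
EQUAL_CLASS_MIX = {"level": 1 / 3, "rubble": 1 / 3, "deformed": 1 / 3}


# ---------------------------------------------------------------------------
# surface irradiance
# ---------------------------------------------------------------------------

def solar_elevation(latitude: float, when: dt.datetime) -> float:
    """Solar elevation angle (degrees) from declination + hour angle.

    Low-precision astronomical approximation (declination from day of year,
    solar time = UTC, longitude 0): adequate for the diurnal shape and the
    polar-night/polar-day transitions, which is all the generators need.
    """
    doy = when.timetuple().tm_yday
    decl = math.radians(23.44) * math.sin(2 * math.pi * (284 + doy) / 365.0)
    hours = when.hour + when.minute / 60 + when.second / 3600
    hour_angle = math.radians(15.0 * (hours - 12.0))
    lat = math.radians(latitude)
    sin_elev = (math.sin(lat) * math.sin(decl)
                + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_elev))))


@dataclass(frozen=True)
class SurfaceParSeries:
    """Regularly sampled incident surface PAR at one latitude."""

    timestamps: tuple[dt.datetime, ...]
    latitude: float
    par: tuple[float, ...]   # umol photons m-2 s-1

    def as_arrays(self):
        return (np.array(self.timestamps), np.asarray(self.par, dtype=float))


def gen_surface_par(latitude: float, start: dt.date, end: dt.date,
                    step_minutes: int = 10,
                    scale: float = 400.0) -> SurfaceParSeries:
    """Deterministic clear-sky surface PAR: scale * max(0, sin(elevation)).

    ``end`` is exclusive; the step must divide 24 h.
    """
    if not -90 <= latitude <= 90:
        raise ValueError("latitude must be in [-90, 90]")
    if end <= start:
        raise ValueError("empty date range")
    if (24 * 60) % step_minutes != 0:
        raise ValueError("step must divide 24 h")
    t0 = dt.datetime.combine(start, dt.time(), tzinfo=dt.timezone.utc)
    n = int((end - start).days * 24 * 60 / step_minutes)
    stamps = tuple(t0 + dt.timedelta(minutes=step_minutes * i) for i in range(n))
    par = tuple(
        scale * max(0.0, math.sin(math.radians(solar_elevation(latitude, t))))
        for t in stamps
    )
    return SurfaceParSeries(timestamps=stamps, latitude=latitude, par=par)


# ---------------------------------------------------------------------------
# snow fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnowDepthSample:
    surface_class: str   # level | rubble | deformed
    depth: float         # m, >= 0.03


def gen_snow_field(n: int, class_mix: dict[str, float] | None = None,
                   class_params: dict[str, tuple[float, float]] | None = None,
                   seed: int = 0) -> list[SnowDepthSample]:
    """Draw a heterogeneous snow-depth field by surface class.

    Depths are truncated normal per class (lower bound 3 cm). Class shares
    must sum to 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(class_mix or EQUAL_CLASS_MIX)
    params = dict(class_params or SNOW_CLASS_PARAMS)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix must sum to 1")
    unknown = set(mix) - set(params)
    if unknown:
        raise ValueError(f"unknown surface classes: {sorted(unknown)}")
    for cls, (mu, sd) in params.items():
        if mu <= 0 or sd <= 0:
            raise ValueError(f"non-positive depth parameters for class {cls!r}")
    rng = np.random.default_rng(seed)
    classes = sorted(mix)
    draws = rng.choice(classes, size=n, p=[mix[c] for c in classes])
    out = []
    for cls in classes:
        k = int((draws == cls).sum())
        if k == 0:
            continue
        mu, sd = params[cls]
        a = (SSL_THICKNESS - mu) / sd
        depths = truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=k,
                               random_state=rng)
        out.extend(SnowDepthSample(cls, float(d)) for d in depths)
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# light chains
# ---------------------------------------------------------------------------

def transmissivity_chain(scenario: ScenarioConfig, snow_depth: float) -> float:
    """Combined snow x ice transmissivity at one site (deterministic part)."""
    t_snow = snow_transmissivity(
        snow_depth, SnowOpticsModel(kappa_snow=scenario.kappa_snow))
    return t_snow * scenario.ice_transmissivity


def gen_light_chain(site: str, scenario: ScenarioConfig,
                    surface: SurfaceParSeries, snow_depth: float,
                    ice_thickness: float | None = None) -> list[IrradianceProfile]:
    """Synthesize the light-chain profile time series at one site.

    PAR(z, t) = E_surf(t) * T_snow(h) * T_ice * exp(-kappa_w z)
                * (1 - s exp(-z/ell)) * lognormal noise,
    amplified by any active lead event. With sigma_log = 0 and s = 0 each
    profile is exactly exponential with slope kappa_w.
    """
    thickness = scenario.ice_thickness if ice_thickness is None else ice_thickness
    if thickness <= 0:
        raise ValueError("ice thickness must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=scenario.seed, spawn_key=(zlib.crc32(site.encode()),)))
    z = np.asarray(scenario.sensor_depths, dtype=float)
    shade = 1.0 - scenario.shading_s * np.exp(-z / scenario.shading_ell)
    t_chain = transmissivity_chain(scenario, snow_depth)
    leads = [e for e in scenario.lead_events if e.site == site]
    profiles = []
    for stamp, e_surf in zip(surface.timestamps, surface.par):
        par = e_surf * t_chain * np.exp(-scenario.kappa_w * z) * shade
        for event in leads:
            if event.covers(stamp.date()):
                par = par * event.amplification
        if scenario.sigma_log > 0:
            par = par * rng.lognormal(0.0, scenario.sigma_log, size=z.size)
        profiles.append(IrradianceProfile(
            site=site, timestamp=stamp, depths=tuple(z),
            par=tuple(float(v) for v in par)))
    return profiles


# ---------------------------------------------------------------------------
# chlorophyll a
# ---------------------------------------------------------------------------

def chl_expectation(day: dt.date, scenario: ScenarioConfig) -> float:
    """Noiseless Chl-a expectation: flat baseline, exponential after onset."""
    days_after = (day - scenario.onset_day).days
    if days_after <= 0:
        return scenario.baseline_chl
    return scenario.baseline_chl * math.exp(scenario.r_post * days_after)


def gen_chl_series(start: dt.date, end: dt.date, scenario: ScenarioConfig,
                   source: str = "underway"):
    """Generate replicate-level Chl-a observations over [start, end].

    Returns an :class:`icebloom.onset.ChlSeries`. Multiplicative lognormal
    noise; ``scenario.chl_replicates`` observations per day.
    """
    from .onset import ChlSeries  # local import to avoid a cycle

    if not (start <= scenario.onset_day <= end):
        raise ValueError("onset day must lie inside the date range")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=scenario.seed, spawn_key=(7,)))
    n_days = (end - start).days + 1
    dates, values = [], []
    for i in range(n_days):
        day = start + dt.timedelta(days=i)
        mu = chl_expectation(day, scenario)
        for _ in range(max(scenario.chl_replicates, 1)):
            noise = rng.lognormal(0.0, scenario.sigma_log) if scenario.sigma_log > 0 else 1.0
            dates.append(day)
            values.append(mu * noise)
    return ChlSeries(dates=tuple(dates), concentrations=tuple(values),
                     source=source)


# ---------------------------------------------------------------------------
# 14C incubations
# ---------------------------------------------------------------------------

def gen_incubations(true_npp, dic: float = 2100.0, duration_days: float = 1.0,
                    dpm_total: float = 1e6, blank_fraction: float = 0.25,
                    dark_rate: float = 0.0, n_replicates: int = 2,
                    noise_cv: float = 0.0, seed: int = 0,
                    source: str = "water") -> list[list[IncubationRecord]]:
    """Construct incubation DPM counts that invert to given net NPP values.

    For each value in ``true_npp`` (ug C L-1 d-1, net of the dark control)
    this emits ``n_replicates`` light records plus one dark record whose
    gross rates are ``true_npp + dark_rate`` and ``dark_rate``. The sample
    count is placed so that the blank is ``blank_fraction`` of it; optional
    multiplicative counting noise with coefficient of variation ``noise_cv``
    is applied to the light/dark DPM counts.
    """
    if not 0 <= blank_fraction < 1:
        raise ValueError("blank fraction must be in [0, 1)")
    if duration_days <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    events = []
    for npp in np.atleast_1d(np.asarray(true_npp, dtype=float)):
        if npp < 0:
            raise ValueError("true NPP must be >= 0")
        event = []
        for rate, flag, reps in ((npp + dark_rate, "light", n_replicates),
                                 (dark_rate, "dark", 1)):
            rate_umol = rate / CARBON_UG_PER_UMOL
            delta = rate_umol * dpm_total * duration_days / (dic * FRACTIONATION)
            dpm_sample = delta / (1.0 - blank_fraction)
            dpm_blank = blank_fraction * dpm_sample
            for _ in range(reps):
                noisy = dpm_sample
                if noise_cv > 0:
                    noisy = dpm_sample * rng.lognormal(0.0, noise_cv)
                event.append(IncubationRecord(
                    dpm_sample=float(noisy), dpm_blank=float(dpm_blank),
                    dpm_total=float(dpm_total), dic=float(dic),
                    duration_days=float(duration_days), light=(flag == "light"),
                    source=source))
        events.append(event)
    return events
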