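"""Tab-delimited I/O for every table the pipeline reads or writes.

All files are plain TSV with a header row, '.' decimal separator and
ISO 8601 UTC timestamps, mirroring the layout of polar-repository
time-series tables.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

import pandas as pd

from .light_profiles import IrradianceProfile
from .onset import ChlSeries
from .productivity import IncubationRecord
from .synthetic import SnowDepthSample

_TS_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


def _parse_ts(value: str) -> dt.datetime:
    return dt.datetime.strptime(value, _TS_FORMAT).replace(tzinfo=dt.timezone.utc)


# -- irradiance profiles (long format: one row per sensor reading) ----------

def write_profiles(path, profiles) -> None:
    rows = [
        {"site": p.site, "timestamp": p.timestamp.strftime(_TS_FORMAT),
         "depth_m": z, "par_umol_m2_s": v}
        for p in profiles for z, v in zip(p.depths, p.par)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[IrradianceProfile]:
    frame = pd.read_csv(path, sep="\t")
    groups = defaultdict(list)
    for row in frame.itertuples(index=False):
        groups[(row.site, row.timestamp)].append((row.depth_m, row.par_umol_m2_s))
    profiles = []
    for (site, ts), readings in groups.items():
        readings.sort()
        profiles.append(IrradianceProfile(
            site=site, timestamp=_parse_ts(ts),
            depths=tuple(z for z, _ in readings),
            par=tuple(v for _, v in readings)))
    profiles.sort(key=lambda p: (p.site, p.timestamp))
    return profiles


# -- snow depths -------------------------------------------------------------

def write_snow(path, samples) -> None:
    pd.DataFrame(
        [{"surface_class": s.surface_class, "depth_m": s.depth} for s in samples]
    ).to_csv(path, sep="\t", index=False)


def read_snow(path) -> list[SnowDepthSample]:
    frame = pd.read_csv(path, sep="\t")
    return [SnowDepthSample(r.surface_class, float(r.depth_m))
            for r in frame.itertuples(index=False)]


# -- chlorophyll a -----------------------------------------------------------

def write_chl(path, series: ChlSeries, depth_m: float = 11.0) -> None:
    pd.DataFrame({
        "date": [d.isoformat() for d in series.dates],
        "depth_m": depth_m,
        "chl_ug_l": series.concentrations,
        "source": series.source,
    }).to_csv(path, sep="\t", index=False)


def read_chl(path) -> ChlSeries:
    frame = pd.read_csv(path, sep="\t")
    sources = frame["source"].unique()
    return ChlSeries(
        dates=tuple(dt.date.fromisoformat(d) for d in frame["date"]),
        concentrations=tuple(float(v) for v in frame["chl_ug_l"]),
        source=sources[0] if len(sources) == 1 else "mixed")


# -- 14C incubations ---------------------------------------------------------

def write_incubations(path, events) -> None:
    rows = []
    for i, event in enumerate(events):
        for rec in event:
            rows.append({
                "event": i, "dpm_sample": rec.dpm_sample,
                "dpm_blank": rec.dpm_blank, "dpm_total": rec.dpm_total,
                "dic_umol_l": rec.dic, "duration_days": rec.duration_days,
                "bottle": "light" if rec.light else "dark",
                "volume_l": rec.volume_l, "source": rec.source,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_incubations(path) -> list[list[IncubationRecord]]:
    frame = pd.read_csv(path, sep="\t")
    events = defaultdict(list)
    for r in frame.itertuples(index=False):
        events[r.event].append(IncubationRecord(
            dpm_sample=float(r.dpm_sample), dpm_blank=float(r.dpm_blank),
            dpm_total=float(r.dpm_total), dic=float(r.dic_umol_l),
            duration_days=float(r.duration_days), light=(r.bottle == "light"),
            volume_l=float(r.volume_l), source=r.source))
    return [events[k] for k in sorted(events)]
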