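"""Mixed-layer light exposure and euphotic-depth arithmetic.

Cells drifting in a homogeneously mixed surface layer experience the
*average* light over that layer, not the light at any one depth. This
module averages corrected under-ice profiles vertically (3-50 m by
default, analytic piecewise integrals), temporally (the 24 h before each
biological sampling), and horizontally across sites, and converts light
thresholds into euphotic-zone depths via z = ln(E0/E_threshold) / k.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "MixedLayerPAR",
    "EuphoticQuery",
    "depth_average",
    "time_average",
    "cross_site_stats",
    "euphotic_depth",
    "threshold_fraction",
]


@dataclass(frozen=True)
class MixedLayerPAR:
    """Daily mixed-layer PAR: per-site means and the cross-site summary."""

    date: dt.date
    site_means: dict[str, float]        # 24 h x 3-50 m means, all sites seen
    mean: float                         # cross-site mean (excluded sites out)
    sd: float                           # sample sd (n-1); 0 when n = 1
    n_sites: int
    correction_factor: float = 1.0
    excluded_sites: tuple[str, ...] = ()   # e.g. lead-affected


@dataclass(frozen=True)
class EuphoticQuery:
    """A euphotic-depth question: surface light, attenuation, threshold."""

    e0: float                  # umol photons m-2 s-1
    k: float                   # m-1
    threshold: float | None = None   # absolute PAR threshold
    fraction: float | None = None    # fraction of surface, e.g. 0.01

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.k <= 0:
            raise ValueError("E0 and k must be > 0")
        if (self.threshold is None) == (self.fraction is None):
            raise ValueError("give exactly one of threshold or fraction")
        if self.threshold is not None and not 0 < self.threshold <= self.e0:
            raise ValueError("threshold must be in (0, E0]")
        if self.fraction is not None and not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


def depth_average(profile, z_min: float = 3.0, z_max: float = 50.0) -> float:
    """Mean PAR over [z_min, z_max]: (1/(z_max-z_min)) * integral(profile).

    Uses the profile's exact analytic ``integral`` when available
    (:class:`icebloom.light_profiles.AssembledProfile`), otherwise adaptive
    quadrature on the callable.
    """
    if z_min >= z_max:
        raise ValueError("z_min must be < z_max")
    if hasattr(profile, "integral"):
        total = profile.integral(z_min, z_max)
    else:
        total, _ = quad(profile, z_min, z_max, limit=200)
    return total / (z_max - z_min)


def time_average(timestamps, values, sampling_time: dt.datetime,
                 window_hours: float = 24.0,
                 expected_step: dt.timedelta | None = None
                 ) -> tuple[float, float]:
    """Mean of ``values`` over (sampling_time - window, sampling_time].

    Returns (mean, gap_fraction); the gap fraction compares the number of
    records present against the number a regular cadence would supply
    (cadence inferred from the median spacing unless given).
    """
    stamps = list(timestamps)
    vals = np.asarray(values, dtype=float)
    if len(stamps) != vals.size:
        raise ValueError("timestamps and values must have equal length")
    window = dt.timedelta(hours=window_hours)
    lo = sampling_time - window
    in_window = [i for i, t in enumerate(stamps) if lo < t <= sampling_time]
    if not in_window:
        raise ValueError("no records inside the averaging window")
    if expected_step is None:
        if len(stamps) > 1:
            gaps = sorted((b - a).total_seconds()
                          for a, b in zip(stamps, stamps[1:]))
            expected_step = dt.timedelta(seconds=gaps[len(gaps) // 2])
        else:
            expected_step = window
    n_expected = max(round(window / expected_step), 1)
    gap_fraction = max(0.0, 1.0 - len(in_window) / n_expected)
    return float(vals[in_window].mean()), gap_fraction


def cross_site_stats(site_means) -> tuple[float, float, int]:
    """Cross-site (mean, sample sd, n); sd = 0 for a single site."""
    vals = np.asarray(list(site_means), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one site")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def euphotic_depth(query: EuphoticQuery) -> float:
    """Depth (m) at which light falls to the query's threshold.

    z = ln(E0 / E_threshold) / k for an absolute threshold,
    z = ln(1 / f) / k for a fractional one.
    """
    if query.fraction is not None:
        return math.log(1.0 / query.fraction) / query.k
    return math.log(query.e0 / query.threshold) / query.k


def threshold_fraction(threshold: float, surface: float) -> float:
    """A light threshold as a percentage of the surface value."""
    if threshold <= 0 or surface <= 0:
        raise ValueError("threshold and surface PAR must be > 0")
    return 100.0 * threshold / surface
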