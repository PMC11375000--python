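"""Snow radiative transfer for broadband PAR.

Snow on sea ice is treated as a surface scattering layer (uppermost 3 cm,
lumped transmissivity ``I0``) over a homogeneous slab with exponential
attenuation:

    T_snow,PAR(h) = I0 * exp(-kappa_snow * (h - 0.03 m))

``I0`` cancels in every transmissivity *ratio*, which is all the
heterogeneity correction needs. The module also estimates ``kappa_snow``
from paired above-/below-snow irradiance and computes the area-heterogeneity
factor: the ratio of transect-averaged to site-averaged transmissivity,
which exceeds 1 whenever the transect contains patches of thin snow (the
exponential is convex, so thin patches dominate the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Thickness of the surface scattering layer (m); fixed by the model.
SSL_THICKNESS = 0.03


@dataclass(frozen=True)
class SnowOpticsModel:
    """Bulk snow optics: attenuation coefficient and SSL transmissivity."""

    kappa_snow: float = 14.1   # m-1
    i0: float = 1.0            # SSL transmissivity; cancels in ratios

    def __post_init__(self) -> None:
        if self.kappa_snow <= 0:
            raise ValueError("kappa_snow must be > 0")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")


def snow_transmissivity(h_snow, model: SnowOpticsModel = SnowOpticsModel()):
    """PAR transmissivity of a snow layer of thickness ``h_snow`` (m).

    Accepts scalars or arrays; every depth must be at least the 3 cm
    surface scattering layer.
    """
    h = np.asarray(h_snow, dtype=float)
    if np.any(h < SSL_THICKNESS):
        raise ValueError(f"snow depth below the {SSL_THICKNESS} m surface scattering layer")
    t = model.i0 * np.exp(-model.kappa_snow * (h - SSL_THICKNESS))
    return float(t) if np.isscalar(h_snow) else t


@dataclass(frozen=True)
class AttenuationEstimate:
    kappa_snow: float        # m-1
    stderr: float            # m-1
    n_used: int
    n_excluded: int


def estimate_snow_attenuation(par_above, par_below, snow_depths) -> AttenuationEstimate:
    """Estimate ``kappa_snow`` from paired above-/below-snow PAR.

    Log-linear regression of ln(below/above) on (h_snow - 0.03 m); the slope
    magnitude is the attenuation coefficient. Pairs with a non-positive
    ratio are excluded; at least 3 usable pairs are required.
    """
    above = np.asarray(par_above, dtype=float)
    below = np.asarray(par_below, dtype=float)
    depths = np.asarray(snow_depths, dtype=float)
    if not (above.shape == below.shape == depths.shape):
        raise ValueError("above, below and depths must have equal length")
    if np.any(depths <= SSL_THICKNESS):
        raise ValueError("snow depths must exceed the surface scattering layer")
    ok = (above > 0) & (below > 0)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError("need at least 3 usable above/below pairs")
    x = depths[ok] - SSL_THICKNESS
    y = np.log(below[ok] / above[ok])
    res = stats.linregress(x, y)
    return AttenuationEstimate(
        kappa_snow=float(-res.slope),
        stderr=float(res.stderr),
        n_used=int(ok.sum()),
        n_excluded=n_excluded,
    )


def heterogeneity_factor(transect_depths, site_depths,
                         model: SnowOpticsModel = SnowOpticsModel()) -> float:
    """Ratio of transect-mean to site-mean snow transmissivity.

    ``I0`` cancels exactly. Values above 1 quantify how much the thin-snow
    patches along the transects raise the area-averaged light relative to
    the (level-ice) deployment sites.
    """
    transect = np.asarray(transect_depths, dtype=float)
    sites = np.asarray(site_depths, dtype=float)
    if transect.size == 0 or sites.size == 0:
        raise ValueError("transect and site depth collections must be non-empty")
    return float(np.mean(snow_transmissivity(transect, model))
                 / np.mean(snow_transmissivity(sites, model)))


def apply_area_correction(par, factor: float = 1.33):
    """Scale PAR value(s) by the snow-heterogeneity factor (default +33%)."""
    if factor < 1:
        raise ValueError("area-heterogeneity factor must be >= 1")
    arr = np.asarray(par, dtype=float) * factor
    return float(arr) if np.isscalar(par) else arr
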