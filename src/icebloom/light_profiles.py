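"""Correction and quality control of vertical under-ice irradiance profiles.

Downwelling PAR under a laterally homogeneous ice cover decays exponentially
with depth, E(z) = E0 * exp(-kappa * z). Two systematic departures are
handled here:

* a near-surface *shading deficit*: the shallow sensors sample a narrow,
  locally shaded patch of the underside, so the observed profile is modelled
  as E0 * exp(-kappa z) * (1 - s * exp(-z / ell)) and the unshaded
  exponential is restored;
* a *linear deep tail*: below ~21 m the measured decay is better described
  by a straight line through the two deepest sensors.

Fits are rejected (profile passed through uncorrected) when the residual
standard deviation exceeds 1 umol photons m-2 s-1 or the fitted attenuation
exceeds 0.06 m-1 — implausibly turbid for low-biomass polar waters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IrradianceProfile",
    "ProfileFit",
    "AssembledProfile",
    "fit_attenuation",
    "correct_shading",
    "validate_fit",
    "fit_linear_tail",
    "assemble_corrected_profile",
]

SIGMA_MAX = 1.0     # umol photons m-2 s-1
KAPPA_MAX = 0.06    # m-1
DARK_PAR = 1e-4     # umol photons m-2 s-1; below instrumental relevance
MIN_POINTS = 4


@dataclass(frozen=True)
class IrradianceProfile:
    """One site x timestamp vertical set of PAR readings."""

    site: str
    timestamp: dt.datetime
    depths: tuple[float, ...]      # m, positive downward, strictly increasing
    par: tuple[float, ...]         # umol photons m-2 s-1
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        p = np.asarray(self.par, dtype=float)
        if d.size != p.size:
            raise ValueError("depths and par must have equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("PAR values must be non-negative")

    def with_par(self, par) -> "IrradianceProfile":
        return replace(self, par=tuple(float(v) for v in par))


@dataclass(frozen=True)
class ProfileFit:
    """Fitted attenuation/shading parameters plus QC verdict."""

    e0: float = np.nan           # surface intercept
    kappa: float = np.nan        # m-1
    s: float = 0.0               # shading amplitude
    ell: float = np.nan          # m, shading length
    sigma: float = np.nan        # residual sd, linear PAR scale
    tail_slope: float = np.nan   # umol m-2 s-1 per m
    tail_intercept: float = np.nan
    method: str = "corrected"    # corrected | uncorrected | linear-tail | dark
    valid: bool = True
    reason: str = ""
    n_points: int = 0


def _usable(profile: IrradianceProfile, window=None):
    z = np.asarray(profile.depths, dtype=float)
    p = np.asarray(profile.par, dtype=float)
    mask = p > 0
    if window is not None:
        lo, hi = window
        mask &= (z >= lo) & (z <= hi)
    return z[mask], p[mask]


def fit_attenuation(profile: IrradianceProfile, window=None) -> ProfileFit:
    """Log-linear least-squares fit of E(z) = E0 * exp(-kappa z).

    Non-positive readings are excluded (log undefined); at least 4 usable
    sensors are required.
    """
    z, p = _usable(profile, window)
    if z.size < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} positive PAR readings, got {z.size}")
    slope, intercept = np.polyfit(z, np.log(p), 1)
    e0, kappa = float(np.exp(intercept)), float(-slope)
    resid = p - e0 * np.exp(-kappa * z)
    sigma = float(np.sqrt(np.sum(resid**2) / max(z.size - 2, 1)))
    fit = ProfileFit(e0=e0, kappa=kappa, s=0.0, sigma=sigma,
                     method="uncorrected", n_points=int(z.size))
    return validate_fit(fit)


def validate_fit(fit: ProfileFit) -> ProfileFit:
    """Apply the two printed rejection rules plus the positivity requirement.

    A fit is invalid iff sigma > 1 umol m-2 s-1, kappa > 0.06 m-1, or
    kappa <= 0 (strict inequalities: boundary values pass).
    """
    if fit.kappa <= 0 or not np.isfinite(fit.kappa):
        return replace(fit, valid=False, reason="kappa-nonpositive")
    if fit.sigma > SIGMA_MAX:
        return replace(fit, valid=False, reason="sigma")
    if fit.kappa > KAPPA_MAX:
        return replace(fit, valid=False, reason="kappa")
    return replace(fit, valid=True, reason="")


def _shading_model(z, e0, kappa, s, ell):
    return e0 * np.exp(-kappa * z) * (1.0 - s * np.exp(-z / ell))


def correct_shading(profile: IrradianceProfile,
                    window=None) -> tuple[IrradianceProfile, ProfileFit]:
    """Remove the near-surface shading deficit from one profile.

    Fits E_obs(z) = E0 exp(-kappa z) (1 - s exp(-z/ell)) on the linear PAR
    scale and, when the fit passes QC, replaces each reading by the unshaded
    field E0 exp(-kappa z) (never below the observation: the correction only
    adds back light that local shading removed). Rejected or non-convergent
    fits return the profile unchanged, tagged "uncorrected"; profiles dark at
    the top sensor are passed through, tagged "dark".
    """
    z_all = np.asarray(profile.depths, dtype=float)
    p_all = np.asarray(profile.par, dtype=float)
    if p_all[0] < DARK_PAR:
        return profile, ProfileFit(method="dark", valid=False, reason="dark",
                                   n_points=0)
    z, p = _usable(profile, window)
    if z.size < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} positive PAR readings, got {z.size}")

    try:
        plain = fit_attenuation(profile, window)
    except ValueError:
        plain = ProfileFit(valid=False, reason="no-fit", method="uncorrected")

    p0 = [plain.e0 if np.isfinite(plain.e0) else p[0],
          min(max(plain.kappa, 1e-4), 0.5) if np.isfinite(plain.kappa) else 0.03,
          0.2, 2.0]
    bounds = ([1e-12, 1e-6, 0.0, 0.05], [np.inf, 1.0, 0.999, 50.0])
    try:
        popt, _ = curve_fit(_shading_model, z, p, p0=p0, bounds=bounds,
                            maxfev=20000)
    except Exception:
        fit = replace(plain, method="uncorrected", valid=False, reason="no-fit")
        return profile, fit

    e0, kappa, s, ell = (float(v) for v in popt)
    resid = p - _shading_model(z, *popt)
    dof = max(z.size - 4, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    fit = validate_fit(ProfileFit(e0=e0, kappa=kappa, s=s, ell=ell, sigma=sigma,
                                  method="corrected", n_points=int(z.size)))
    if not fit.valid:
        return profile, replace(fit, method="uncorrected")
    corrected = np.maximum(p_all, e0 * np.exp(-kappa * z_all))
    return profile.with_par(corrected), fit


def fit_linear_tail(profile: IrradianceProfile,
                    tail_depths=(32.0, 50.0)) -> tuple[float, float]:
    """Line through the deep sensor pair (default 32 m and 50 m).

    Returns (slope, intercept) in umol m-2 s-1 (per m for the slope).
    Raises if either deep sensor is missing.
    """
    z = np.asarray(profile.depths, dtype=float)
    p = np.asarray(profile.par, dtype=float)
    idx = [np.flatnonzero(np.isclose(z, d)) for d in tail_depths]
    if any(i.size == 0 for i in idx):
        raise ValueError("deep sensors missing; tail omitted")
    zd = np.array([z[i[0]] for i in idx])
    pd_ = np.array([p[i[0]] for i in idx])
    slope, intercept = np.polyfit(zd, pd_, 1)
    return float(slope), float(intercept)


class AssembledProfile:
    """Continuous corrected profile over [0, z_deep] m.

    Exponential segment E0 exp(-kappa z) down to the junction depth (21 m by
    default), then the linear deep tail rescaled so both segments agree at
    the junction; clamped at zero. Exposes exact analytic integrals so that
    depth averages are sensor-spacing independent.
    """

    def __init__(self, fit: ProfileFit, junction: float = 21.0,
                 z_deep: float = 50.0):
        if not (np.isfinite(fit.e0) and np.isfinite(fit.kappa) and fit.kappa > 0):
            raise ValueError("no valid exponential segment to assemble")
        self.e0 = float(fit.e0)
        self.kappa = float(fit.kappa)
        self.junction = float(junction)
        self.z_deep = float(z_deep)
        e_junction = self.e0 * np.exp(-self.kappa * self.junction)
        if np.isfinite(fit.tail_slope) and np.isfinite(fit.tail_intercept):
            raw_at_junction = fit.tail_slope * self.junction + fit.tail_intercept
            if raw_at_junction > 0:
                scale = e_junction / raw_at_junction
                self.tail_slope = float(fit.tail_slope * scale)
                self.tail_intercept = float(fit.tail_intercept * scale)
            else:  # degenerate tail; fall back to continuing the exponential
                self.tail_slope = None
                self.tail_intercept = None
        else:
            self.tail_slope = None
            self.tail_intercept = None

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        exp_part = self.e0 * np.exp(-self.kappa * z)
        if self.tail_slope is None:
            out = exp_part
        else:
            lin = self.tail_slope * z + self.tail_intercept
            out = np.where(z <= self.junction, exp_part, np.maximum(lin, 0.0))
        return float(out) if out.ndim == 0 else out

    def _exp_integral(self, a: float, b: float) -> float:
        return self.e0 / self.kappa * (np.exp(-self.kappa * a) - np.exp(-self.kappa * b))

    def _lin_integral(self, a: float, b: float) -> float:
        m, c = self.tail_slope, self.tail_intercept
        if m < 0:
            root = -c / m
            b = min(b, root) if root > a else a
        if b <= a:
            return 0.0
        return 0.5 * m * (b**2 - a**2) + c * (b - a)

    def integral(self, z1: float, z2: float) -> float:
        """Exact integral of the piecewise profile over [z1, z2]."""
        if z2 <= z1:
            raise ValueError("z2 must exceed z1")
        if self.tail_slope is None:
            return self._exp_integral(z1, z2)
        total = 0.0
        if z1 < self.junction:
            total += self._exp_integral(z1, min(z2, self.junction))
        if z2 > self.junction:
            total += self._lin_integral(max(z1, self.junction), z2)
        return total


def assemble_corrected_profile(fit: ProfileFit, junction: float = 21.0,
                               z_deep: float = 50.0) -> AssembledProfile:
    """Build the continuous piecewise profile from a populated fit."""
    return AssembledProfile(fit, junction=junction, z_deep=z_deep)
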