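"""Detection of the onset of photosynthetic biomass buildup.

Three complementary statistics locate the day a flat winter Chl-a baseline
turns into exponential growth:

* a 5-day sliding-window **rate of change**, with onset declared at the
  first run of >= 5 consecutive positive slopes;
* 7-day **accumulation rate constants** r = ln(C(t+7)/C(t)) / 7, summarised
  before and after the change point;
* a **change-point model ensemble** on the daily log-concentration series,
  fitted by exact maximum-likelihood search over all single change
  locations and compared against the corresponding no-change null by BIC.

A flat-then-exponential Chl-a signal is *continuous* in log space: a
constant winter baseline joined to a linear growth ramp. The ensemble
therefore uses continuous segmented ("hinge") models — a flat baseline
breaking into a trend (the mean-to-growth shift), a free-slope trend break,
and the flat hinge with AR(1) errors. A discontinuous mean-shift model on
the levels is deliberately not an ensemble member: on a gradual onset its
change location is maximised roughly a third of the way into the growth
segment even without noise, i.e. it is not a consistent estimator of the
onset day (see docs/methods.md; the exact mean-shift search is still
exported as :func:`mean_shift_search`).

Mann-Kendall trend tests (tie-corrected normal approximation) and
log-linear exponential back-extrapolation for ice-algae doubling dates
round out the module.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChlSeries",
    "OnsetReport",
    "MannKendallResult",
    "rate_of_change",
    "detect_onset_roc",
    "accumulation_rate",
    "summarize_rates",
    "changepoint_suite",
    "mann_kendall",
    "exp_backextrapolate_doubling",
    "chl_par_regression",
    "CHANGEPOINT_MODELS",
]

ONE_DAY = dt.timedelta(days=1)


@dataclass(frozen=True)
class ChlSeries:
    """Dated Chl-a concentrations (possibly replicated within a day)."""

    dates: tuple[dt.date, ...]
    concentrations: tuple[float, ...]   # ug L-1
    source: str = "underway"            # underway | rosette-integrated | ice-core

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.concentrations):
            raise ValueError("dates and concentrations must have equal length")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")

    def daily_average(self) -> "ChlSeries":
        """Arithmetic mean of replicates per day; dates strictly increasing."""
        frame = pd.DataFrame({"date": self.dates, "chl": self.concentrations})
        daily = frame.groupby("date", sort=True)["chl"].mean()
        return ChlSeries(dates=tuple(daily.index),
                         concentrations=tuple(float(v) for v in daily.values),
                         source=self.source)

    def as_series(self) -> pd.Series:
        return pd.Series(self.concentrations, index=pd.Index(self.dates))


# ---------------------------------------------------------------------------
# rate of change & accumulation rates
# ---------------------------------------------------------------------------

def rate_of_change(series: ChlSeries, interval_days: int = 5,
                   max_gap_days: int = 2) -> pd.Series:
    """Sliding-window least-squares slope of daily Chl-a (ug L-1 d-1).

    For every calendar day ``d`` with data, the slope is fitted over the
    observations in [d - interval + 1, d] and assigned to ``d``. Windows
    with fewer than 3 points or an internal gap longer than ``max_gap_days``
    are skipped.
    """
    daily = series.daily_average()
    dates = np.array(daily.dates)
    values = np.asarray(daily.concentrations, dtype=float)
    day0 = dates[0]
    offsets = np.array([(d - day0).days for d in dates], dtype=float)
    out_dates, out_slopes = [], []
    for i, d in enumerate(dates):
        lo = (d - day0).days - (interval_days - 1)
        mask = (offsets >= lo) & (offsets <= offsets[i])
        if mask.sum() < 3:
            continue
        covered = offsets[mask]
        edges = np.concatenate(([lo], covered, [offsets[i]]))
        if np.max(np.diff(edges)) > max_gap_days:
            continue
        slope = np.polyfit(covered, values[mask], 1)[0]
        out_dates.append(d)
        out_slopes.append(float(slope))
    return pd.Series(out_slopes, index=pd.Index(out_dates), dtype=float)


def detect_onset_roc(slopes: pd.Series, run_days: int = 5) -> dt.date | None:
    """First date starting >= ``run_days`` consecutive positive daily slopes."""
    if slopes.empty:
        return None
    dates = list(slopes.index)
    pos = (slopes.values > 0)
    run_start, run_len = None, 0
    for i, (d, p) in enumerate(zip(dates, pos)):
        contiguous = i > 0 and (d - dates[i - 1]).days == 1
        if p:
            if run_len > 0 and contiguous:
                run_len += 1
            else:
                run_start, run_len = d, 1
            if run_len >= run_days:
                return run_start
        else:
            run_len = 0
    return None


def accumulation_rate(series: ChlSeries, interval_days: int = 7) -> pd.Series:
    """Accumulation rate constants r = ln(C(t+T)/C(t)) / T, indexed by t.

    Days whose partner ``t + T`` is missing are skipped.
    """
    daily = series.daily_average().as_series()
    rates, dates = [], []
    lookup = {d: v for d, v in daily.items()}
    for d, c in daily.items():
        partner = d + dt.timedelta(days=interval_days)
        if partner in lookup:
            rates.append(math.log(lookup[partner] / c) / interval_days)
            dates.append(d)
    return pd.Series(rates, index=pd.Index(dates), dtype=float)


def summarize_rates(rates: pd.Series, split: dt.date,
                    interval_days: int = 7) -> dict:
    """Mean +- sd of rate constants whose window lies fully pre/post split."""
    out = {}
    for label, mask in (
        ("pre", [d + dt.timedelta(days=interval_days) <= split for d in rates.index]),
        ("post", [d >= split for d in rates.index]),
    ):
        sel = rates[np.asarray(mask, dtype=bool)]
        out[label] = {
            "mean": float(sel.mean()) if len(sel) else float("nan"),
            "sd": float(sel.std(ddof=1)) if len(sel) > 1 else 0.0,
            "n": int(len(sel)),
        }
    return out


# ---------------------------------------------------------------------------
# change-point models
# ---------------------------------------------------------------------------

_MIN_SEG = 3


def mean_shift_search(x: np.ndarray, min_seg: int = _MIN_SEG
                      ) -> tuple[int, float]:
    """Exact search for the single mean-shift split minimising within-SSE.

    Returns (tau, sse) where ``tau`` is the last index (0-based) of the
    first segment. Equivalent to brute-force enumeration of all splits.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * min_seg:
        raise ValueError("series too short for a mean-shift search")
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    taus = np.arange(min_seg - 1, n - min_seg)
    n1 = taus + 1.0
    n2 = n - n1
    s1 = cs[taus]
    s2 = cs[-1] - s1
    sse = (cs2[-1]) - s1**2 / n1 - s2**2 / n2
    k = int(np.argmin(sse))
    return int(taus[k]), float(sse[k])


def _lstsq_sse(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _hinge_design(n: int, tau: int, free_pre_slope: bool) -> np.ndarray:
    """Design matrix of the continuous segmented ("hinge") mean model.

    mu(t) = a (+ b1 t) + b2 * max(0, t - tau): constant or linear up to the
    change index ``tau`` (the last pre-change point), then an added linear
    ramp. The fitted mean is continuous at the change.
    """
    t = np.arange(n, dtype=float)
    ramp = np.maximum(0.0, t - tau)
    cols = [np.ones(n), t, ramp] if free_pre_slope else [np.ones(n), ramp]
    return np.column_stack(cols)


def hinge_search(y: np.ndarray, free_pre_slope: bool = False,
                 min_seg: int = _MIN_SEG) -> tuple[int, float]:
    """Exact least-squares search over all single hinge locations.

    Returns (tau, sse): ``tau`` is the 0-based index of the last pre-change
    observation of the SSE-minimising continuous segmented fit.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2 * min_seg:
        raise ValueError("series too short for a hinge search")
    best = (None, np.inf)
    for tau in range(min_seg - 1, n - min_seg):
        sse = _lstsq_sse(_hinge_design(n, tau, free_pre_slope), y)
        if sse < best[1]:
            best = (tau, sse)
    return int(best[0]), float(best[1])


def _gaussian_bic(sse: float, n_obs: int, k_params: int) -> float:
    sigma2 = max(sse / n_obs, 1e-30)
    return n_obs * math.log(sigma2) + k_params * math.log(n_obs)


_PHI_GRID = np.linspace(-0.9, 0.9, 37)


def _ar1_profile_sse(y: np.ndarray, X: np.ndarray,
                     phis: np.ndarray = _PHI_GRID) -> float:
    """Min over phi of the conditional AR(1) SSE for mean structure X.

    Quasi-differences both response and design (Cochrane-Orcutt on a grid)
    and returns the smallest residual sum of squares.
    """
    best = np.inf
    for phi in phis:
        Xq = X[1:] - phi * X[:-1]
        yq = y[1:] - phi * y[:-1]
        sse = _lstsq_sse(Xq, yq)
        if sse < best:
            best = sse
    return float(best)


def _fit_flat_hinge(y: np.ndarray) -> tuple[int, float, float]:
    """Flat baseline breaking into a trend (mean-to-growth shift)."""
    n = y.size
    tau, sse = hinge_search(y, free_pre_slope=False)
    sse0 = float(((y - y.mean()) ** 2).sum())
    bic_alt = _gaussian_bic(sse, n, 4)    # level, ramp slope, sigma, location
    bic_null = _gaussian_bic(sse0, n, 2)  # level, sigma
    return tau, bic_alt, bic_null


def _fit_trend_hinge(y: np.ndarray) -> tuple[int, float, float]:
    """Free-slope trend breaking to a new slope (trend shift), continuous."""
    n = y.size
    tau, sse = hinge_search(y, free_pre_slope=True)
    t = np.arange(n, dtype=float)
    sse0 = _lstsq_sse(np.column_stack([np.ones(n), t]), y)
    bic_alt = _gaussian_bic(sse, n, 5)    # intercept, 2 slopes, sigma, location
    bic_null = _gaussian_bic(sse0, n, 3)
    return tau, bic_alt, bic_null


def _fit_flat_hinge_ar1(y: np.ndarray) -> tuple[int, float, float]:
    """Flat-to-trend hinge with AR(1) errors (phi profiled on a grid)."""
    n = y.size
    best = (None, np.inf)
    for tau in range(_MIN_SEG - 1, n - _MIN_SEG):
        sse = _ar1_profile_sse(y, _hinge_design(n, tau, False))
        if sse < best[1]:
            best = (tau, sse)
    sse0 = _ar1_profile_sse(y, np.ones((n, 1)))
    rows = n - 1
    bic_alt = _gaussian_bic(best[1], rows, 5)   # level, slope, phi, sigma, loc
    bic_null = _gaussian_bic(sse0, rows, 3)
    return best[0], bic_alt, bic_null


CHANGEPOINT_MODELS = {
    "flat_hinge": _fit_flat_hinge,
    "trend_hinge": _fit_trend_hinge,
    "flat_hinge_ar1": _fit_flat_hinge_ar1,
}


def changepoint_suite(series: ChlSeries, models=None) -> dict:
    """Fit the change-point model ensemble to a daily Chl-a series.

    Works on daily-averaged log concentrations, which must form an
    uninterrupted daily sequence of >= 20 values. Each model reports the
    date of the last pre-change day, or None when BIC prefers its no-change
    null. Returns per-model dates plus the ensemble mean, sample sd, range,
    and the conservative onset (ensemble mean + 1 day).
    """
    daily = series.daily_average()
    dates = list(daily.dates)
    if len(dates) < 20:
        raise ValueError("need >= 20 daily values for change-point analysis")
    deltas = {(b - a).days for a, b in zip(dates, dates[1:])}
    if deltas != {1}:
        raise ValueError("change-point analysis requires consecutive daily values")
    y = np.log(np.asarray(daily.concentrations, dtype=float))
    chosen = models or CHANGEPOINT_MODELS
    model_dates: dict[str, dt.date | None] = {}
    for name, fit in chosen.items():
        tau, bic_alt, bic_null = fit(y)
        model_dates[name] = dates[tau] if bic_alt < bic_null else None
    found = [d for d in model_dates.values() if d is not None]
    report = {"model_dates": model_dates, "n_detecting": len(found)}
    if found:
        ordinals = np.array([d.toordinal() for d in found], dtype=float)
        mean_ord = float(ordinals.mean())
        report["ensemble_mean_date"] = dt.date.fromordinal(round(mean_ord))
        report["ensemble_sd_days"] = (
            float(ordinals.std(ddof=1)) if len(found) > 1 else 0.0)
        report["ensemble_range_days"] = float(ordinals.max() - ordinals.min())
        report["conservative_onset"] = report["ensemble_mean_date"] + ONE_DAY
    else:
        report.update(ensemble_mean_date=None, ensemble_sd_days=None,
                      ensemble_range_days=None, conservative_onset=None)
    return report


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannKendallResult:
    s: int
    tau: float
    var_s: float
    z: float
    p: float                 # two-sided
    trend: str               # increasing | decreasing | no trend
    all_tied: bool = False


def mann_kendall(values, alpha: float = 0.05) -> MannKendallResult:
    """Mann-Kendall trend test with tie-corrected normal approximation.

    S = sum_{i<j} sign(x_j - x_i); Var(S) includes the tie correction;
    z uses the +-1 continuity correction. Requires n >= 4.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall test requires n >= 4")
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_sign, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    if counts.max() == n:
        return MannKendallResult(s=0, tau=float("nan"), var_s=0.0, z=0.0,
                                 p=1.0, trend="no trend", all_tied=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    # tau-b denominator corrects for ties in the ranking
    t_corr = float(np.sum(counts * (counts - 1)) / 2)
    n_pairs = n * (n - 1) / 2
    denom = math.sqrt((n_pairs - t_corr) * n_pairs)
    tau = s / denom if denom > 0 else float("nan")
    if p < alpha:
        trend = "increasing" if s > 0 else "decreasing"
    else:
        trend = "no trend"
    return MannKendallResult(s=s, tau=tau, var_s=var_s, z=z, p=p, trend=trend)


# ---------------------------------------------------------------------------
# exponential back-extrapolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoublingResult:
    rate: float              # d-1
    r_squared: float         # of the log-linear fit
    t_doubling_days: float | None   # days after the series start
    doubling_date: dt.date | None
    no_doubling: bool = False


def exp_backextrapolate_doubling(series: ChlSeries,
                                 window: tuple[dt.date, dt.date] | None = None
                                 ) -> DoublingResult:
    """Log-linear exponential fit with backward extrapolation to doubling.

    Fits C(t) = C0 * exp(r t) (t in days from the series start) over
    ``window`` (default: whole series) and finds the earliest continuous
    time at which the fitted curve reaches twice the first observed
    concentration. A non-positive fitted rate yields no doubling date.
    """
    daily = series.daily_average()
    dates = np.array(daily.dates)
    values = np.asarray(daily.concentrations, dtype=float)
    start = dates[0]
    c_ref = values[0]
    if window is not None:
        lo, hi = window
        mask = np.array([lo <= d <= hi for d in dates])
    else:
        mask = np.ones(dates.size, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need >= 3 positive values in the fit window")
    t = np.array([(d - start).days for d in dates[mask]], dtype=float)
    res = stats.linregress(t, np.log(values[mask]))
    rate, r2 = float(res.slope), float(res.rvalue**2)
    if rate <= 0:
        return DoublingResult(rate=rate, r_squared=r2, t_doubling_days=None,
                              doubling_date=None, no_doubling=True)
    t_double = (math.log(2.0 * c_ref) - float(res.intercept)) / rate
    date = start + dt.timedelta(days=math.ceil(t_double - 1e-9))
    return DoublingResult(rate=rate, r_squared=r2,
                          t_doubling_days=float(t_double), doubling_date=date)


# ---------------------------------------------------------------------------
# Chl-a vs PAR regression
# ---------------------------------------------------------------------------

def chl_par_regression(series: ChlSeries, daily_par: dict, split: dt.date,
                       exclude_dates=()) -> dict:
    """Exponential Chl-a vs PAR fits before/after the change point.

    Regresses ln(Chl) on the daily mixed-layer PAR separately for dates
    before ``split`` and from ``split`` onward; lead-affected dates are
    excluded. Periods with < 3 matched points are skipped (absent from the
    returned dict).
    """
    daily = series.daily_average()
    excluded = set(exclude_dates)
    pairs = [(d, c, daily_par[d]) for d, c in zip(daily.dates, daily.concentrations)
             if d in daily_par and d not in excluded]
    out = {}
    for label, sel in (("pre", [p for p in pairs if p[0] < split]),
                       ("post", [p for p in pairs if p[0] >= split])):
        if len(sel) < 3:
            continue
        par = np.array([p[2] for p in sel], dtype=float)
        if np.ptp(par) == 0:   # no light variation: relationship inestimable
            continue
        log_chl = np.log(np.array([p[1] for p in sel], dtype=float))
        res = stats.linregress(par, log_chl)
        out[label] = {"intercept": float(res.intercept),
                      "slope": float(res.slope),
                      "r_squared": float(res.rvalue**2),
                      "n": len(sel)}
    return out
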