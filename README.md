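# icebloom

Tools for answering a deceptively simple question in polar bio-optics: **at
how little light does net photosynthetic growth begin under snow-covered sea
ice?** The package reconstructs the mixed-layer light climate experienced by
phytoplankton drifting beneath pack ice, computes potential net primary
production (NPP) from ¹⁴C incubations, and pins down the onset of biomass
buildup in chlorophyll-*a* time series — the three ingredients needed to
attach an irradiance value to the first day of net growth after the polar
night. A synthetic-campaign generator emulates every input (light-chain
profiles, snow fields, underway Chl-a, incubation counts), so the whole
chain is testable without any field data.

It is intended for bio-optical oceanographers and ecological statisticians
working with under-ice irradiance chains, ¹⁴C productivity incubations, and
bloom-phenology time series.

## What it computes

**Under-ice light.** Vertical PAR profiles decay as E(z) = E₀·e^(−κz).
Observed profiles carry a near-surface shading deficit (the shallow sensors
sample a locally shaded patch), modelled as

    E_obs(z) = E₀ · e^(−κz) · (1 − s·e^(−z/ℓ)),

and the unshaded field is restored by nonlinear least squares. Fits with a
residual standard deviation σ > 1 µmol photons m⁻² s⁻¹ or κ > 0.06 m⁻¹
(implausibly turbid for low-biomass polar water) are passed through
uncorrected. Below 21 m the deep sensor pair (32/50 m) defines a linear
tail, spliced continuously onto the exponential segment. Snow transmissivity
follows T(h) = I₀·e^(−κ_snow(h − 0.03 m)) with κ_snow = 14.1 m⁻¹; the ratio
of transect-averaged to site-averaged transmissivity gives the
area-heterogeneity factor (+33 % by default, recomputable from snow fields).
Corrected profiles are averaged vertically (3–50 m, exact piecewise
integrals), over 24 h, and across sites.

**¹⁴C productivity.**

    NPP = [DIC] · (DPM_sample − DPM_0%) · 1.05 / (DPM_100% · t),

with duplicate light bottles averaged and the dark-control rate subtracted;
output in µg C L⁻¹ d⁻¹ (negative net rates flagged, never clamped).

**Onset detection.** Three statistics on daily underway Chl-a: a 5-day
sliding-window rate of change (onset = first run of ≥ 5 positive days);
7-day accumulation rate constants r = ln(C(t+7)/C(t))/7 summarised before
and after the change point; and a change-point ensemble of continuous
segmented models on log concentration (flat→trend hinge, free-slope hinge,
flat hinge with AR(1) errors), each fitted by exact search over all single
change locations and screened against its no-change null by BIC. The
ensemble mean + 1 day is the conservative onset. Mann–Kendall trend tests
and exponential back-extrapolation (ice-algae first-doubling dates) round
out the module.

## Worked example

```
$ icebloom report
{
  "euphotic_depth_1pct_m": 23.025850929940457,
  "euphotic_depth_1pct_rounded": 23,
  "euphotic_depth_low_threshold_m": 54.098891422051416,
  "euphotic_depth_low_threshold_rounded": 54,
  "n_sites": 3,
  "onset_par_mean": 0.036,
  "onset_par_mean_rounded": 0.04,
  "onset_par_sd": 0.023643180835073777,
  "onset_par_sd_rounded": 0.02,
  "threshold_pct_of_surface": 0.002
}
```

The three per-site onset-day mixed-layer PAR values (0.014, 0.033,
0.061 µmol photons m⁻² s⁻¹) average to **0.04 ± 0.02 µmol photons m⁻² s⁻¹**
— the light level at which biomass buildup was already underway. Read as an
isolume under a 2000 µmol photons m⁻² s⁻¹ surface with attenuation
0.2 m⁻¹, such a threshold sits at **54 m**, versus **23 m** for the
classical 1 %-of-surface criterion: the euphotic zone more than doubles in
depth.

A full synthetic campaign runs end to end with

```
icebloom run-all --seed 3 --outdir out/
```

which simulates the inputs, corrects and averages the light profiles,
computes NPP, runs the onset statistics, and writes `manifest.json` whose
change-point block (for the default scenario: onset 2020-03-27) reads

```
"model_dates": {"flat_hinge": "2020-03-27", "trend_hinge": "2020-03-27",
                "flat_hinge_ar1": "2020-03-27"},
"ensemble_mean_date": "2020-03-27", "conservative_onset": "2020-03-28"
```

together with the mixed-layer PAR on the conservative onset day and
per-stage record counts. Reruns with the same seed are byte-identical.

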