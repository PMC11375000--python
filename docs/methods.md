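# Methods

This note documents the models implemented in `icebloom`, the defaults and
their units, the design choices made where the literature leaves the
procedure open, and what the synthetic-data tests do and do not establish.

## Light-profile correction

Downwelling PAR under laterally homogeneous ice decays exponentially,
E(z) = E₀·e^(−κz), with κ the diffuse attenuation coefficient of the water
column (m⁻¹). Two systematic departures are corrected:

**Near-surface shading.** The uppermost sensors of an ice-tethered chain
sample a narrow, locally shaded patch of the ice underside, depressing the
shallow readings relative to the wide-area mean. We model the observed
profile as E_obs(z) = E₀·e^(−κz)·(1 − s·e^(−z/ℓ)) with shading amplitude
s ∈ [0, 1) and decay length ℓ (m), fitted by nonlinear least squares on the
linear PAR scale (the quality threshold below is quoted in absolute PAR
units, which implies linear-scale residuals). The two-parameter
multiplicative deficit is this package's own minimal form: it removes the
near-surface shaded region and reduces exactly to the plain exponential at
s = 0. The published correction it stands in for is not reproduced
equation-by-equation in the source literature, so the form here is
documented as a stand-in with the same qualitative action. The corrected
profile is the unshaded field E₀·e^(−κz), floored elementwise at the
observations so the correction can only add back light — consistent with
treating the result as an upper bound on the true light field.

**Quality control.** A fit is rejected when σ > 1 µmol photons m⁻² s⁻¹
(residual standard deviation, dof-corrected) or κ > 0.06 m⁻¹ (implausible
for low-biomass polar waters), or when κ ≤ 0. Inequalities are strict:
boundary values pass. Rejected profiles are passed through uncorrected —
never discarded — and profiles darker than 10⁻⁴ µmol m⁻² s⁻¹ at the top
sensor are tagged `dark` and skipped (the log-domain fit is undefined and
the values are below instrumental relevance).

**Deep tail and assembly.** Below ~21 m the measured decay is better
described by a straight line; the 32 m/50 m sensor pair defines it. The
assembled profile is the corrected exponential on [0, 21] m and the tail
line on (21, 50] m, multiplicatively rescaled to agree with the exponential
at 21 m (the splice rule is this package's choice; the junction sits at the
deepest exponential-regime sensor) and clamped at zero. The object exposes
exact segment integrals, so depth averages are analytic and independent of
sensor spacing.

## Snow optics

Snow is a 3 cm surface scattering layer of lumped transmissivity I₀ over a
homogeneous slab: T(h) = I₀·e^(−κ_snow(h − 0.03 m)), κ_snow = 14.1 m⁻¹ by
default (±1.4 m⁻¹ reported as an uncertainty band on the estimate, not
propagated into headline means — the headline error budget is dominated by
the flat ±20 % radiometric calibration, taken as given). I₀ cancels in
every ratio the pipeline uses. κ_snow is estimated by log-linear regression
of ln(below/above) on (h − 0.03).

Because the transmissivity is convex in h, a heterogeneous snow field
transmits more light than a uniform field of the same mean depth (Jensen's
inequality); thin-snow patches dominate. The area-heterogeneity factor is
the ratio of transect-mean to site-mean transmissivity (unweighted sample
means; no weighting scheme is defensible without survey-design metadata).
The pipeline default multiplies corrected PAR by the constant 1.33, and the
factor is also recomputable from snow fields; since the correction is a
scalar multiple, it commutes with depth and time averaging, so applying it
before or after averaging is equivalent.

## Mixed-layer light and euphotic depths

Cells mixed homogeneously through the surface layer experience the average
light over that layer. Daily exposure is computed as the vertical mean over
3–50 m (analytic piecewise integral), the temporal mean over the 24 h up to
the day's last record, and the cross-site mean with sample (n−1) standard
deviation — three drifting sites are a sample of ice conditions, and at the
reported precision both sd conventions agree. Site-days overlapping a
configured lead event (open water locally amplifying under-ice light) are
flagged and excluded from cross-site statistics by default.

Euphotic depths follow z = ln(E₀/E_thr)/k for an absolute threshold and
z = ln(1/f)/k for a fractional one. `threshold_fraction` expresses a
threshold as a percentage of a surface value; for 0.04 of 2000 it returns
0.002 % (the module computes the arithmetic; it does not reconcile rounded
values quoted elsewhere).

## ¹⁴C productivity

NPP = [DIC]·(DPM_sample − DPM_0%)·1.05/(DPM_100%·t): DIC in µmol C L⁻¹,
DPM the scintillation counts of sample, blank and total spike, t in days,
1.05 the correction for biological fractionation against ¹⁴C. Output is
converted to µg C L⁻¹ d⁻¹ via 12.011 µg µmol⁻¹ (the source arithmetic
leaves its output units implicit; mass units per day are the community
convention). Duplicate light bottles are averaged, the dark-control rate is
subtracted, and both blank and dark subtraction are applied exactly as
written even though they may partly double-count abiotic uptake. Negative
net rates are flagged, never clamped, so downstream statistics see the full
error distribution. Missing dark controls yield a flagged gross-only
result.

## Onset statistics

All statistics operate on daily averages (replicates are averaged per day
first).

**Rate of change.** The least-squares slope of concentration against time
over a 5-day sliding window (not a two-point difference — robust to
single-day noise), assigned to the window's last day; windows with an
internal gap longer than 2 days or fewer than 3 points are skipped. Onset =
first date starting ≥ 5 consecutive positive daily slopes. On flat noisy
baselines this rule can fire by chance (a 5-day positive run under sign
symmetry has probability 1/32 per position); it is reported alongside, not
instead of, the change-point estimate.

**Accumulation rate constants.** r = ln(C(t+7)/C(t))/7, the standard net
specific accumulation rate in d⁻¹, summarised as mean ± sd over windows
lying fully before/after the split date.

**Change-point ensemble.** On log concentration a flat-then-exponential
signal is a constant joined continuously to a linear ramp. The ensemble
therefore fits continuous segmented ("hinge") mean models by exact search
over all single change locations: (1) flat baseline breaking into a trend,
(2) free-slope trend breaking to a new slope, (3) the flat hinge with AR(1)
errors (conditional likelihood, AR coefficient profiled on a grid over
[−0.9, 0.9]). Each model is screened against its no-change null by BIC
(change location counted as a parameter; variance floored at 10⁻³⁰ so
noiseless signals remain comparable); models preferring the null report
none. Detected dates are combined as ensemble mean ± sample sd, with the
range also reported, and the conservative onset is the ensemble mean + 1
day. A *discontinuous* mean-shift model on the levels is deliberately not a
member: on a gradual onset its optimal split sits far inside the growth
segment even without noise (≈ 11 days late on a 30 + 30-day flat/ramp
signal — a regression test documents this), i.e. it estimates where the
average level splits best, not where growth began. The exact mean-shift
search is still exported for mean-structured problems.

**Trend tests and back-extrapolation.** Mann–Kendall S with tie-corrected
variance, continuity-corrected normal approximation, and tau-b; exactness
of S is verified against brute-force pair counting and tau against an
independent library implementation. Ice-algae doubling dates come from a
log-linear exponential fit over a chosen window, extrapolated backward to
the earliest continuous time the fitted curve reaches twice the first
observed concentration; non-positive rates yield a flagged no-doubling
result.

## Synthetic campaigns

The generator emulates one late-winter high-Arctic drift campaign at 86° N,
February–April. Defaults (chosen once, as the conditions the analysis is
meant to operate under):

| parameter | default | basis |
|---|---|---|
| Chl-a baseline | 0.015 µg L⁻¹ | mid-winter under-ice concentrations ~0.01–0.02 |
| onset day | 2020-03-27 | late-March return of usable light |
| post-onset rate r | 0.06 d⁻¹ | observed under-ice spring accumulation rates |
| log-noise σ | 0.10, 2 replicates/day | fluorometric duplicate precision ~10 % |
| κ_w | 0.05 m⁻¹ | clear polar water, below the 0.06 QC bound |
| κ_snow | 14.1 m⁻¹ | field estimate for March/April snow |
| ice transmissivity | 0.01 (scalar/site) | snow dominates variability; ice-interior optics not modelled |
| shading s, ℓ | 0.3, 2 m | moderate site-local shading |
| sensor depths | 1…50 m (12 sensors) | standard chain layout |
| snow classes | level N(0.20, 0.03²), rubble N(0.28, 0.06²), deformed N(0.33, 0.10²), equal shares, truncated at 0.03 m | reproduces ~0.20 m level-ice sites and 0.25–0.30 m transect means |
| cadence | 10 min | typical logger setting; exposed as a parameter |

Surface PAR uses a low-precision declination/hour-angle solar model
(longitude 0, solar time = UTC) — adequate for the diurnal shape and the
polar-night transition, which is all the pipeline consumes; it is checked
against an independent NOAA-style formula in the tests. Noise is
multiplicative lognormal on PAR and Chl-a (both positive, spanning
decades). Incubation records are constructed by inverting the production
equation with the blank placed at 25 % of the sample counts, so every
estimator has an exact round trip on noiseless input.

What the generator does **not** emulate: ice drift and thermodynamics,
spectrally resolved radiative transfer, storm-driven mixing events, patchy
grazing losses, instrument drift, or the ±20 % absolute calibration
uncertainty. Passing tests therefore demonstrate correctness of the
arithmetic and statistical machinery under the stated noise model — not
that field data of arbitrary quality will yield ±1-day onsets.

## Numerical choices and problem sizes

Shading fits use bounded trust-region least squares seeded from the plain
log-linear fit; non-convergence returns the profile uncorrected with reason
`no-fit`. QC thresholds are strict inequalities. Ties in exact change-point
searches resolve to the earliest location (argmin convention). Test and
demonstration runs use 40–60-day scenarios at 3–6 h light-chain cadence and
the recovery studies use 500 accumulation windows / 200 snow pairs —
problem sizes at which every estimator's sampling error is comfortably
inside its tolerance while the full suite runs in well under a minute.

## Known limitations

* The shading model is a documented stand-in, not the published
  correction's exact functional form.
* Single change point only; no multiple-segmentation.
* The AR(1) grid profile (step 0.05) bounds the likelihood optimum rather
  than solving it exactly; adequate for BIC screening at these series
  lengths.
* The euphotic-depth arithmetic assumes a single exponential water column;
  it is a conversion utility, not a radiative-transfer model.
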