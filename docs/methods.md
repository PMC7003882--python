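# Methods

This note documents the models in `daphnegain`, the choices behind their
defaults, and what the synthetic generators do and do not emulate.

## Photosynthetic response surfaces

Chamber gas-exchange factorials (by default six temperatures 5, 10, 15, 20,
25, 30 °C × ten PAR levels 0, 10, 30, 50, 100, 300, 500, 700, 900,
1100 µmol m⁻² s⁻¹; 60 records per plant) are fitted in two regimes because
the low-light response — dominated by the temperature dependence of dark
respiration and the initial slope of the light response — is qualitatively
different from the saturating, temperature-peaked behaviour at high light.

- **Split point.** 75 µmol m⁻² s⁻¹, half-open: the paraboloid owns
  [0, 75), the Lorentzian [75, ∞). The boundary assignment is a convention;
  predictions at exactly 75 use the high regime.
- **No continuity enforcement.** The regimes are fitted independently, so a
  step discontinuity at the split is possible; it is exposed as
  `HybridResponseSurface.split_step(temp)` rather than repaired, because
  repairing it would bias one regime's coefficients by the other's
  misspecification.
- **Paraboloid** `Pn = k − a·Temp + b·PAR + c·Temp² − d·PAR²` is linear in
  its coefficients and fitted by exact least squares. Reported diagnostics:
  R² = 1 − SSE/SST with SST corrected for the observation mean, and the
  regression ANOVA F with (4, n − 5) degrees of freedom.
- **Lorentzian** `Pn = a / [(1 + ((Temp−k)/b)²)(1 + ((PAR−l)/c)²)]` is
  fitted by bounded Levenberg–Marquardt (trust-region reflective) from a
  data-driven start (a = max Pn, k and l at the argmax record, half-widths =
  half the data ranges) plus 10 jittered restarts; the best converged start
  by SSE wins and total failure raises `ConvergenceError` rather than
  returning silently. The model's value is bounded by |a| everywhere, which
  keeps extrapolation to extreme microclimate inputs benign.
- **Light-response traits** from single-temperature curves use the
  non-rectangular hyperbola with curvature θ bounded in [0.5, 0.99] — the
  conventional general-purpose A–Q model. A_max is reported as Pmax − Rd
  (light-saturated *net* rate); LCP is the bracketed root of the fitted
  curve, reported as absent when the curve never crosses zero within the
  measured range.

### Prediction sanitization

Surface predictions driven by field inputs occasionally violate physics —
chiefly positive Pn at PAR = 0 (the paraboloid's PAR terms cannot bend fast
enough at some temperatures), or values below a physical floor (default
−10 µmol m⁻² s⁻¹). Flagged values are replaced by the mean of the nearest
non-flagged predictions, searching outward in time, whose inputs lie within
±2 °C and ±10 µmol m⁻² s⁻¹ of the flagged record (both configurable; the
similarity window is a convention, chosen tight enough that the replacement
reflects the same radiative/thermal conditions). If no similar neighbour
exists in the entire series, the nearest non-flagged values are used
regardless; if everything is flagged the series is rejected with a
diagnostic instead of fabricating data.

## Carbon-gain integration

Per 2-min step, flux = Pn × 120 s (µmol m⁻²); daily sums over days 10–15 of
each month (six days) are averaged and reported in mmol CO₂ m⁻² day⁻¹. The
six-day window is the standard design this pipeline targets; a constant
1 µmol m⁻² s⁻¹ over a day integrates to exactly 86.4 mmol m⁻² day⁻¹, which
is the unit audit used in the tests. Days missing more than 5% of their 720
steps abort the day; smaller gaps are filled by linear interpolation.

Leaf temperature is approximated by air temperature by default. A seasonal
leaf-temperature regression (−12.05 + 0.346·JD − 0.0008·JD²,
a field-calibrated quadratic peaking near day 216) is available as an
alternative driver; it captures the seasonal march but not diurnal leaf
energy balance, so it is not the default.

### Leaf aging

Leaves flushed in October start at 100% relative performance and reach 30%
by the following August (10 months). The default schedule is geometric,
factor = 0.30^(Δ/10) per month elapsed (≈ 11.3% compounded decline per
month); a linear 7%-per-month alternative reaching the same endpoint is
selectable. The factor multiplies the **gross** assimilation component
(Pn + Rd) with Rd held constant — aging degrades assimilative capacity
while maintenance respiration persists — so aged gain = factor·gross −
resp. A `component="net"` switch scales net gain directly for the simpler
reading. The gross/resp split uses the surface's own dark-respiration curve
Rd(Temp) = −Pn(Temp, 0).

### Diagnostics

- **LCP time budget**: fraction of all 2-min steps — day and night combined
  — with PAR below the light compensation point, and the ratio of
  respiratory loss integrated over those steps to photosynthetic gain over
  the rest. The ratio is reported as absent when the above-LCP gain is not
  positive.
- **Rd sensitivity**: the surface is shifted by a uniform additive offset
  so that Pn(PAR = 0) at a reference temperature (default 20 °C) equals
  −Rd, and the month is re-integrated per Rd level. Because the offset is
  uniform, gain is exactly linear in Rd (slope −86.4 mmol day⁻¹ per
  µmol m⁻² s⁻¹), which makes the sign-crossing Rd* easy to locate; the
  demo configuration sweeps Rd in 0.04-unit steps over 0.30–1.50.

## Leaf economics

`payback_days = (cost_factor × LMA) / (daily_gain × cho_per_mmol)` and the
same hyperbola with the lifetime target (default 4 g CHO per g leaf) in
place of the cost factor. Two constants required decisions:

- **cost_factor = 1.0 g CHO per g leaf.** Back-calculation from the four
  published worked day-counts (51 and 204 days at LMA 60 g m⁻² and
  40 mmol day⁻¹; 17 and 68 days at LMA 30 g m⁻² and 60 mmol day⁻¹) forces
  contribution/payback = target/cost = 4, hence cost = 1.0 on a CHO basis.
  The literature leaf construction cost of ≈1.5 g glucose per g leaf is
  available via the `cost_factor` argument but does not reproduce those
  day-counts.
- **cho_per_mmol = 1/34 ≈ 0.0294 g CHO per mmol CO₂.** The same
  back-calculation fixes the conversion: 60/(40·c) = 51 and 30/(60·c) = 17
  both give c = 1/34 exactly, and then all four day-counts are reproduced
  to the day. The textbook CH₂O-monomer convention (30 mg per mmol) is a
  selectable alternative (`cho_per_mmol=0.030`) and shifts the examples to
  50/17/200/67 days. Why the empirical constant is 34 rather than 30 mg is
  not derivable from first principles here; it is treated as a calibration
  constant of the published curves, not asserted as a stoichiometric claim.

Payback is undefined (infinite, `repays=False`) for non-positive gains.
Reported day-counts are rounded to whole days; exact values are retained.

## Trait statistics

Per-group OLS of Rd on A_max, and the dummy-variable model
`Rd = b0 + b1·A_max + b2·d1 + b3·A_max·d1` with d1 = 0 for the wintergreen
group and 1 for the comparison group. The two-sided t-test of b3 with n − 4
residual degrees of freedom is the single planned slope-equality contrast
(no multiplicity correction). This is algebraically identical to fitting
the two groups separately and testing the slope difference with pooled
residual variance, which the tests verify against an independent
implementation.

## Synthetic generators

The generators define the study conditions for all tests and the demo.

**Microclimate.** Above-canopy clear-sky PAR = 2000 µmol m⁻² s⁻¹ × sin
(solar elevation), from the standard declination + hour-angle model at the
configured latitude (default 35.4°N); longitude/equation-of-time effects
are ignored (solar noon = clock noon). Understory PAR = above-canopy PAR ×
canopy openness, on a piecewise-linear schedule: 30% open until canopy
leaf-out (day 110), closing linearly over 20 days to 8%, reopening at day
310. Openness is used directly as transmittance. Rare sunflecks
(probability 0.001 per daytime step) multiply PAR by 8, capped at the
above-canopy value; Gaussian noise (SD 5 µmol m⁻² s⁻¹) is added in daytime
only, then clamped at zero, so night-time PAR is exactly zero. Air
temperature is an annual sinusoid solved so the January and August monthly
means hit 3 °C and 25 °C, plus an 8 °C diurnal sinusoid peaking at 14:00
and Gaussian noise (SD 0.5 °C).

What this does **not** emulate: cloud-cover sequences and overcast spells,
diffuse-vs-direct partitioning (real deep-shade understories receive mostly
diffuse light, so the simulated summer understory is somewhat brighter than
a heavily shaded field site), snow burial, cold-air drainage, and
between-sensor heterogeneity. Passing tests therefore demonstrate that the
pipeline reproduces the *qualitative* seasonal structure — summer carbon
deficit under a closed canopy, spring/autumn gains under an open one — not
that it predicts any particular field site's absolute monthly totals.

**Reference response surface.** The built-in "true" plant is a
high-light-adapted, cool-optimum wintergreen leaf: paraboloid
(k, a, b, c, d) = (−0.3, −0.01, 0.05, −0.0025, 10⁻⁴), giving
Rd(T) ≈ 0.3 − 0.01·T + 0.0025·T² (≈ 1.6 µmol m⁻² s⁻¹ at 25 °C) and an
apparent quantum yield of 0.05; Lorentzian (a, k, b, l, c) =
(7.5, 13, 8, 900, 800), a 7.5 µmol m⁻² s⁻¹ peak at a cool 13 °C optimum
with a narrow 8 °C half-width. These values were chosen once so that the
default climate yields the qualitative seasonal pattern of interest — a
July–August deficit on the order of −20 mmol m⁻² day⁻¹ and strong
spring/autumn gains — and are fixed; plant-to-plant variation in the demo
ensemble is lognormal with 6% CV plus ±1 °C optimum jitter. Chamber
measurement noise defaults to SD 0.4 µmol m⁻² s⁻¹, which places fitted
surface R² in the high-0.8s/low-0.9s typical of such factorials.

**Trait tables.** A_max uniform on [3, 13] µmol m⁻² s⁻¹; Rd from the
generating lines 0.2201 + 0.0503·A_max (wintergreen group) and
0.4048 + 0.0504·A_max (comparison group) plus Gaussian noise (SD 0.05).
The two slopes are deliberately nearly identical, so the slope-equality
test should be non-significant under the defaults — the generator encodes
the null the statistics module is meant to fail to reject.

## Pipeline and reproducibility

The pipeline derives per-stage seeds from the single config seed by fixed
offsets, so every stage is independently reproducible and a rerun with an
identical config is bit-identical (the manifest records the config hash,
seed, package version and per-output row counts, and deliberately contains
no timestamps). Problem sizes in the demo and tests — five plants, one
synthetic year, six-day monthly windows, 200-replicate null checks — were
chosen as the smallest designs that exercise every code path with stable
statistics.

## Known limitations

- The paraboloid has no Temp × PAR interaction; seasonal contrast in the
  low-light regime enters only through Rd(Temp).
- Openness-as-transmittance overestimates deep-shade summer light (see
  above); absolute simulated gains are upper bounds for such sites.
- The aging schedule is parameterized (geometric or linear to a fixed
  endpoint), not derived from repeated field gas-exchange campaigns.
- The LCP time-budget and cost-ratio diagnostics depend on the fitted
  surface's behaviour near zero PAR, where chamber designs have few levels;
  they are reported, not error-barred.
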