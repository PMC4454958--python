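# Methods

This note documents the models, parameter choices and numerical
conventions behind `workrisk`, and what its synthetic-data tests do and
do not demonstrate about real measurement campaigns.

## Exposure model

Workplace air concentrations are treated as i.i.d. draws from a single
positive, right-skewed distribution; personal and area samples are pooled
(the reference campaign's fit did not stratify by sample kind, and with
~38 observations a stratified fit would be underpowered anyway). Four
candidate families are fitted by maximum likelihood with the location
pinned at zero — log-logistic, lognormal, gamma, Weibull — and ranked by
the Anderson–Darling statistic, computed against each fitted CDF via the
probability-integral transform:

    A² = −n − (1/n) Σᵢ (2i−1) [ln uᵢ + ln(1 − u_{n+1−i})],  uᵢ = F(x₍ᵢ₎).

Anderson–Darling is the primary criterion because it weights the tails,
and the quantity of regulatory interest (RME) is a tail quantile; the
Kolmogorov–Smirnov statistic breaks ties, then a fixed family order. A
family whose optimizer fails is dropped with a warning rather than
aborting the ranking. Note that A² values computed against a *fitted*
CDF are comparative scores, not significance tests.

CTE and RME are the median and 95th percentile of the selected
distribution, estimated by Monte-Carlo simulation (default 100,000
iterations, seeded NumPy `default_rng`, linear-interpolation order
statistics). The closed-form quantiles — for the log-logistic,
Q(p) = α(p/(1−p))^(1/β) — agree to within Monte-Carlo error and serve as
the independent oracle in the tests; the simulation route is kept as the
primary estimator because it generalises unchanged when exposure becomes
a function of several sampled variables. Runs under 1,000 iterations are
flagged, not refused. The geometric mean of the raw data is reported
alongside the fitted median, since both are conventional central-tendency
measures in exposure assessment; the median is the one that propagates
into risk characterization.

The log-logistic is the two-parameter form (no location shift): a third
parameter is not identifiable from a 38-sample campaign and would couple
the scale estimate to the detection limit.

## Synthetic measurement campaigns

The generator emulates a three-workplace campaign: for each workplace a
lognormal is moment-matched to the published arithmetic mean and SD
(σ² = ln(1 + SD²/AM²), μ = ln AM − σ²/2) and sampled by rejection into
the published [min, max] range. Defaults are the biphenyl campaign rows
(A: n=12, AM 0.034, SD 0.048, range 0.001–0.145; B: 14, 0.014, 0.022,
0.001–0.057; C: 12, 0.066, 0.075, 0.001–0.240 mg/m³; 38 samples in all,
detection limit 0.001 mg/m³).

Design choices:

- **Lognormal generation** even though the analysis stage often selects
  another family on a given draw — the standard industrial-hygiene
  generating assumption, and recovering a plausible family from data the
  generator did not label is precisely what the fitting stage must do.
- **Rejection rather than clipping**, because the published ranges are
  observed extremes, not censoring bounds; clipping would pile mass on
  the endpoints and bias the fitted tail. If a truncation window captures
  < 1% of the lognormal mass the generator refuses to sample instead of
  silently distorting the shape.
- **Per-workplace substreams** keyed by a SHA-256 hash of the workplace
  label under one master seed, so adding a workplace never shifts another
  workplace's draws.
- **Sample kinds alternate** personal/area as labels only; the analysis
  pools them.

What passing tests show — and don't. The synthetic campaign matches the
published first and second moments and range per workplace, but it is
i.i.d. by construction: no within-worker correlation, no day-to-day or
task structure, no censored records below the detection limit (values at
the limit are flagged but used at face value, as the reference assessment
did). Agreement of the pipeline on synthetic data therefore validates the
computational chain, not the distributional claims about any real
workplace. Accordingly the stochastic acceptance check is a band, not a
point: across 100 seeded replicate campaigns the fitted CTE must fall in
[0.01, 0.06] and the RME in [0.06, 0.25] mg/m³ in ≥ 90% of runs —
brackets around the reference values 0.03 and 0.12 mg/m³, which are not
exactly reproducible without the unpublished raw measurements. (In
practice the fitted CTE, a median, sits below the arithmetic mean 0.038
of a right-skewed distribution, typically near 0.02.)

## Dose-response derivations

**Carcinogenic.** UR_work = (SF·IR/BW)/CF with reference profile
IR = 20 m³/day, BW = 70 kg, lifetime 70 years, continuous exposure, and
worker profile 10 m³ per working day, 260 days/year, 40 years, 60 kg.
CF = (20/10)(365/260)(70/40) = 4.913 → 4.9 at reporting precision. The
body-weight pair is carried on the profiles but does not enter CF: the
inhalation-rate ratio already converts breathing volumes, and unit risks
are per-concentration, not per-body-burden.

**Non-carcinogenic.** RfC_work = POD_air · NOAEL_ADJ · NOAEL_HEC /
(UF_inter · UF_intra · UF_duration · UF_severity · UF_quality). The
duration factor comes from study-duration bands (≥ 6 months → 1,
≥ 13 weeks → 2, ≥ 4 weeks → 6; shorter studies are refused as
unsupported, with the longest matching band winning) and the severity
factor from the POD type (BMDL/NOAEL → 1, LOAEL → 5). Each agency schema
(KOSHA 0.5/1/3/5/2/1/1, EPA 0.17/1/3/10/3/1/1, ECHA 0.5/1/2.5/5/2/1/1,
MHLW 0.5/1/10/1/1/1/1 for ADJ/HEC/inter/intra/duration/severity/quality)
also carries generic duration/severity defaults for when study details
are unknown; the study-specific rules supersede them.

**Route-to-route extrapolation.** Oral PODs (mg/kg-day) are converted to
equivalent air concentrations by a composite multiplier in
(mg/m³)/(mg/kg-day) that is a mandatory, named configuration value of the
substance dossier. For biphenyl it is 2.78, inferred from the published
reference-concentration results (both oral chains, 23 → 2.13 and
20 → 0.31 mg/m³, back-solve to the same value); it absorbs the allometric
animal-to-human dose-scaling entry ("4") documented in the derivation
table, whose stand-alone physiological basis is not stated. The scaling
entry is kept on the schema for the audit trail but not applied
separately — applying both would double-count.

**Staged rounding.** Published chains propagate printed intermediates:
e.g. the ECR at the exposure limit, 7.05×10⁻⁴, arises only as
1.5 × (rounded 4.7×10⁻⁴), not from the unrounded product. The package
therefore rounds each intermediate to its printed precision before the
next step — half-up (0.005 → 0.01), 2 significant figures for IUR, CF and
UR_work, 2 decimals for RfC_work, 2 decimals on the 10⁻⁴ scale for ECR,
and 2 decimals below 1 / 1 decimal above for HQ — while every result
object retains the unrounded value and the ordered factor trail
(re-multiplying the trail reconstructs the unrounded value to 1e-12
relative error). Acceptability flags (ECR ≤ 1×10⁻⁴, HQ ≤ 1.0, boundary
inclusive — a value exactly at the limit is acceptable) are evaluated on
the *unrounded* values, so screening decisions never hinge on a rounding
step.

Known inconsistencies in the reference derivation are resolved as
follows: the correction factor is carried as 4.9 (the value consistent
with 2.3×10⁻³ → 4.7×10⁻⁴; an alternative 4.2 appears in the source
narrative but is not reconstructible from the stated profile ratios), the
inhalation LOAEL as 157.75 mg/m³ (also printed as 157.7 elsewhere), and
the OEL pairing 0.2 ppm ↔ 1.5 mg/m³ verbatim rather than recomputed
(the ideal-gas conversion with MW 154.21 and molar volume 24.45 L/mol
gives ≈ 1.26 mg/m³); risk at the OEL uses 1.5 mg/m³. The typical-exposure
HQ set published alongside the reference grid (0.05 inhalation, 0.08
reproductive at CTE) is not reproducible from the rounded CTE 0.03 under
any of these conventions (0.03/0.53 → 0.06, 0.03/0.31 → 0.10) and was
most likely computed from unrounded simulation output; the package
reports the values its own documented rounding produces.

## Units, defaults, degenerate inputs

| Parameter | Unit | Default | Why |
|---|---|---|---|
| molar volume | L/mol | 24.45 | 25 °C, 1 atm convention for workplace air |
| detection limit | mg/m³ | 0.001 | campaign floor; values at/below are flagged, used at face value |
| Monte-Carlo iterations | – | 100,000 | percentile SE ≪ reporting precision; < 1,000 flags a warning |
| ECR limit | – | 1×10⁻⁴ | conventional workplace acceptability |
| HQ limit | – | 1.0 | conventional acceptability |
| reference profile | m³/day, d/y, y, kg | 20, 365, 70, 70 | general-population basis of published unit risks |
| worker profile | m³/day, d/y, y, kg | 10, 260, 40, 60 | light-work shift, Korean worker basis |

Degenerate inputs are refused loudly: constant-valued data (no
distribution fittable), fewer than 5 observations, non-positive
concentrations for fitting, study durations under 4 weeks, oral PODs
without a conversion multiplier, truncation windows under 1% acceptance.
Summaries of single-observation groups report SD = 0 with a degeneracy
flag. SD uses the n−1 denominator throughout.

## Problem sizes

The default test suite runs ~150 tests in a few seconds: fitting checks
use 5,000–10,000 draws, the seeded band check runs 100 replicate
campaigns of 38 samples with 100,000 Monte-Carlo iterations each, and
`scripts/acceptance.py` repeats that plus the deterministic chains in a
few seconds. These sizes put Monte-Carlo error well below every tolerance
asserted.

## Limitations

Screening-level by design: no censoring-aware fitting (simple
substitution at the detection limit), no between-/within-worker variance
components or Bayesian exposure models, no dermal route, no mixtures, no
benchmark-dose modelling from raw dose-response data (PODs enter as
published numbers), and no toxicokinetic human-equivalent-concentration
modelling beyond the scalar NOAEL_HEC factor. The oral-to-air multiplier
is an empirical composite, not a physiological model; assessments of
other substances must supply their own value deliberately.
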