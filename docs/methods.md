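# Methods

## Carbonate system

All chemistry is on the total pH scale at surface pressure (the archive
grows at ≤ 10 m).  Constants as functions of temperature and salinity:
K₁/K₂ from the Lueker formulation (total scale), boric acid K_B from
Dickson (1990), K_w from Millero (1995), CO₂ solubility K₀ from Weiss
(1974), total boron B_T = 415.7·S/35 µmol/kg (Uppström proportionality;
the scale factor is an argument).  The K_w expression is used in its
published form without the sulfate/fluoride scale conversion: the ~0.01
shift in pK_w it would introduce moves a solved surface pH by < 10⁻⁴,
far below every tolerance in play.  Nutrient (Si, P) alkalinity terms are
omitted — the scenario models are defined on ALK/DIC/S/T only.

pH from (ALK, DIC) is the root of

ALK = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]

found by Brent bracketing on pH ∈ [2, 12] with xtol 10⁻⁸; the solved state
must close the balance to < 0.01 µmol/kg or a no-solution error is raised
(an absent sign change in the bracket signals an unphysical ALK/DIC pair).
The companions — ALK from (pH, DIC), DIC from (pH, ALK) and from
(pH, pCO₂) — are closed-form speciation evaluations; (ALK, pCO₂) is a
one-dimensional root in pH.  The solver is verified in the tests against a
brute-force pH grid scan at 10⁻⁵ resolution with independently written
speciation expressions.

Below S = 19 psu (the stated validity floor of the Lueker constants) the
package warns and proceeds rather than clamping: river-mixing sweeps
legitimately pass through that regime and the user should see it.
pK*_B averaged over 6–11 °C at S = 30.3 reproduces the 8.82 constant used
in the worked proxy example; per-year values from the environment series
are the default, with a fixed-8.82 mode for reproducing that example.

## δ¹¹B → pH

The species calibration (slope 1.46, intercept 6.91 ‰, 2σ errors 0.06 and
0.72) maps skeletal δ¹¹B to borate δ¹¹B; the borate equation
(α_B = 1.0272) maps borate δ¹¹B and pK*_B to pH.  Below a skeletal δ¹¹B of
about 24.7 ‰ (at δ¹¹B_sw = 39.73) the log argument is non-positive and no
pH exists; scalar calls raise, the Monte-Carlo path counts and drops such
draws, and a record with > 50% invalid draws is excluded with a warning.

δ¹¹B_sw defaults to 39.73 ‰, the mean of the five local seawater
measurements shipped with the package, because it reproduces the worked
7.87 example; the open-ocean compilation value 39.61 ‰ is a parameter.
The two differ by ~0.02 in reconstructed pH.

Monte-Carlo reconstruction: per record, n_draws (default 2000) independent
draws of measurement error (normal, σ = half the concentration-dependent
2σ), calibration slope and intercept (stated 2σ halved; sampled
independently — the calibration covariance is unpublished, and
independence is the conservative documented assumption), δ¹¹B_sw
(±0.1 ‰), temperature (±1 °C) and salinity (±1 psu), with pK*_B recomputed
per draw.  Medians and the 16/84 and 2.5/97.5 percentiles are reported.
Draws are vectorised per record in fixed row order from one seeded
generator, so output is bit-stable for a given seed.  In the small-noise
limit the envelope half-width matches first-order analytic propagation
within 15% (tested); empirical 68% coverage is nominal when each record's
generating parameters are drawn from the same error model (tested at
n = 200).

## Screening

Primary algal carbonate shows a positive linear B/Ca–δ¹¹B association;
serpulid worm infill (B/Ca ≈ 400 µmol/mol, δ¹¹B ≈ 18 ‰) drags sub-samples
off it towards high B/Ca and low δ¹¹B.  The published exclusion of such
samples was partly visual (proximity to borings); here a reproducible rule
replaces it: a Theil–Sen fit of δ¹¹B on B/Ca, then one deterministic pass
flagging records whose residual falls below −k·MAD (scaled MAD, k = 3 by
default, exposed in config) while their B/Ca exceeds the median.  Records
below the δ¹¹B invertibility limit are independently flagged
`uninvertible`.  One-pass flagging guarantees order-invariance and
idempotence; an optional two-pass refit exists but is off by default.
A two-endmember mass balance (primary component assumed on the trend,
linear mixing in both coordinates) gives a contamination-fraction estimate
for flagged records, clipped to [0, 1].

The residual criterion is a calibration choice, not a derivation: no
numeric threshold accompanies the published exclusions, so k = 3 is the
default and reproducing any particular flagged count on real data is a
calibration outcome.  Because analytical noise is strongly
heteroscedastic in [B], records measured at very low boron concentration
can sit near the threshold; the false-positive rate on clean synthetic
records stays below 1% (tested at n = 10⁴).

## Chronology

Annual anchors are local maxima of the linearly detrended, moving-mean
smoothed Mg/Ca transect (resampled to a uniform grid).  Defaults are
data-derived so the procedure is invariant to uniform rescaling of the
distance axis: smoothing window = 1/8 of the median cycle length from the
periodogram's dominant frequency; prominence threshold = 0.25 × IQR of the
detrended series.  The series is reflect-padded by half a cycle so maxima
truncated by the transect ends keep their prominence; candidate peaks
falling exactly on an end sample are ambiguous (a real boundary maximum
vs. the mirror of an unsampled one) and are accepted only when the sampled
length in units of the median annual spacing implies more years than the
interior maxima supply.  Years count backwards from the collection year
(the living surface), the partial outermost year belonging to the
collection year.  Bands are dated by largest overlap with the annual
intervals (boundaries midway between anchors), ties to the younger year.

The published chronology was built by counting cycles without a stated
algorithm, so these parameters are free choices validated on synthetic
transects: exact counts on noise-free input at any phase, ±1 year under
20% amplitude noise with ±30% growth-rate jitter, and ≥ 95% correct band
dates at those noise levels.

## Mixing models

Alkalinity, DIC and salinity mix linearly (conservative); temperature is a
scenario constant, not mixed.  Endmembers: Warm Slope Water
(2375/2050/36.5), Labrador Slope Water (2200/2050/34), Scotian Shelf Water
(2150/2000/32), offshore Gulf of Maine seawater (2200/2050/33, pH 8.00 at
the default 10 °C — the temperature was chosen so the unmixed seawater pH
is 8.0 as specified).  The two-water sweep trades WSW against LSW (the
hydrographic scenario it represents); the full three-water simplex is a
separate grid, optionally at fixed salinity for contour-plot use.

River mixing uses a 230 µmol/kg river alkalinity with DIC 428 µmol/kg at
river pH 6.6 and 261 at pH 7.2 (linearly interpolated between), following
the values published alongside the scenario; recomputing river DIC from
(ALK, pH) with the marine constants extrapolated to the freshwater limit
reproduces the pH-7.2 value within ~2% but not the pH-6.6 value, which is
why the tabulated pair is the default.  The sensitivity sweep rescales
river ALK by ±50% with DIC scaled proportionally (preserving river pH, to
first order, since freshwater alkalinity is carbonate-dominated).

One scenario result disagrees with the published discussion and is
reported as computed: the smallest river fraction whose between-scenario
pH shift reaches 0.2 units is ~29%, not > 50%.  The shift grows
superlinearly with river fraction because dilution collapses the
mixture's buffer capacity; a linear extrapolation of the 5% response
(0.02 × 10) gives exactly the published 50%.  The package's threshold
does satisfy the companion published bound that the contribution must be
"significantly more than 20%".

The +0.2-pH alkalinity-budget question is exposed through both framings —
fixed DIC (≈ 60 µmol/kg for 7.7 → 7.9 at 10 °C, S 30.3, DIC 2050) and
fixed pCO₂ (much larger, since equilibrium DIC rises steeply with pH at
constant pCO₂) — and neither is asserted to equal any particular value:
the two answer different scenario questions.

## Synthetic data

The generator forward-models the reconstruction chain exactly: prescribed
pH → borate δ¹¹B (inverse borate equation at that year's pK*_B from the
generated T/S series) → skeletal δ¹¹B (calibration) → analytical noise.
Default conditions emulate the study setting: years 1920–2020; baseline pH
oscillating between 7.7 and 7.9 with a period drawn once from 8–12 yr (the
quasi-decadal variability is described but not parameterised in the
source, so a fixed-amplitude sinusoid stands in); a +0.2 ramp over
1980–2000; temperature ~8 °C warming linearly to ~11 °C over 1980–2020
(clipped to 5–13 °C); salinity 30.3 ± 0.3 psu; solution boron 4–40 ng/g.
B/Ca follows a linear trend of 25 µmol/mol per ‰ anchored at
(27 ‰, 250 µmol/mol) with σ = 5 noise — free parameters chosen to give
realistic coralline B/Ca values below the worm endmember.  5% of bands are
mixed toward the worm endmember with a per-band fraction drawn from
0.1–0.5: infill intensity varies in reality, and the heavily infilled
bands are the ones that also fall below the δ¹¹B invertibility limit.
Mg/Ca transects carry one seasonal cosine per year (mean 2.5, amplitude
0.8 mmol/mol, 20% amplitude noise) with ±30% growth-rate jitter around
300 µm/yr.

What passing tests show — and what they do not: the generator shares the
proxy equations with the reconstructor, so round-trip exactness in the
noise-free limit validates the inversion algebra and plumbing, not the
calibration's truth on real algae.  Real archives add specimen-level
systematics (vital-effect drift, light, growth hiatuses) and spatially
correlated contamination that the generator does not emulate; envelope
coverage on the default single-specimen scenario therefore exceeds its
nominal 68% (the propagated calibration/T/S/δ¹¹B_sw uncertainties are
systematic there, not per-band noise), and the dedicated coverage
simulation redraws every source per record to test the nominal case.

## Problem sizes and numerics

Defaults used throughout the tests and scripts: 2000 Monte-Carlo draws per
record (10⁴–5×10⁴ where convergence or the linear-propagation limit is
itself under test), 200-record coverage simulations, 101-point river
sweeps at 0.01 fraction steps, 1000-state solver validation against the
grid-scan oracle.  All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; reruns with the same seed are
byte-identical.  Degenerate inputs are errors, not silent fixes, with two
exceptions chosen deliberately: sub-19-psu salinity warns, and bands
outside a dated transect get a missing year plus a warning.

## Known limitations

- No pressure correction, fugacity correction, or alternative constant
  sets; not a general CO2SYS replacement.
- The borate equation's pH sensitivity degrades near the invertibility
  limit; records there carry asymmetric, wide envelopes.
- Calibration slope/intercept independence is assumed (covariance
  unpublished); if they covary negatively the envelopes are conservative.
- The screening rule is blind to contaminants that mimic the primary
  B/Ca–δ¹¹B trend.
- Chronology assumes one Mg/Ca cycle per year; missed or doubled years in
  slow-growth intervals alias directly into band dates.
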