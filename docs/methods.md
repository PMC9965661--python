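# Methods

## The measurement and its model

A closed-bottle respirometry trial incubates a micronized polymer
(100 mg/L by default) in nutrient-enriched seawater with a natural marine
inoculum and logs cumulative biological oxygen demand (BOD, mg O₂/L)
daily for 28 days. Three bottle roles are required: blanks (inoculum
only), a PHB positive control, and the test materials, each in replicate
(duplicates by default). Mineralization of accessible polymer carbon
produces a sigmoidal BOD curve; the kinetics module models it with a
family of nested log-logistic forms

- fixed slope (2 parameters): `Y = BOD_L / (1 + a/X)`
- variable slope (3): `Y = BOD_L / (1 + (a/X)^b)`
- asymmetric (4): `Y = BOD_L / [1 + (2^(1/S) − 1)(a/X)^b]^S`

with ultimate BOD `BOD_L` (mg O₂/L), half-degradation time `a` (days),
slope `b` (dimensionless rate proxy) and asymmetry `S`. The asymmetric
form's normalizing constant is chosen so all three curves pass through
`BOD_L/2` at `X = a`; at `X = 0` all are continued by their limit 0. The
forms are strictly nested (`b = 1` recovers the fixed slope, `S = 1` the
variable slope), which is what licenses the extra-sum-of-squares F-test.

Assumptions worth stating: cumulative BOD is carbonaceous (the protocol
uses nitrate, not ammonium, as nitrogen source precisely to suppress
nitrogenous oxygen demand — no nitrification correction is applied);
measurement errors are additive, homoscedastic and independent between
readings; replicate bottles share one true curve.

## Preprocessing and normalization

Blank correction subtracts the mean blank BOD, interpolated linearly onto
each material's observation grid, from every replicate of every treatment
— including the positive control, for symmetry (blank signal is gated
below 2%, so the choice of whether to correct the control is numerically
immaterial). Negative corrected values are retained, not clipped: clipping
would bias low-signal materials upward. Replicates are aggregated by
arithmetic mean for reporting, but fitting pools the individual replicate
points so the residual degrees of freedom reflect all observations.

%C+ at day `d` is `100 × corrected(d) / corrected_C+(d)`. Classification
uses the *observed* %C+ at the assessment day (28 d by default), not a
ratio of fitted asymptotes: the class thresholds are defined for a fixed
28-day window, while `BOD_L` is reported alongside as the
exposure-time-independent biodegradability estimate.

Theoretical oxygen demand is standard complete-oxidation stoichiometry
per repeat unit: `ThOD = (32·nC + 8·nH − 16·nO + 24·nS + 40·nP + Nterm) / M`
g O₂/g, with `Nterm = +40·nN` when nitrogen ends as nitrate (default,
matching the medium) or `−24·nN` when it stays reduced. For the PHB repeat
unit C₄H₆O₂ this gives 1.673 g O₂/g, so a 100 mg/L dose has a 167.3 mg
O₂/L ceiling; the QA gate requires the control to exceed 60% of it.

## Fitting and confidence intervals

Bound-constrained nonlinear least squares (trust-region reflective) over
the pooled replicate points, unweighted. Bounds: `BOD_L ∈ (0, 10×max BOD]`,
`a ∈ (0, 10×max time]`, `b ∈ (0, 20]`, `S ∈ [0.01, 100]`. Starting values
are deterministic and data-driven — `BOD_L₀ = 1.1×max`, `a₀` the first
half-maximum crossing of the replicate-mean curve (linear interpolation),
`b₀ = S₀ = 1` — so a fit has no random state and is bit-reproducible.

95% CIs are asymptotic Wald intervals, `θ̂ ± t₀.₉₇₅,df · se(θ̂)` with
`se` from `s²(JᵀJ)⁻¹` at the optimum. Commercial curve-fitting software
often reports intervals from a transformed scale, which look asymmetric;
the plain Wald intervals here are symmetric by construction. A parameter
whose covariance entry is singular or non-finite is flagged *not
calculable* (n.c.). A series whose corrected signal never rises above
zero is not fitted at all: the result is a refused fit carrying the mean
of the final three observations as a `BOD_L` point estimate, with every
interval n.c. — flat negative-control curves are reported, not errored.

## Model selection

For nested fits the extra-sum-of-squares statistic is
`F = ((RSS_s − RSS_c)/(df_s − df_c)) / (RSS_c/df_c)` on
`(df_s − df_c, df_c)` degrees of freedom, clamped to `F = 0, p = 1` when
the optimizer leaves the complex model no better. The information
criterion is AICc, `n·ln(RSS/n) + 2K + 2K(K+1)/(n−K−1)` with `K =
n_params + 1` (the error variance counts as a parameter); AICc rather
than plain AIC because typical trials have 29–58 points against 3–5
parameters (a plain-AIC mode exists behind a flag). The comparison is
reported as `ΔAICc = AICc(simple) − AICc(complex)`, positive favouring
the complex model.

Selection walks the ladder fixed → variable → asymmetric and steps up
only when the F-test (α = 0.05 by default), ΔAICc > 0, **and**
identifiability of the newly added parameters all agree. The third clause
is not decorative: on real sigmoids the asymmetry parameter routinely
improves RSS significantly while its own confidence interval spans the
whole line, and a significantly-better-fitting model with an
unidentifiable parameter is noise-fitting, so the simpler model is kept.
Selection is deterministic given the data.

## Synthetic trials

The generator mirrors the standard design: daily sampling over days 0–28,
duplicate bottles, treatment reading = true curve + blank level + N(0, σ²),
blank reading = blank level + noise, all clipped at 0 (a cumulative-uptake
sensor cannot go negative). Defaults, chosen once as a realistic trial:
σ = 0.3 mg O₂/L (the scale of a manometric sensor's resolution; a
heteroscedastic option scales σ with the signal for robustness checks);
blank level `0.6 + t/70` mg O₂/L, putting the day-28 blank near 1% of the
default control — inside the <2% QA gate — while keeping clipping below
1% of points; control = PHB-like curve with `BOD_L = 110` mg O₂/L
(≈66% of the ThOD ceiling), `a = 8` d, `b = 2`. Randomness is
counter-based: one seed spawns an independent stream per bottle, so
extending a spec never perturbs existing bottles.

The reference-panel presets pin each material's published variable-slope
parameters (`b`, `BOD_L`) and default the unpublished half-degradation
time to 10 d, mid-assay. The control asymptote is then tuned so the
simulated day-28 %C+ reproduces the material's published value, clamped
to a physically plausible 110–165 mg O₂/L (above the 60%-of-ThOD gate,
below the 167 mg O₂/L ceiling). For a few materials the published %C+ and
`BOD_L` are mutually inconsistent under the arbitrary 10-day
half-degradation time, so their simulated %C+ lands near rather than on
the published number; every preset still reproduces the published
four-class verdict end-to-end.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: lag-phase microbiology and inoculum
variability, autocorrelated sensor drift, temperature excursions,
leaching of soluble additives (which produces early plateaus the logistic
family can only approximate), and replicate-to-replicate biological
variance beyond additive noise.

## Numerical choices and edge cases

- Linear interpolation everywhere a value is needed off-grid; requests
  outside a bottle's observed range raise rather than extrapolate.
- Strict-inequality QA gates exactly as defined (<2%, >60%); an unknown
  control composition makes the ThOD gate indeterminate, not failed.
- Class boundaries close on the lower class: 5 → non, 20 → slightly,
  60 → moderately.
- Day-0 readings are accepted and enter the fit with model value 0.
- A perfect (zero-RSS) fit gets a floor of 1e-300 inside the AICc
  logarithm.
- `%C+` with a non-positive control at the assessment day is refused as a
  degenerate trial rather than returning a signed surprise.

## Problem sizes

Tests and the reproduction script run 28-day daily grids with duplicate
bottles; stochastic checks use 200 seeded trials (parameter recovery,
mean-slope reproduction) and 1000 trials for the type-I-error rate of the
F-test under fixed-slope truth, sizes at which the binomial/Monte-Carlo
error is comfortably inside the asserted tolerances.

## Known limitations

Wald intervals are symmetric first-order approximations and degrade for
strongly correlated parameters (notably `BOD_L`–`a` when the curve has
not plateaued by day 28; the panel materials with the widest published
intervals show exactly this). Unweighted least squares is correctly
specified only under homoscedastic noise. The four-class scheme is a
screening heuristic on a 28-day window, not a regulatory pass/fail, and
%C+ inherits any atypicality of the positive-control batch.
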