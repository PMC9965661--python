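# marbod — marine biodegradability assessment from BOD respirometry

`marbod` turns raw closed-bottle respirometry data into a defensible
marine-biodegradability verdict. It is written for labs running rapid
(28-day) seawater biodegradation screens of polymers — compostable bags,
coatings, prototype bio-based materials — with a manometric respirometer
(e.g. OxiTop bottles), duplicate treatments, blanks, and a PHB positive
control.

From per-bottle cumulative BOD time series the package performs:

1. **Blank correction** — the mean blank BOD is subtracted from every
   treatment at every time point.
2. **%C+ normalization** — corrected BOD is expressed as a percentage of
   the corrected positive-control BOD at the same day. Normalizing to a
   fully marine-biodegradable reference (PHB) sidesteps the need to know
   the exact elemental composition of heteropolymers and blends.
3. **Kinetic modeling** — BOD curves are fit by bound-constrained nonlinear
   least squares to a family of nested log-logistic models:

   - variable slope: `Y = BOD_L / (1 + (a/X)^b)`
   - fixed slope: the same with `b = 1`
   - asymmetric: `Y = BOD_L / [1 + (2^(1/S) − 1)(a/X)^b]^S`

   where `X` is time (days), `Y` cumulative BOD (mg O₂/L), `BOD_L` the
   ultimate BOD (asymptote — biodegradability independent of exposure
   time), `a` the half-degradation time (days), `b` the slope (a rate
   proxy) and `S` the asymmetry. 95% confidence intervals are asymptotic
   (Wald) intervals; unidentifiable parameters are flagged "n.c.".
4. **Model selection** — extra-sum-of-squares F-test plus small-sample
   Akaike criterion (AICc), stepping up to a more complex model only when
   both criteria agree *and* the added parameters are identifiable.
5. **QA gates** — blanks must stay below 2% of the positive control at the
   assessment day, and the positive control must exceed 60% of its
   theoretical oxygen demand (ThOD, computed from complete-oxidation
   stoichiometry: per repeat unit, grams O₂ = 32·C + 8·H − 16·O + 24·S +
   40·P, plus 40·N with nitrate as nitrogen source or −24·N with ammonium,
   divided by the unit's molar mass).
6. **Classification** — the day-28 %C+ maps onto four classes:

   | %C+ at day 28 | verdict |
   |---|---|
   | > 60 | readily biodegradable |
   | 20 < x ≤ 60 | moderately biodegradable |
   | 5 < x ≤ 20 | slightly biodegradable |
   | ≤ 5 | non-biodegradable |

A synthetic-data module simulates complete trials (sigmoidal treatments,
drifting low-signal blanks, additive Gaussian sensor noise, replicate
bottles, clipping at zero) so the whole pipeline is testable without any
instrument data, and ships presets for a 14-material reference panel
spanning all four classes.

## Worked example

Simulate the home-compostable-bag scenario (true slope b = 1.40, ultimate
BOD 22.2 mg O₂/L, half-degradation time 10 d, 0.3 mg/L sensor noise) and
assess it:

```sh
$ marbod simulate --preset ID016 --seed 7 --output id016.csv --meta-output id016-meta.csv
wrote 6 bottles to id016.csv

$ marbod assess --input id016.csv --meta id016-meta.csv --output report.json
material       %C+ class        model              BOD_L
ID016        17.4% slightly     variable_slope     23.10
```

The material reached 17.4% of the positive control by day 28, which lands
in the "slightly biodegradable" band (5–20%). The kinetic detail:

```sh
$ marbod fit --input id016.csv --meta id016-meta.csv --material ID016
# ID016
  fixed_slope     rss=16.91  BOD_L=30.86 (29.10, 32.62)  a=18.31 (16.27, 20.36)
  variable_slope  rss=9.446  BOD_L=23.10 (21.63, 24.57)  a=10.55 (9.39, 11.72)  b=1.35 (1.23, 1.46)
  asymmetric      rss=9.421  BOD_L=22.46 (18.92, 25.99)  a=10.14 (7.85, 12.43)  b=1.47 (0.77, 2.17)  S=0.85 (0.17, 1.54)
  fixed_slope vs variable_slope: F=43.5 p=1.75e-08 dAICc=31.5 -> complex
  variable_slope vs asymmetric: F=0.14 p=0.71 dAICc=-2.25 -> simple
  selected: variable_slope
```

The variable-slope model is strongly preferred over the fixed slope
(p ≈ 2·10⁻⁸, ΔAICc = +31.5) while the asymmetric form adds nothing
(p = 0.71, ΔAICc < 0), so the selected fit recovers b = 1.35 (1.23, 1.46)
and BOD_L = 23.1 (21.6, 24.6) mg O₂/L against the true 1.40 / 22.2 — the
asymptote estimates ultimate biodegradability without waiting for the
curve to plateau. Quality gates:

```sh
$ marbod qa --input id016.csv --meta id016-meta.csv
blank / C+ at day 28: 1.07% [PASS, must be < 2%]
C+ / ThOD at day 28: 60.7% [PASS, must be > 60%]
```

The same pipeline is available as a library (`marbod.assess`,
`marbod.fit`, `marbod.select_model`, `marbod.classify`, …); see the module
docstrings and `docs/methods.md`.

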