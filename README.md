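# symporteq

Equilibrium analysis of reversible, electroneutral monocarboxylate/H⁺
symport across the yeast plasma membrane — the transport mode of
carriers like Jen1, which co-translocate one proton per monovalent
carboxylate anion (lactate, pyruvate).

## The problem

Because the proton and the anion cross together, the transport step
moves no net charge: of the two components of the proton motive force,
only the pH gradient ΔpH = pH_in − pH_out drives accumulation. At
thermodynamic equilibrium the anion distributes as

```
[A⁻]_in / [A⁻]_out = 10^ΔpH            (accumulation ratio, AR)
```

and the ratio of *total* acid (anion + undissociated form, pKₐ) is

```
R_total = 10^ΔpH · (1 + 10^(pKₐ − pH_in)) / (1 + 10^(pKₐ − pH_out))
```

At a typical acidic culture pH of 5 and cytosolic pH 7 this predicts a
100-fold anion accumulation (93-fold for total lactic acid, pKₐ 3.86).
But as the medium approaches and exceeds the cytosolic pH, equilibrium
flips to net *export*: holding a constant cytosolic pool forces the
extracellular concentration up as 10^(pH_out − pH_in), and in dilute
cultures (intracellular volume ≈ 0.02% of the culture at 100 mg/L
biomass) essentially the whole metabolite pool leaks into the medium.
Removing the transporter from the membrane (endocytosis above
pH ≈ 7.0–7.25) prevents that loss.

The package is aimed at researchers analysing chemostat pH-ramp
experiments and transporter-localisation micrographs. It provides:

* `symporteq.thermo` — closed-form equilibrium thermodynamics
  (accumulation ratios, Henderson–Hasselbalch speciation, driving force).
* `symporteq.inference` — back-calculation of cytosolic concentrations
  from residual-metabolite series, observed/predicted AR profiles, and
  `AccumulationRatioModel` / `AccumulationRatioResults`, a
  statsmodels-style least-squares fit of the log-linear equilibrium law
  `log10 c_out = (log10 c_in − pH_in) + pH_out`.
* `symporteq.chemostat` — a stiff-safe simulator of a continuous
  culture (D = 0.07 h⁻¹, 33 mM lactate + 50 mM ethanol feed) under a
  programmed pH ramp, with reversible symport kinetics, a pH-dependent
  growth ceiling (washout above pH ≈ 7.25) and seeded measurement
  noise — the synthetic-data generator for end-to-end testing.
* `symporteq.leakage` — the metabolite-partition mass balance for
  dilute cultures.
* `symporteq.imaging` — the per-cell plasma-membrane/total fluorescence
  statistic (integrated-density difference between a whole-cell mask
  and its erosion) plus a synthetic epifluorescence image generator
  with exact ground truth.
* `symporteq.cli` — a `symporteq` command with `thermo`, `infer`,
  `simulate`, `leakage`, `quantify` and `demo` subcommands; every run
  writes a reproducibility manifest.

## Worked example

```sh
$ symporteq demo
```

prints (abridged):

```
pH_in 7.0, pH_out 5.0:
  anion accumulation ratio 10^dpH              = 100
  combined lactate/lactic-acid ratio (pKa 3.86) = 93.3 (~93-fold)

100 mg/L biomass, 2 mL/g intracellular volume, 1 L culture:
  intracellular volume fraction                 = 0.02%

1 mM intracellular pyruvate at dpH = 0 (molar mass 88 g/mol):
  intracellular amount                          = 0.2 umol
  extracellular amount                          = 1 mmol
  extracellular mass                            = 88 mg
  as % of total cell mass                       = 88%
```

i.e. a two-decade pH gradient sustains a 100-fold anion accumulation
(93-fold after the pKₐ correction), while at ΔpH = 0 a dilute culture
holds only 0.2 µmol of a 1 mM cytosolic pyruvate pool inside the cells
against 1 mmol — 88 mg, 88% of the cell dry mass — outside.

The simulation → inference round trip, from the library:

```python
import numpy as np
from symporteq import ChemostatConfig, recover_parameters
from symporteq.chemostat import simulate, sample_measurements

config = ChemostatConfig()            # pH 6.75 -> 7.25 at 0.05 pH/h, D = 0.07/h
trace = simulate(config)
series = sample_measurements(trace, np.linspace(6.75, 7.0, 20),
                             noise_cv=0.05, seed=1, n_replicates=1)
res = recover_parameters(series["lactate"], max_pH=7.0, assume_pH_in=7.0)
print(res.summary())
```

recovers the configured cytosolic lactate concentration (0.62 mM) to
within a few percent, with a diagnostic free slope ≈ 1 confirming the
simulated culture tracks transport equilibrium below the
internalization threshold.

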