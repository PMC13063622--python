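# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `symporteq`.

## 1. Equilibrium thermodynamics (`symporteq.thermo`)

**Model.** A secondary carrier co-transporting n_H protons with one
carboxylate anion of charge z is electroneutral iff n_H + z = 0. For the
electroneutral mode the membrane potential Δψ cancels from the
electrochemical balance and equilibrium requires

    μ_A(in) + n_H·μ_H(in) = μ_A(out) + n_H·μ_H(out)
    ⇒  [A⁻]_in/[A⁻]_out = 10^(n_H·ΔpH),   ΔpH = pH_in − pH_out.

The default stoichiometry is 1 H⁺ : 1 anion. Non-electroneutral
stoichiometries are rejected with `UnsupportedStoichiometryError`
rather than silently invoking a Δψ term: the charged generalisation
would require a parameterised membrane potential that this equilibrium
layer deliberately does not model. `delta_psi` is stored and validated
on `TransmembraneState` for completeness only.

**Speciation.** Henderson–Hasselbalch gives the anion fraction
f(pH) = 1/(1 + 10^(pKa − pH)). Since only the anion is transported, the
total-acid ratio is the anion ratio times
(1 + 10^(pKa − pH_in))/(1 + 10^(pKa − pH_out)). For lactic acid
(pKa 3.86) between pH_out 5 and pH_in 7 this converts the 100-fold
anion ratio into a 93-fold total ratio; the correction vanishes
(relative deviation < 10⁻³) once pKa ≤ min(pH) − 3.

**Driving force.** ΔG = RT·[ln(c_in/c_out) − n_H·ln10·ΔpH], reported in
kJ/mol with R = 8.314 J mol⁻¹ K⁻¹ and T defaulting to 303.15 K
(cultures grown at 30 °C). ΔG = 0 exactly at the accumulation ratio.

**Units.** Concentrations are mM throughout the computational layers;
g/L appears only at the I/O boundary, converted with the acid's molar
mass (lactate 90.08, pyruvate 88.06 g/mol). The leakage worked example
deliberately uses the round value 88 g/mol (see §4).

**Verification.** All ratio operations are checked against an
independent oracle that equilibrates chemical potentials numerically
(root-finding on log10 c_out) to 10⁻⁶ relative error over randomised
(pH_in, pH_out, pKa) grids.

## 2. Accumulation-ratio inference (`symporteq.inference`)

**Observed vs predicted AR.** Given replicate residual concentrations
c_out(pH) and an assumed constant cytosolic pool c_in at cytosolic pH
pH_in, the observed accumulation ratio is c_in/c_out(pH) and the
prediction is 10^(pH_in − pH_out). Replicates are aggregated by
arithmetic mean per pH before the ratio is formed (the study design
this emulates runs duplicate cultures); per-replicate ratios are also
emitted for dispersion reporting. Zero/below-detection measurements
cannot produce a finite ratio and are dropped with a logged warning
rather than imputed.

**Back-calculating c_in.** At pH_out = pH_in the equilibrium ratio is
1, so c_in equals the measured c_out there. The replicate-averaged
measurement nearest to pH_in is used when one lies within 0.05 pH
units; otherwise the value is interpolated linearly in concentration
between the bracketing pH points (the sampling intervals in the
emulated design are ≤ 0.25 pH units, where curvature of the exponential
is negligible). Queries outside the measured range raise — the
back-calculation never extrapolates. Note the nearest-point rule
carries the local concentration slope over up to 0.05 pH units
(≤ ~5% at unit slope); grids that include pH_in exactly avoid it.

**The equilibrium fit.** `AccumulationRatioModel` fits
log10 c_out = α + pH_out with the slope fixed at its theoretical value
of 1, so α̂ is the mean of log10 c_out − pH_out and its standard error
is σ̂/√n. A free-slope OLS fit (statsmodels) runs alongside as a
diagnostic: a slope far from 1 means the culture is not tracking
transport equilibrium, and the fit window should be restricted (the
`max_pH` cut excludes the internalization regime).

**Identifiability.** Only α = log10 c_in − pH_in enters the
likelihood: (pH_in, c_in) pairs with equal α produce identical data, so
the pair is not jointly identifiable from a single series. `fit()`
therefore estimates one parameter conditional on an anchor for the
other; with no anchor given, pH_in is fixed at 7.0, the literature
value for the budding-yeast cytosol that the emulated study also
adopts. The reported RMSEs in the acceptance study are the conditional
estimators' errors and quantify the precision of α̂ propagated to
either parameter.

**Deviation flags.** `deviation_report` labels each pH point
below/at/above equilibrium using a relative band (default 30%). The
default is wide enough that a faithful simulated ramp measured with 5%
noise is never flagged at or below pH_in, while the post-threshold
regime (residuals held up by internalization and, in the real system,
elevated intracellular demand) is flagged reliably. The tool only flags
deviations; it does not model their mechanism.

## 3. Chemostat simulator (`symporteq.chemostat`)

**What it emulates.** Aerobic carbon-limited continuous cultures,
D = 0.07 h⁻¹, fed 33 mM L-lactate + 50 mM ethanol, held at steady state
and then subjected to a linear pH ramp (default: pH 6.75 → 7.25 at
0.05 pH h⁻¹; the slower 0.01 pH h⁻¹ design is a parameter change).
State variables: biomass X (g/L), residual lactate, ethanol and
pyruvate (mM). The pH profile is piecewise linear and exact, not
integrated.

**Rate laws.**

* Lactate: reversible symport in the linear nonequilibrium regime,
  q_lac = k_up·f(pH)·(S_lac − c_in·10^(pH − pH_in)) with f(pH) the
  surface fraction of the transporter, a decreasing logistic
  1/(1 + 10^(k·(pH − pH_half))) with pH_half = 7.1 and k = 8 decades per
  pH unit (midpoint inside the observed 7.0–7.25 internalization
  window). First-order reversibility was chosen over full reversible
  Michaelis–Menten because the claim being reproduced is operation *at
  or close to equilibrium*, which this law captures with a single
  parameter; k_up = 800 L g⁻¹ h⁻¹ makes the relaxation time of the
  lactate balance milliseconds-scale so the residual tracks the
  thermodynamic floor quasi-statically during the ramp (residual
  offset D·(S_feed − S)/(k_up·f·X) ≲ 1% of the floor over the fit
  window). No reported quantity depends on k_up once it is large.
* Pyruvate: absent from the feed; the mirrored reverse flux
  q_pyr = k_up·f(pH)·(c_in,pyr·10^(pH − pH_in) − S_pyr) drives the
  residual toward equilibrium from below.
* Ethanol: Monod uptake (q_max 12 mmol g⁻¹ h⁻¹, K 0.1 mM) supplying
  whatever growth the pH ceiling still allows after the
  lactate contribution.
* Growth: µ = min(µ_max(pH), Y_lac·max(q_lac,0) + Y_eth·q_eth), with
  µ_max(pH) = µ_ref/(1 + 10^(s·(pH − pH_crit))), µ_ref = 0.35 h⁻¹,
  pH_crit = 7.2, s = 12 — calibrated so the ceiling crosses
  D = 0.07 h⁻¹ just above pH 7.25, reproducing washout (declining
  biomass, rising residual ethanol) where the emulated cultures failed.
* Yields default to 0.6 g biomass per g substrate for both carbon
  sources (typical aerobic values; they shape only the synthetic data).

**Numerics.** LSODA via `scipy.solve_ivp` with max step 0.1 h,
rtol 10⁻¹⁰, atol 10⁻¹², initialised at the fixed-pH steady state
(obtained by a bracketing scalar solve on the residual lactate; at
µ = D the rest of the state follows in closed form). The noise-free
trace is a deterministic function of the configuration. Steady-state
substrate balances D·(S_feed − S) = q·X close to better than 10⁻⁶
(relative) at the integrator endpoint of a 300 h constant-pH run.

**Measurement noise.** Sampling emulates drawing culture samples at
programmed pH values: trace values are interpolated at the requested
pH and multiplied by mean-one lognormal noise with coefficient of
variation `noise_cv` (default 5%), drawn per replicate (default 2,
mirroring duplicate cultures) from a seeded generator.

**Problem sizes.** The recovery study uses one noise-free trace, 20
sampling points over pH 6.75–7.0 and 100 noise seeds at 5% CV —
enough to estimate the RMSE of the conditional estimators to a few
percent while keeping the whole study in seconds.

**Not modelled.** Intracellular metabolism and transcription,
byproducts other than pyruvate, adaptation over long runs, and any
feedback of internalization on the cytosolic pools (c_in is held
fixed by assumption, exactly as in the inference model).

## 4. Leakage mass balance (`symporteq.leakage`)

One gram of yeast biomass carries ≈ 2 mL of intracellular volume, so a
culture at X g/L has an intracellular volume fraction of
100·X·(2/1000) percent — 0.02% at 100 mg/L. At equilibrium the
extracellular concentration is c_in/10^ΔpH, and amounts follow from the
compartment volumes; the extracellular volume is approximated by the
full culture volume (error ≤ 0.02% in the reference scenario),
matching the source arithmetic; `exact_volume=True` subtracts the
intracellular volume instead. The pyruvate worked example uses the
printed round molar mass of 88 g/mol rather than 88.06 so the
reference numbers (0.2 µmol inside, 1 mmol / 88 mg / 88% of cell dry
mass outside) are reproduced exactly. ΔpH < 0 strictly increases the
extracellular share.

## 5. Imaging statistic and generator (`symporteq.imaging`)

**Statistic.** Per cell: IntDens(whole mask) − IntDens(interior mask)
is the plasma-membrane signal; the reported ratio divides by the
whole-cell IntDens and is clamped to [0, 1] after background
subtraction. The manual inner-ellipse placement of the original
procedure has no stated width, so the interior is defined
reproducibly as the whole-cell mask eroded by a disc of radius
`ring_width` (default 3 px, configurable). Background defaults to the
median intensity outside all cell masks, subtracted per pixel.
Vacuolar signal is counted in the total, as in the visual convention
the procedure follows. The quantifier is tested for exact agreement
with a brute-force per-pixel summation oracle, and for invariance to
global intensity scaling (at zero background) and to translation.

**Generator.** Cells are discs (radius 10–14 px by default) on a
jittered grid, which guarantees non-overlap and ≥ 2 px gaps by
construction; requesting more cells than grid sites raises
`PlacementError`. The membrane ring is defined as the disc minus its
binary erosion by the same structuring element the quantifier uses, so
the generator's region split is exactly the one the measurement
recovers. With `membrane_fraction` set, the ring intensity is solved
per cell so the ring carries exactly that fraction of the cell's
pre-noise integrated intensity (ground truth is exact by
construction). Defaults: interior 300, background 10, Gaussian noise
sd 6 (Poisson optional), 16-bit output range.

**Segmentation.** Median smoothing (radius 1; edge-preserving, so the
threshold boundary lands on the rasterised disc edge), a global robust
threshold (median + 5 scaled MADs), hole filling, small-object removal
and connected-component labelling. On generator defaults this recovers
every cell with mask Jaccard ≥ 0.8; across true membrane fractions
0.1–0.9 (300 cells each) the median recovered ratio is monotone and
within ±0.05 of truth (measured ≤ 0.013).

**Limitations.** The generator's geometry is circular — budding cells,
out-of-focus planes and uneven illumination are not emulated, so
passing recovery tests demonstrate correctness of the statistic and
pipeline, not segmentation accuracy on real micrographs. The reference
cohort values of the emulated study (0.51/0.42/0.30/0.18) depend on
unavailable raw images and are not reproduction targets; the synthetic
cohorts at matching fractions only demonstrate that the pipeline would
resolve differences of that size.

## 6. Reproducibility

Every CLI run writes a manifest (config echo, seed, package version,
config hash). `scripts/acceptance.py --seed N --out f.json` recomputes
all headline numbers from scratch; all stochastic draws descend from
the single `--seed`.
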