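# Methods

## The measurement model

An electrochemical impedance spectroscopy (EIS) sweep of a protein
suspension in a two-plate cell is summarized by the Randles equivalent
circuit

```
Z(ω) = Ru + [ Z_CPE(ω) ∥ (Rp + Z_W(ω)) ],      ∥ : parallel combination
```

with five parameters:

| parameter | meaning | units | typical range here |
|---|---|---|---|
| `Ru` | solution (uncompensated) resistance | Ω | 0.3–2.7 kΩ |
| `Y0` | CPE admittance coefficient | S·s^α | 1–14 µ |
| `α` | CPE exponent (1 = ideal capacitor) | — | 0.65–1.0 |
| `Wd` | semi-infinite Warburg coefficient, Z_W = Wd·(jω)^(−1/2) | Ω·s^(−1/2) | 20–35 µ |
| `Rp` | polarization / charge-transfer resistance | Ω | 24 Ω–24 kΩ |

The constant-phase element `Z_CPE = 1/(Y0·(jω)^α)` models the dispersive
double layer; the Warburg element adds the −45° diffusion tail.  The
published parameter table labels `Wd` in ohms, but its values (tens of
µ-units) are impossible for a pure resistance in circuits whose other
resistances are 10^1–10^4 Ω; we therefore read it as the coefficient of a
semi-infinite Warburg element (the common vendor convention), which also
reproduces the diffusion behavior the original analysis attributes to the
medium.  Likewise the table's "Alpha (F)" unit is treated as a typo —
α is dimensionless.  The circuit topology (Ru in series with the
CPE-parallel-faradaic branch) is the canonical Randles arrangement; the
original figure is not reproduced in text form, so the canonical topology
is a deliberate choice.

Sign conventions: e^{+jωt} time dependence, capacitive reactance negative,
Nyquist ordinate −Im(Z), complex powers on the principal branch.

## Fitting

`fit_randles` minimizes the weighted complex least-squares objective
Σᵢ wᵢ[(ZRᵢ−ẐRᵢ)² + (ZIMᵢ−ẐIMᵢ)²] with `scipy.optimize.least_squares`
(trust-region reflective).  Ru, Y0, Wd, Rp are fitted in log space
(positivity by construction, bounded to ±46 in the log to keep every
intermediate product finite); α is bounded on (0, 1].  The default
weighting is `modulus` (wᵢ = 1/|Zᵢ|²) because |Z| spans several decades
across a sweep and unit weights would let the low-frequency points dominate;
`unit` and `proportional` (each residual component scaled by its own data
component) are available.  Tolerances are ftol = xtol = gtol = 1e−15 with a
500-iteration cap; the solver is deterministic, and an optional multi-start
mode takes an explicit seed.

Two structural pathologies of this circuit needed dedicated handling:

* **Sub-noise additive terms.**  `Ru` and especially `Wd` can contribute as
  little as 1e−9 of |Z| (kΩ circuits with tens-of-µ Warburg coefficients).
  In log space the point `Wd → 0` is a flat valley in which the optimizer
  stalls while the other parameters absorb the difference.  After the first
  solve, the weighted *linear* problem `data − model ≈ J·[ΔRu, ΔWd]` is
  solved with the analytic sensitivities (∂Z/∂Ru = 1,
  ∂Z/∂Wd = (Z_CPE/(Z_CPE+Rp+Z_W))²·(jω)^(−1/2)) and the fit restarted from
  the corrected point.
* **The ideal-capacitor bound.**  When the true α is exactly 1, the solver
  can converge just inside the bound (α ≈ 1−2e−7) with the small terms
  collapsed.  If a fit ends with α > 0.95 at nonzero cost, a full second
  campaign is run from the α = 1 snap with the small terms re-estimated
  there, and the lower-cost result kept.

With both measures, all five parameters of every generating set in the
study ranges (including the blank row's milliohm Ru) are recovered from
noiseless spectra to ≲1e−6 relative — three orders tighter than the 0.1%
contract the tests assert.

The initial guess reads the spectrum's geometry: Ru from the
high-frequency real-axis intercept, Rp from the low-frequency span, Y0
from the −ZIM peak via ω_peak ≈ 1/(RpC), α = 0.8, Wd = 0.1·Rp·√ω_min.
Standard errors come from the Gauss–Newton curvature at the optimum
(delta method for the log-parameters); they are local approximations, not
profile likelihoods.

## From impedance to dielectric quantities

For a parallel-plate cell with gap L = 4.75 mm and plate area
A = 1.97 cm², the cell constant is κ = L/A = 24.11 m⁻¹ and
σ = κ/R.  The published conductivity column is reproduced **by the
polarization resistance Rp**, not by the solution resistance Ru that the
formula's prose names (κ/23.69 Ω = 1.02 S/m, the series' headline value,
and likewise all five other rows to 3 significant figures; Ru of the stock
row would give 77 mS/m instead of the printed 6.37 mS/m).  The pipeline
therefore defaults to `resistance_source: rp` and exposes `ru` as a
config switch, logging whichever was used, so the discrepancy stays visible
rather than silently resolved.

`permittivity_from_impedance` defaults to the exact admittance form for a
parallel-plate cell: Y = 1/Z, σ = Re(Y)·κ, ε′ = Im(Y)·κ/(ωε₀),
ε″ = σ/(ωε₀).  The component-wise approximation that reads ε′ from 1/Z_IM
and ε″ from 1/Z_R alone is kept as a `literal` comparison mode (with
ε₀ restored for dimensional consistency — the printed relations omit it);
points with zero reactance are flagged undefined rather than dropped.
The "cross-section area 1.97×10⁻⁴ m" of the cell table is read as m².

## Clausius–Mossotti factor and mixture model

The dielectrophoresis (DEP) direction of a small particle follows the sign
of Re[f_CM] with

```
f_CM = (εp* − εm*)/(εp* + 2εm*) = (Zm* − Zp*)/(Zm* + 2Zp*),
ε* = ε′ − jσ/(ωε₀),
```

the impedance form being the exact algebraic alias when Z = κ/(jωε₀ε*)
for a common cell (asserted to machine precision in the tests).  The dilute
suspension obeys the Maxwell–Wagner mixture relation
εmix* = εm*(1+2δf_CM)/(1−δf_CM) with volume fraction δ; its closed-form
inverse f_CM = (εmix*−εm*)/(δ(εmix*+2εm*)) round-trips to machine
precision.  δ is never stated for the protein suspensions, so inverting
measured mixture spectra requires δ as explicit user input.

`dep_response` evaluates Re[f_CM] point-wise on the grid, classifies each
point (|Re f_CM| < 1e−12 counts as zero force), and refines every sign
change by bisection on log-frequency with the two permittivity spectra
interpolated linearly against log f, to 1e−6 relative tolerance.  When the
zero-force point falls on a grid point (a run of below-threshold values),
the run's geometric-mean frequency is reported directly.  For homogeneous
lossy spheres the crossover has the closed form

```
ω_c² = (σm−σp)(σp+2σm) / [ε₀²(εp−εm)(εp+2εm)],
```

real only when the conductivity and permittivity contrasts have opposite
signs; the bisection solver is tested against it to 0.1% (measured
≈0.03% on 40 points/decade grids, dominated by the log-linear
interpolation of the 1/f loss term, not by the bisection itself).
The recommended operating band is the widest positive band in
log-frequency, ties broken toward lower frequency where electrothermal
stress is gentler.  Multiple crossovers are all reported.

## Synthetic data

No raw spectra are publicly available for the six-sample concentration
series (blank deionized water, then 218.34 nM protein stock halved to
109.15, 54.58, 27.29 and 13.64 nM — the printed dilution labels are kept
verbatim even though they are not exact halvings, and exact-halving
arithmetic lives separately in `serial_dilution`).  The generator
re-creates each sample as the exact Randles response of its published
parameter row on a log-spaced grid, default 0.1 Hz–1 MHz at 10
points/decade — inside the union of the two measurement ranges the
original report quotes and wide enough to expose both the charge-transfer
semicircle and the diffusion tail for every row.  Noise is proportional
and Gaussian, independently on the real and imaginary components
(|Z| spans decades, so additive noise would be meaningless at the
low-|Z| end), default 0.5% relative, seeded per sample.

The blank row's Ru = 1.228 mΩ is physically implausible for deionized
water but is reproduced verbatim (with a logged warning): the fixtures are
faithful to the printed table, not to physical plausibility.

What the generator does *not* emulate: instrument artifacts (inductive
wiring tails, drift), frequency-dependent protein dielectric dispersion,
and the time-domain square-wave excitation of the original instrument.
Passing the round-trip tests therefore shows the estimator is correct for
data that follow the assumed circuit and noise model; it does not validate
the circuit choice against real measurements.

## Problem sizes and numerical choices

The recovery studies use 50 random parameter sets (log-uniform in the
series ranges) for the noiseless contract and 20 seeds at 1% noise for the
Monte-Carlo contract — enough to exercise the whole range while keeping
the full suite and the acceptance script each well under a minute.
Degenerate inputs are rejected loudly: non-positive frequencies or
resistances, α outside (0, 1], volume fractions outside [0, 1) (and δ = 0
for inversion, where f_CM is unidentifiable), near-cancelling
Clausius–Mossotti denominators, spectra with fewer than two points.

## Known limitations

* Fixed topology: no model selection among alternative circuits, no
  Kramers–Kronig validity screening, no finite-length Warburg variants.
* The DEP prediction treats the particle as a homogeneous lossy sphere
  with the suspension's measured conductivity and a protein-like static
  permittivity; shelled-particle models and DEP force magnitudes
  (field-gradient modeling) are out of scope.
* Parameter uncertainties are local standard errors and are not propagated
  into the DEP prediction.
* The original study inferred positive DEP qualitatively from the position
  of Bode-plot traces; that reading has no quantitative counterpart, so
  this package computes Re[f_CM] from the dielectric model directly and
  makes no claim to reproduce the Bode-plot inference itself.
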