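# eisdep

Electrochemical impedance spectroscopy (EIS) analysis and
dielectrophoresis (DEP) response prediction for protein suspensions.

Measuring how strongly a suspended protein polarizes in an AC field — and
therefore whether it can be trapped by positive DEP and in which frequency
band — requires its dielectric properties, which are rarely tabulated for
individual proteins.  This package implements the analytical chain that
extracts them from an EIS sweep of the suspension in a two-plate cell:

1. **Equivalent-circuit fitting** (`eisdep.eis_fit`): weighted complex
   nonlinear least squares of the Randles circuit
   `Z(ω) = Ru + [Z_CPE ∥ (Rp + Z_W)]`, with a constant-phase element
   `Z_CPE = 1/(Y0(jω)^α)` and a semi-infinite Warburg element
   `Z_W = Wd(jω)^(−1/2)`.
2. **Conductivity from geometry** (`eisdep.dielectric`): `σ = κ/R` with
   cell constant `κ = L/A` of the parallel-plate cell.
3. **Complex permittivity** from the impedance via the cell admittance,
   `ε* = ε′ − jσ/(ωε₀)`.
4. **DEP prediction**: the Clausius–Mossotti factor
   `f_CM = (εp*−εm*)/(εp*+2εm*)`, the Maxwell–Wagner dilute-mixture
   relation `εmix* = εm*(1+2δf_CM)/(1−δf_CM)` and its inverse, sign bands
   and crossover frequencies of Re[f_CM], and a recommended operating band.

Because no raw spectra are publicly available for the Tau-441 protein
concentration series that motivates the defaults, `eisdep.synthetic_data`
regenerates the six-sample series (blank + 218.34 → 13.64 nM) from its
published fitted parameters, with seeded proportional noise.  See
`docs/methods.md` for the model, conventions, and limitations.

## Worked example

```python
from eisdep import (
    CellGeometry, conductivity_from_resistance,
    fit_randles, generate_table3_series,
)

geometry = CellGeometry(thickness=4.75e-3, area=1.97e-4)  # kappa = 24.11 1/m
_, spectra = generate_table3_series()  # noiseless; pass NoiseModel(...) for noise

for s in spectra:
    fit = fit_randles(s)                 # modulus-weighted complex NLLS
    sigma = conductivity_from_resistance(fit.params.r_p, geometry)
    print(f"{s.label:>10}: Rp = {fit.params.r_p:9.4g} ohm -> sigma = {sigma:.3g} S/m")
```

prints

```
     blank: Rp = 1.139e+04 ohm -> sigma = 0.00212 S/m
 218.34 nM: Rp =      3785 ohm -> sigma = 0.00637 S/m
 109.15 nM: Rp =      2925 ohm -> sigma = 0.00824 S/m
  54.58 nM: Rp =      4038 ohm -> sigma = 0.00597 S/m
  27.29 nM: Rp =      8381 ohm -> sigma = 0.00288 S/m
  13.64 nM: Rp =     23.69 ohm -> sigma = 1.02 S/m
```

— the published conductivity column of the series, recovered by refitting
regenerated spectra; the most dilute sample's 1.02 S/m is the peak value
used as the particle conductivity for the DEP prediction.  Note the
conductivities follow the *polarization* resistance Rp: the solution
resistance Ru, which the conductivity formula nominally names, does not
reproduce the published values (the pipeline exposes both via
`resistance_source`, see `docs/methods.md`).

Predicting the DEP band for that particle in deionized water:

```python
from eisdep import dep_response
from eisdep.dielectric import complex_permittivity
from eisdep.synthetic_data import log_frequency_grid

f = log_frequency_grid(1e3, 1e9, 20)
pred = dep_response(
    f,
    complex_permittivity(5.0, 1.02, f),      # protein-like particle
    complex_permittivity(78.4, 5.5e-6, f),   # deionized water
)
print(pred.recommended_band, pred.crossover_frequencies)
```

```
(1000.0, 168520787.73516217) [168520787.73516217]
```

positive DEP across the whole 1 kHz–1 MHz operating window, crossing over
to negative DEP only near 170 MHz.

## Command line

```sh
eisdep fixtures --out-dir spectra/          # emit the packaged series
eisdep fit spectra/218p34_nM.csv            # one fit, JSON output
eisdep conductivity --resistance 23.69 --thickness 4.75e-3 --area 1.97e-4
eisdep run --config config.yaml --report report.json --table report.txt spectra/*.csv
```

The `run` pipeline requires the fitting window in the config (the source
measurements quote two conflicting ranges, so there is deliberately no
default), isolates per-sample failures, and exits 0/2/1 for
success/partial/total failure.

## Analysis scripts

`analysis/01_simulate_series.py` … `04_dep_prediction.py` run the study
end-to-end — simulate the series, fit it, tabulate conductivities both
ways, predict the DEP band — writing tables under `results/`.

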