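# pdlvisco

Viscoelastic creep analysis of the human periodontal ligament (PDL),
built around a fiber-content-based constitutive model. The package is for
tissue-biomechanics researchers who run constant-load (creep)
nano-indentation on soft connective tissue and quantify collagen content
from Masson-trichrome histology: it ingests or synthesizes
time/load/depth records, fits the creep law to hold-stage strain curves,
extracts flat-punch reduced moduli from unloading branches, and measures
collagen area fractions over regions of interest.

## The model

The PDL is a standard linear solid: a collagen-fiber spring `E_tf` in
parallel with a Maxwell matrix branch (`E_m` in series with a dashpot
`η`). Its linear creep compliance is

    D(t) = 1/E_tf − [E_m/(E_tf(E_tf+E_m))]·e^(−t/τ₁),
    τ₁ = η(E_tf+E_m)/(E_tf·E_m)

Fiber-content effects enter through dimensionless Schapery-type factors
multiplying the equivalent Kelvin–Voigt compliance terms:

    ε(t) = g₀·D₀′·σ₀ − g₁·g₂·|D₁′|·(1 − e^(−t/τ₁))·σ₀

with `D₀′ = (2E_m+E_tf)/(E_tf(E_tf+E_m))`, `D₁′ = −E_m/(E_tf(E_tf+E_m))`.
A single hold-stage curve identifies exactly `(g₀, g₂, η)` once
`E_tf = E_m = σ₀ = 1` and `g₁ = 1` (full rebound) are fixed; the fit runs
in the equivalent `(A, B, τ)` space and maps back. For the flat
cylindrical indenter (R = 100 μm) the reduced modulus is `E* = S/(2R)`
with `S` the unloading stiffness. Collagen content is
`V_f (%) = collagen px / ROI px × 100`, averaged per region.
See `docs/methods.md` for assumptions, parameter units and defaults.

## Worked example

Fit the creep law to a synthetic hold-stage curve generated from a
published neck-region parameter set:

```python
from pdlvisco import (SLSParameters, SchaperyParameters,
                      SchaperyCreepModel, generate_hold_curve)

sch = SchaperyParameters(g0=0.0049, g1=1.0, g2=-0.0096)
sls = SLSParameters(Etf=1.0, Em=1.0, eta=260.8893)
curve = generate_hold_curve(sch, sls, sample_id="neck-1",
                            region="neck", plane="transverse")
print(SchaperyCreepModel(curve).fit().summary())
```

```
Schapery creep fit
==============================================
sample: neck-1  region: neck  plane: transverse
n = 201  hold span = 200.0 s
converged: True   nfev: 11   R^2: 1.000000
creep regime (B >= 0): True
----------------------------------------------
 param       estimate      std err
    g0         0.0049     8.46e-20
    g2        -0.0096     1.47e-17
   eta        260.889     4.88e-13
----------------------------------------------
reduced: A = 0.00735, B = 0.0048, tau = 521.779 s
```

The fit recovers the generating factors exactly: `g0` (instantaneous),
`g2` (transient, negative in the creep regime) and the matrix viscosity
`eta` (MPa·s), with `R² = 1` on the noiseless curve; `A`, `B`, `tau` are
the identifiable curve parameters (initial strain, creep amplitude,
retardation time).

The full pipeline — synthesize a study (30 indentation records, 15
stained sections), segment, fit, measure collagen, report — runs from the
shell:

```bash
pdlvisco run-all --seed 7 --out results/
pdlvisco generate --out study/ --seed 7
pdlvisco fit-creep --input curves.csv --out fits.csv
pdlvisco fiber-content --images study/images --out vf.csv
```

`results/` then holds `creep_parameters.csv` (per-sample g₀, g₂, η, R²),
`reduced_modulus.csv` (region × plane E*), `collagen_content.csv`
(region × slice V_f with means), averaged strain curves, and a
`report.json` manifest with the seed and config hash; reruns with the
same config are bit-identical.

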