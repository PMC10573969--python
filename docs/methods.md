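# Methods

## The constitutive model

The periodontal ligament (PDL) is modelled as a three-element standard
linear solid reflecting its microstructure: the collagen fiber bundles act
as a linear spring of modulus `Etf` (MPa) in parallel with the ground
matrix, itself a Maxwell element — a spring `Em` (MPa) in series with a
dashpot `eta` (MPa·s). Under a step stress `sigma0` the governing ODE

    deps/dt = Em (sigma0 − Etf·eps) / (eta (Em + Etf)),  eps(0) = sigma0/(Etf+Em)

has the closed-form creep compliance

    D(t) = 1/Etf − [Em/(Etf(Etf+Em))] · exp(−t/tau1),
    tau1 = eta (Etf + Em) / (Etf · Em)

with `D(0) = 1/(Etf+Em)` (both springs load instantaneously) and
`D(∞) = 1/Etf` (the matrix has fully relaxed). `tau1` is the retardation
time, the only timescale in the model.

To express collagen-fiber-content effects, the linear compliance is
re-parameterized as a first-order generalized Kelvin–Voigt model,

    D0' = (2Em + Etf)/(Etf(Etf+Em)),   D1' = −Em/(Etf(Etf+Em)),

which satisfies the exact identity `D0' + D1' = 1/Etf`, and each term is
multiplied by a dimensionless Schapery-type factor:

    eps(t) = g0·D0'·sigma0 − g1·g2·|D1'|·(1 − exp(−t/tau1))·sigma0

`g0` scales the instantaneous response, `g2` the transient (negative in
the creep regime so strain grows), and `g1` is the strain-recovery factor,
equal to 1 for tissue that rebounds fully on unloading — the convention
used for all fits here. A stress-dependent reduced-time exponent
(`alpha_sigma`) is exposed as a hook in `strain_response` but fixed at 1;
the fitted strain law contains no such exponent.

Two deliberate points about this law:

* `D0'` is **not** the SLS instantaneous compliance `1/(Etf+Em)`. The
  strain law is implemented with `D0'` as written above because the
  published fitted parameter sets presuppose that form; the linear SLS
  compliance `creep_compliance` is kept as a separate, self-consistent
  operation, and the test suite checks each against its own identities.
* With `g0 = g1 = 1, g2 = −1` the long-time strain
  `(3Em+Etf)/(Etf(Etf+Em))·sigma0` exceeds the linear equilibrium
  `sigma0/Etf`. That is a property of the law's sign structure, not a bug;
  it is asserted in a test so it cannot be "fixed" silently.

## Identifiability and the reduced parameterization

A single hold-stage curve determines exactly three quantities

    A = g0·D0'·sigma0,   B = −g1·g2·|D1'|·sigma0,   tau = tau1,

so `Etf`, `Em` and `sigma0` are not separately identifiable from one creep
test. The package therefore fixes the conventional normalization
`Etf = Em = 1 MPa, sigma0 = 1, g1 = 1` (the `FitContext`), under which the
map `(A, B, tau) -> (g0, g2, eta)` is a bijection; users with measured
moduli or stresses may supply their own context and the dimensionless
factors rescale accordingly (checked by test). Reported `g0`/`g2`/`eta`
values are comparable across samples only under a shared context.

## Fitting

`SchaperyCreepModel.fit` runs bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) in the well-conditioned
`(A, B, tau)` space, then maps back. Choices:

* initial guess `A = eps[0]`, `B = eps[-1] − eps[0]`, `tau = span/3`;
* `tau` bounded to `(0, 100×span]`; `A`, `B` unbounded so decreasing
  (non-creep) curves still fit — they are flagged via `creep_regime`,
  not rejected;
* tolerances `xtol = ftol = gtol = 1e-12`, at most 1000 function
  evaluations; non-convergence is reported in the result, never raised;
* `R²` is computed on the hold stage only (the loading phase is excluded
  by construction) and reported as undefined for a zero-range curve;
* standard errors come from the Gauss–Newton covariance at the optimum,
  scaled through the linear reduced-to-full map.

Resolvability: with a 200 s hold, `tau1` beyond roughly 5× the hold
duration is poorly constrained; the generator warns in that case. All
published parameter columns have `tau1 = 2·eta` between ~384 and ~741 s,
inside the resolvable band, and round-trip through the fit to better than
1e-6 relative error on the 201-point grid.

## Indentation analysis

The protocol is a 0.5 mN/s ramp to a 3 mN peak, a 200 s hold, then
unloading, with a flat cylindrical indenter of radius R = 100 μm.
Segmentation finds the first sample at ≥ 99% of peak load (1% tolerance),
takes the hold as the following 200 s, and the remainder as unload.
Hold-stage strain is depth divided by the local PDL thickness; by default
it keeps the loading-phase penetration (total depth over thickness), with
a hold-relative convention available. Replicate curves are averaged by
linear interpolation onto the first curve's grid without extrapolation.

Because the indenter is a flat punch, the contact area is constant and the
unloading analysis reduces to `E* = S/(2R)` with `S = dP/dh` the unloading
stiffness, estimated by a straight-line fit to the top 50% of the
unloading branch by load (fraction configurable). The published per-region
moduli (0.39–5.08 MPa) cannot be recomputed without the cadaveric
specimens and their unprinted thicknesses; the package instead verifies
the estimator by round-tripping synthetic elastic unloads across that
modulus range to within 1%.

## Collagen content

Masson trichrome renders collagen blue/green and muscle/cytoplasm red.
The default classifier keeps pixels with HSV hue in [0.45, 0.75] and
saturation ≥ 0.15 inside the ROI; the rule is configurable and recorded in
every report, since no reference thresholding settings exist to copy.
`Vf (%) = collagen px / ROI px × 100` is an exact integer ratio;
per-slice values are averaged per region. ROIs are 0-based half-open
rectangles or polygons. The published per-slice values serve as fixture
inputs for the averaging step (their means are reproduced exactly); they
are not segmentation ground truth, as the underlying slides were never
deposited.

## Synthetic data

The generator is the package's stand-in for the cadaveric study and uses
the study's own design as defaults: 3 root regions × 2 sampling planes ×
5 indentation points, 5 stained slices × 3 regions, 200 μm PDL thickness
(the protocol's minimum usable thickness), and the published per-region
creep parameters and per-slice collagen fractions as generating truths
(package convention: sample column 1 = transverse, 2 = longitudinal; the
source does not assert that mapping, so it is metadata only).

Records: the loading ramp uses the instantaneous strain term only
(quasi-static `g0·D0'·sigma(t)`), since only the hold stage is fitted; the
hold follows the full strain law, so noiseless hold strain equals the
constitutive response exactly; the optional unload is linear-elastic with
stiffness `2·E*·R`. Noise is i.i.d. Gaussian on depth (sd = `noise_sd` ×
thickness), with no drift term. Stained images are built by thresholding
an anisotropically smoothed Gaussian random field at the target-fraction
quantile, giving interwoven-bundle textures whose true mask hits the
target fraction to sub-pixel quantization; collagen is rendered in
Masson-blue hues, background in red, with mild RGB noise. Everything
derives from one integer seed through `numpy.random.SeedSequence`
spawning, so identical specs give identical bytes.

What passing tests on these data do and do not show: they demonstrate the
estimators are correct and well-conditioned under the model's own
assumptions (exponential creep, uncorrelated noise, clean two-class
staining). Real indentation data add drift, adhesion, machine compliance
and anisotropy, and real histology adds stain variability — none of which
the generator emulates; results on real tissue depend on those effects.

## Problem sizes

Default analysis sizes were chosen as the smallest that exercise every
code path at the study's own design scale: hold curves of 201 points over
200 s, noise studies of 200 replicates per parameter set, stained images
of 256² px in the pipeline (1024² in the round-trip checks), and the full
30-record / 15-image study in the end-to-end test.

## Known limitations

* Transverse isotropy only; no anisotropic or fluid–solid-coupled
  formulation, and no general (non-step) loading history.
* `Etf`, `Em`, `sigma0` are fixed by convention, not estimated; only
  `(A, B, tau)`-equivalent information is recoverable from one curve.
* Single-exponential transient (first-order Kelvin–Voigt); tissues with
  multiple retardation times will show structured residuals.
* The image classifier is a hue threshold, not a trained stain-separation
  model; heavily counterstained or faded slides need parameter changes.
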