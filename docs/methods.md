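# Methods

## Scope and model

`mipvolt` implements the computational chain used to characterize a
molecularly imprinted polypyrrole sensor for chlorferron: anodic-peak
extraction from voltammograms, electron-transfer mechanism inference,
binding-energy screening of candidate imprinting monomers, and analytical
method validation. Quantum chemistry (DFT/PM3) is consumed as energy tables,
never executed; no physical electrochemical simulation (diffusion equation,
Butler–Volmer kinetics) is performed anywhere — the synthetic-data generator
is deliberately phenomenological.

## Peak extraction

A straight baseline is fitted by least squares over a pre-peak window
(default: the first 20% of the sweep; any interval inside the trace may be
given) and subtracted. `Ep` is the potential of the maximum corrected
current on the raw grid — no resampling, and parabolic refinement exists but
is off by default so results are exactly reproducible from the grid. `Ip` is
that corrected maximum, and `Ep1/2` is the linear interpolation of the first
rising-flank crossing of `Ip/2`. A corrected maximum on the sweep boundary,
or a non-positive corrected maximum, is reported as "no peak" rather than a
value. The linear-baseline choice is the minimal defensible background
model; subtracting any linear function of potential leaves the extracted
peak unchanged (tested as an invariant).

## Mechanism relations

- **Proton coupling**: Ep is regressed on pH; |slope| ≥ 20 mV/pH flags
  proton participation. The threshold is permissive on purpose — a
  Nernstian one-proton/one-electron process gives ≈ 59 mV/pH, and anything
  above 20 mV/pH is chemically meaningful pH dependence.
- **Control regime**: the `log10(Ip)`–`log10(v)` exponent is classified with
  a ±0.05 band, inclusive toward the pure regimes: ≤ 0.55 diffusion,
  ≥ 0.95 adsorption, otherwise mixed. `Ip` against `sqrt(v)` is also fitted
  and reported as an auxiliary linearity diagnostic, but the operative
  classifier is the log-log exponent.
- **Laviron**: `αn = 2.303·R·T/(F·slope)` from the slope of Ep against
  `log10(v)`. Ep enters untransformed (the relation is linear in log v), with
  v in V/s — the unit choice moves only intercepts, never slopes.
  Constants: R = 8.314 J K⁻¹ mol⁻¹, F = 96,480 C mol⁻¹, T = 298 K by default
  (overridable). With the slope 0.1016 V/decade this evaluates to
  αn = 0.582; values near 0.57 in the literature for this system reflect
  intermediate rounding, and the package reports the unrounded 0.582.
  The standard rate constant k° and formal potential E° are not extracted
  from the intercept.
- **Half-peak width**: `α = 47.7 mV / (Ep − Ep1/2)` at 25 °C; α is computed
  from the peak measured closest to the reference scan rate (default
  0.1 V/s, the usual working condition).
- **Electron count**: `n = αn/α` with nearest-integer rounding, ties away
  from zero.

OLS is `scipy.stats.linregress` behind one `fit_linear` surface; a constant
response is handled by convention (slope 0, r² = 0), a constant predictor is
an error. Each fit carries its residual sd and slope standard error, from
which t-based confidence intervals are formed.

## Monomer screening

`ΔE = E(complex) − E(template) − ΣE(monomer)` is a pure difference: the
module is unit-agnostic and passes the input unit label through untouched
(the packaged table is labelled as printed in its source even though the
magnitudes are characteristic of hartree-scale totals; the ranking is
unaffected). The reader accepts a pre-summed monomer energy column or
several `e_monomer_*` columns summed on input. Ranking is ascending in ΔE;
ties are broken lexicographically with a warning, since they have no
physical basis. Stoichiometry selection is an argmin over supplied
complex-energy scores; the packaged ratio scan is synthetic (see
`mipvolt/data/__init__.py`) because no real PM3 energies were published.

## Validation statistics

- LOD = 3.3σ/S, LOQ = 10σ/S. The blank standard deviation is preferred when
  supplied; otherwise the calibration residual sd is used, and the source is
  recorded in the output. LOQ/LOD = 10/3.3 ≈ 3.03 by construction. With a
  noiseless calibration σ = 0 and both limits collapse to zero (the ratio is
  then undefined); absolute LOD values depend entirely on instrument noise
  and are therefore not meaningful targets for synthetic data.
- %RSD uses the sample standard deviation (n − 1); precision is summarised
  per level plus the median across levels. Levels with one replicate are
  skipped with a warning; a single-replicate recovery reports %RSD = 0.
- Interference percent change is unsigned (`100·|ΔI|/I_ref`), matching the
  convention of reporting positive percents for signal suppression. A
  consistency oracle back-derives the implied reference current per row of a
  printed interference table and checks all rows share one reference; rows
  deviating more than 2% are flagged, 5% is the consistency bound.
- Method comparison is plain OLS with the reference method (GC-MS) as the
  response; agreement means slope in [0.9, 1.1] with r² ≥ 0.99. Deming
  regression and Bland–Altman analysis are out of scope.

Display rounding (two decimals for percents, three significant figures for
LOD/LOQ) happens only at the report boundary; raw doubles are serialized.

## Synthetic-data generator

The generator emulates the empirical behaviour of the sensor, not its
physics. Peak placement composes the pH law (0.0567 V/pH), the scan-rate law
(0.1016 V/decade) and the power law for current (exponent 0.7677, log
intercept 1.5706 with Ip in µA and v in V/s at 50 µM) **additively around
the reference condition** pH 7, 0.1 V/s, Ep = 0.736 V — the laws' printed
intercepts are mutually inconsistent when extrapolated, so only slopes are
treated as load-bearing. The default calibration sensitivity
(≈ 0.1271 µA/µM) is derived from the power-law intercept at the reference
condition so that the configured laws are exactly self-consistent.

**Peak shape.** Each peak is a compactly supported smooth bump,
`exp(1 − 1/(1 − u²))`, with independent rising and falling width scales; the
rising-flank half-width (default 90 mV, giving α = 0.53) is a direct
parameter. Compact support makes the baseline window exactly peak-free, so
on noiseless traces baseline fitting, the grid argmax and the half-height
interpolation are all exact — the generator/analyzer closure holds to
machine precision, which is the central oracle of the test suite. A true
asymmetric Gaussian (`peak_shape="gaussian"`) is available when realistic
tails matter; closure is then only approximate. The potential grid
(2 mV step) is anchored at the law-predicted peak centre for the same
reason.

**Noise model**, chosen once as realistic instrument-scale values: 3%
relative peak-amplitude noise per trace/replicate (median %RSD of repeated
electrochemical measurements of this kind is around 3%), 2 mV Gaussian
jitter on the peak centre, 0.01 µA additive noise per current sample, 3%
day-to-day factor for inter-day precision, 0.2 µM scatter in the
reference-method comparison. Matrix effects default to 0.95 (plasma) and
0.96 (urine); interferent perturbations are linear in interferent
concentration with coefficients (µA/µM) fitted to reproduce published
interference magnitudes — both are labelled synthetic in every output.
Randomness uses NumPy's default PCG64 generator seeded with
`(root seed, per-table/per-trace offset)` so traces are decorrelated and
every dataset is byte-reproducible from the seed.

**What it does not emulate:** peak-shape distortion at high scan rate,
electrode fouling or drift between replicates, non-linear calibration
rolloff, correlated noise, cathodic sweeps (the modelled process is
irreversible and shows no return peak), or any matrix-dependent peak shift.
Passing tests therefore demonstrate correctness of the analysis chain under
the stated laws, not instrument-level realism.

## Problem sizes and numerical choices

Studies follow the published designs: pH grid 3–9 (7 traces), scan-rate grid
log-spaced 0.05–1.0 V/s (6 traces), calibration at 2–75 µM (7 levels × 3),
recovery at 25/40 µM × plasma/urine × 3 replicates, interferents at
10/50/100 µM, comparison at 25–85 µM (5 samples). Stochastic
coverage checks use 200 seeded replicates of the full mechanism study, which
runs in about a second. Reported fits keep raw doubles; classification
boundaries and rounding conventions are stated above; degenerate inputs
(constant predictor, boundary maxima, single replicates, σ = 0
calibrations) are handled explicitly rather than silently.

## Known limitations

- The mechanism chain assumes a single dominant anodic peak; there is no
  multi-peak deconvolution or cathodic handling.
- The printed pH law's optimum-current pH (7 in the body of the source
  characterization, 6 in its conclusions) is not modelled: generated peak
  current is pH-independent, as only the Ep–pH slope is load-bearing.
- Absolute LOD/LOQ from synthetic data reflect the configured noise, not any
  real instrument; only their ratio and scaling laws are meaningful.
- The Ep grid quantization (2 mV) adds a small uniform error component to
  noisy Ep estimates; confidence-interval coverage remains within its
  nominal band (checked empirically), but very small configured jitter would
  be quantization-dominated.
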