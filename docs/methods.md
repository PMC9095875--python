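# Methods

## Problem and data

The package correlates the equilibrium mole-fraction solubility y₂ of a
solid solute in supercritical CO₂ as a function of temperature T, pressure
P and solvent density ρ₁. The packaged dataset holds 24 measurements of
pantoprazole sodium sesquihydrate in ScCO₂ on a full 4 × 6 grid
(T ∈ {308, 318, 328, 338} K, P ∈ {12, 15, 18, 21, 24, 27} MPa), with y₂
between 0.0301×10⁻⁴ and 0.4634×10⁻⁴ and CO₂ densities taken from standard
reference tables at each state point. Units are fixed package-wide (K, MPa,
kg/m³, dimensionless y₂); each model converts internally to its own
convention, and fitted quality is provably invariant to those conventions
(tested). The dataset's uncertainty columns (standard deviation and
expanded uncertainty of y₂) are carried as data but never used in fitting;
all fits are to point values.

## The solid–liquid-equilibrium model

ScCO₂ is treated as an expanded liquid. Equating solute fugacities across
phases gives y₂ = (f₂ˢ/f₂ᴸ)/γ₂∞. With a constant heat-capacity difference
ΔCp between solid and (hypothetical) liquid solute,

    ln(f₂ˢ/f₂ᴸ) = ΔH₂ᵐ/(RT)·(T/Tm − 1) − ΔCp/R·[ln(T/Tm) − Tm(1/Tm − 1/T)]

For solutes whose melting enthalpy cannot be estimated (group-contribution
methods fail for sodium-containing molecules), the ΔH₂ᵐ term is replaced by
the empirical constant-entropy substitution with coefficient 6.54. That
substitution circulates in two sign variants, 6.54(1 − T/Tm) and
6.54(1 − Tm/T); both are implemented (`new_model`, `new_model_textual`),
default the former. Both collapse to a ratio of 1 at T = Tm, and the fitted
ΔCp absorbs much of the difference between them; on the packaged dataset
the 1 − Tm/T variant fits marginally better (AARD 19.7% vs 20.3%).

The activity coefficient comes from regular solution theory with
density-scaled solubility parameters, reduced via the solute molar volume
v₂:

    γ₂∞ = exp[(a₂₂ + a₁₁v₂ρ₁ − 2√(a₁₁a₂₂)·(v₂ρ₁)^½)/(RT)]

a₁₁ and a₂₂ (≥ 0) are solvent–solvent and solute–solute interaction
potentials. The model needs Tm (412 K here) and v₂ (2.8202×10⁻⁴ m³/mol,
a crystallographic group-contribution value taken as a constant) and has
three fitted parameters (ΔCp, a₁₁, a₂₂), fitted either globally or per
isotherm.

## Convention constants

Values not determined by the data, all configurable through
`SubstanceConstants`:

| constant | default | used by |
|---|---|---|
| CO₂ Tc, Pc, ρc | 304.13 K, 7.377 MPa, 467.6 kg/m³ | reduced-variable models |
| Bartle P_ref, ρ_ref | 0.1 MPa, 700 kg/m³ | `bartle` |
| standard-state fugacity f• | 0.1 MPa | `r_chrastil` |
| R | 8.314 J/(mol K) | all |

Rescaling any of these is compensated exactly by the affected parameter
(e.g. doubling ρc doubles the fitted A₂ and shifts A₀ by −ln 2), so AARD,
SSE and the enthalpy slopes do not depend on them; the test suite asserts
this both analytically and by refitting.

## Fitting

`fit_model` minimizes one of three objectives: `aard` (mean absolute
relative deviation of y₂ — the field's headline statistic, the default),
`sse_y` (squared error in mole-fraction space — the basis of the AICc
variance), or `sse_log_y`. Each of `n_starts` (default 64) starting points
drawn from a seeded scrambled-Halton sequence inside the parameter bounds
runs a bounded trust-region least-squares pass on the objective's residual
vector (`x_scale='jac'`, making the search covariant under diagonal
parameter rescaling) followed by a bounded Nelder–Mead polish of the scalar
objective (tolerance 10⁻¹⁰); the incumbent best is re-polished once at the
end, which helps escape the flat facets of the L1 surface. Halton points
are prefix-nested, so enlarging `n_starts` can only improve the result, and
everything is a pure function of (dataset, model, config, constants).

One deterministic "smart start" per model is prepended where the model
log-linearizes: exact OLS in ln-space for Chrastil-type, Bartle and
Alwi-Garlapati forms, in y-space for the Reddy-Garlapati polynomial, and a
relaxed linearization for the SLE model (OLS over the four regressors
{T·g(T), v₂ρ₁, √(v₂ρ₁), 1} with √(a₁₁a₂₂) freed, then projected back).
On noise-free synthetic data these starts make recovery exact to machine
precision for every model (tested).

The MT model is never iterated: it is linear in (H₀, H₁, H₂) in the space
T·ln(y₂P) = H₀ + H₁ρ₁ + H₂T and is fitted there by ordinary least squares,
the conventional route for this model; metrics are then computed after
inverting to y₂. Exponentials are clipped at ±700 (logged once) so
optimizers can traverse bad regions without overflow.

Default bounds are generous physical boxes (κ ∈ (1, 20), E₁ and F₁ in
(−20000, 0) K, G₁ ∈ (−30000, 0) K, interaction potentials in (0, 10⁹) with
log-uniform start sampling); `FitConfig.bounds` overrides them.

## Metrics and model selection

All residual statistics are computed in y₂-space. AICc uses the
maximum-likelihood variance σ² = SSE/n (not SSE/(n−Q)); with n = 24 and
Q = 3 or 6 this choice exactly reproduces the published model-comparison
table when the published SSE values are inserted (tested to ±0.05).
`rank_models` sorts ascending by AICc with ties broken by AARD then model
id. AICc needs n > Q + 1; smaller datasets are rejected.

## Thermodynamic derivations

ΔH_vap = −G₁R and ΔH_total = −E₁R (or −F₁R), reported in kJ/mol;
ΔH_solv = ΔH_total − ΔH_vap by construction (negative = exothermic). The
slopes come from the thermo pipeline's fits with the default AARD
objective. Crossover pressure: for each isotherm pair sharing the pressure
grid, ln y₂ is interpolated linearly in P and the intersection located;
ln-space interpolation was chosen because isotherms are near-exponential in
P (the choice moves the estimate by < 0.5 MPa on the packaged data). The
result reports all pairwise crossings, their mean and the bracketing grid
interval; absence of an ordering flip is a regular result, not an error.
On the packaged data all six pairs cross inside [15, 18] MPa with mean
16.6 MPa. The MT self-consistency transform returns (ρ₁, T·ln(y₂P) − H₂T)
pairs whose scatter about H₀ + H₁ρ₁ equals the MT fit residuals; residual
homogeneity across isotherms (Levene test) is the package's consistency
check.

## Synthetic data

`generate` draws y₂ from any registered model at known parameters on an
arbitrary (T, P, ρ₁) grid — default, the packaged 24-point grid, so
synthetic studies share the real design. Default noise is multiplicative
lognormal at 2% relative, reflecting the < 5% relative standard uncertainty
typical of loop-sampling solubility measurements; additive Gaussian noise
(with truncation and a log message on non-positive draws) is available.
What the generator emulates is the point-scatter of a well-behaved
measurement chain; it does not emulate systematic density-table error,
equilibration failure, or the sharp isotherm kink the real dataset shows
near 15–18 MPa — so a model's ability to recover its own synthetic data
(which the tests verify to ≤ 2% AARD at 1% noise) says nothing about its
adequacy for real data with structure the model cannot express.

## Known limitations

* The published study this dataset comes from reports statistics this
  pipeline cannot reproduce from the printed data: its AARD values lie
  below the global minima attainable by the stated formulas for five of the
  eight models (verified by differential-evolution search), its printed SSE
  column exceeds the dataset's total sum of squares (inconsistent with its
  own R² values by a factor ≈ 100), and its printed constants do not
  reproduce the printed solubilities under any unit convention. The
  package therefore reports honestly recomputed values; where they differ
  from the printed ones, the recomputed fits have strictly better objective
  values on the printed data.
* Fits are point estimates; no parameter uncertainty is computed.
* No equation-of-state route: the solute's critical properties are not
  estimable (sodium-containing molecule), which is precisely the regime the
  SLE/regular-solution model targets.
* The density provider is the dataset itself; densities are taken as given
  rather than recomputed from an equation of state.
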