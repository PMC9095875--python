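# sccosol

Correlation of solid-drug solubility in supercritical CO₂.

Supercritical CO₂ (ScCO₂) is a tunable solvent used to micronize poorly
soluble drugs; designing such a process needs the equilibrium mole-fraction
solubility y₂(T, P) of the solid in the fluid, which is measured at only a
handful of state points and interpolated with semi-empirical correlations.
`sccosol` fits eight such correlations to isothermal (T, P, ρ₁, y₂) data,
ranks them statistically, and extracts the enthalpies implied by their
temperature slopes. It ships a 24-point dataset for pantoprazole sodium
sesquihydrate in ScCO₂ (308–338 K, 12–27 MPa) as a built-in fixture.

## Models

With T in K, P in MPa, ρ₁ the CO₂ density in kg/m³, and θ the fitted
constants:

| id | form | θ |
|---|---|---|
| `new_model` | y₂ = (f₂ˢ/f₂ᴸ)/γ₂∞ — solid–liquid equilibrium with ScCO₂ treated as an expanded liquid; γ₂∞ from regular solution theory with density-scaled solubility parameters | ΔCp, a₁₁, a₂₂ |
| `alwi_garlapati` | y₂ = exp(A₀ + A₁/Tr + A₂ρr)/(ρr·Tr) | A₀–A₂ |
| `sodeifian` | ln y₂ = B₀ + B₁P²/T + B₂ln(ρ₁T) + B₃ρ₁ln ρ₁ + B₄P ln T + B₅ln(ρ₁)/T | B₀–B₅ |
| `reddy_garlapati` | y₂ = (D₀ + D₁Pr + D₂Pr²)Tr² + (D₃ + D₄Pr + D₅Pr²) | D₀–D₅ |
| `chrastil` | y₂ = x/(1+x), x = ρ₁^(κ−1)exp(E₀ + E₁/T) | κ, E₀, E₁ |
| `r_chrastil` | y₂ = (RTρ₁/M f•)^(κ′−1)exp(F₀ + F₁/T) (dimensionless base) | κ′, F₀, F₁ |
| `bartle` | ln(y₂P/P_ref) = G₀ + G₁/T + G₂(ρ₁ − ρ_ref) | G₀–G₂ |
| `mt` | T ln(y₂P) − H₂T = H₀ + H₁ρ₁ (Mendez-Santiago–Teja) | H₀–H₂ |

Fits are multi-start bounded nonlinear regression (seeded, deterministic);
the MT model is fitted exactly by linear least squares in its transformed
space. Fit quality is reported as AARD% = 100/n·Σ|y₂ᶜᵃˡᶜ−y₂ᵉˣᵖ|/y₂ᵉˣᵖ, SSE,
RMSE, R², R²adj, and models are ranked by the corrected Akaike criterion
AICc = n·ln(SSE/n) + 2Q + 2Q(Q+1)/(n−Q−1).

The 1/T slopes carry thermodynamics: ΔH_vap = −G₁R (Bartle),
ΔH_total = −E₁R (Chrastil), and ΔH_solvation = ΔH_total − ΔH_vap.

## Worked example

```sh
$ sccosol thermo --starts 16 --seed 1
chrastil_bartle:
  total_kJ_mol: 56.345
  vaporization_kJ_mol: 75.937
  solvation_kJ_mol: -19.592
r_chrastil_bartle:
  total_kJ_mol: 38.992
  vaporization_kJ_mol: 75.937
  solvation_kJ_mol: -36.945
crossover:
  found: true
  estimate_MPa: 16.64
  bracket_MPa:
  - 15.0
  - 18.0
```

Reading this: the Bartle fit's 1/T slope gives a vaporization enthalpy of
75.9 kJ/mol; the Chrastil fit's slope gives a total (vaporization +
solvation) heat of 56.3 kJ/mol; their difference, −19.6 kJ/mol, is the
exothermic solvation enthalpy of the drug in ScCO₂. The solubility
isotherms cross at ≈16.6 MPa (between the 15 and 18 MPa grid lines): below
that pressure solubility falls with temperature because the density effect
dominates, above it the sublimation-pressure effect wins.

```sh
$ sccosol compare --models chrastil,bartle,mt,alwi_garlapati --starts 16 --seed 1
model=alwi_garlapati  aard_percent=19.91  sse=8.703468e-11  ...  aicc=-625.03
model=bartle          aard_percent=20.10  sse=9.262090e-11  ...  aicc=-623.53
model=chrastil        aard_percent=21.02  sse=9.778906e-11  ...  aicc=-622.23
model=mt              aard_percent=20.70  sse=3.115851e-10  ...  aicc=-594.42
```

`compare` fits each model by least squares in mole-fraction space and ranks
by AICc (lower is better); here the Alwi-Garlapati reduced-density model
correlates this dataset best per parameter spent.

Other commands: `sccosol fit --model chrastil` (single fit, YAML report,
`--per-isotherm` for temperature-dependent constants) and
`sccosol simulate` (synthetic noisy datasets for recovery studies). All of
this is also available as a library — see `sccosol.fit_model`,
`sccosol.compute_metrics`, `sccosol.enthalpy_report`,
`sccosol.crossover_pressure`, `sccosol.recovery_study`.

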