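# Methods

## Scope and data model

The package correlates isothermal solid-solubility data in a supercritical
solvent. A dataset is an ordered set of records (T [K], P [bar],
ρ₁ [kg·m⁻³], y₂ [–], optionally S [g/L]) grouped into isotherms with
strictly increasing pressure and density, together with solute constants
(molecular weight; fusion enthalpy and melting point when the
expanded-liquid model is used) and solvent constants (molecular weight and
critical point). Densities are inputs, read from the dataset — the package
deliberately contains no equation of state; reduced variables are formed
with the solvent's critical constants (for CO₂: T_c = 304.13 K,
P_c = 73.8 bar, ρ_c = 467.6 kg·m⁻³, NIST values). The gas constant is
R = 8.314 J·mol⁻¹·K⁻¹ throughout. Pressure is stored in bar; the MST model
converts to MPa internally at its own boundary, and the Bartle reference
state is P_ref = 1 bar, ρ_ref = 700 kg·m⁻³. Mole fractions are stored as
plain numbers (never a ×10⁵ display scale), which removes an entire class
of scale bugs; the bundled HCQS table applies its display factor exactly
once, at construction.

The bundled reference system, hydroxychloroquine sulfate in scCO₂, uses
M_s = 434 g/mol, ΔH_m = 65 208 J/mol (group-contribution estimate),
T_m = 513.15 K (240 °C from the MSDS) and v₂ = 3.306·10⁻⁴ m³/mol; these are
fixture constants, not estimated by the package.

## Measurement conversions

For static sampling with loop volume V₁ (default 600 µL) and vial volume
V_s (default 5 mL), the vial assay concentration C_s (g/L) converts to
moles of drug C_s·V_s/M_s and moles of solvent V₁ρ₁/M (ρ₁ in kg·m⁻³ equals
g/L identically, so no unit factor appears — documented to prevent a double
conversion), whence y₂ as the mole ratio and S = C_s·V_s/V₁ as the g/L
solubility. The exact algebraic bridge S = ρ₁(M_s/M)·y₂/(1−y₂) and its
inverse are used for cross-validation: every stored record must satisfy it
within 1.5 % (rounding of tabulated values). Absorbance-to-concentration
calibration is instrument-specific and out of scope.

## Fitting procedure

All models sit behind one contract, `predict(params, T, P, ρ₁, solute,
solvent) → y₂`, addressable by name in a registry. Fitting minimizes, by
default, the **sum of squared relative deviations**

    L(θ) = Σᵢ ((y₂ᵢᵉˣᵖ − y₂ᵢᶜᵃˡᶜ(θ)) / y₂ᵢᵉˣᵖ)²,

the smooth counterpart of the absolute-relative-deviation sum that the
field quotes as AARD%. Relative (not absolute) residuals are essential:
solubilities span a decade and a half, and absolute least squares would fit
only the hottest isotherm. The squared form is the package default because
it is differentiable at the optimum and therefore identifies stable, sharply
defined constants; the L1 form (`loss="absolute_relative"`) is available
but its optima on flat valleys (e.g. the Chrastil κ direction) are poorly
pinned — on the reference data its κ wanders between 3.5 and 5.5 within
0.3 % of the objective. AARD% is always reported as
(100/N)·Σ|rel. dev.| evaluated at the fitted constants, so
`aard_pct = 100 · objective / N` holds exactly.

Predictions that are non-finite or ≤ 0 (possible for the polynomial
surfaces) contribute a fixed penalty of 10³ per point — large but finite,
steering the simplex away without a discontinuity at the feasibility
boundary.

The optimizer is derivative-free multistart: a Latin-hypercube sample of
`n_restarts` (default 50) points inside the model's search box is screened
by objective value; Nelder–Mead descent (adaptive simplex, budget 400·d
evaluations) runs from the best 12 screened points plus an analytic warm
start; the incumbent is then polished three times at tight tolerance
(600·d evaluations, xatol 10⁻¹³). Everything is deterministic given the
seed, and the same seed reproduces a fit bitwise. Warm starts are
linearized least-squares solutions — log-space regressions for the
Chrastil, Bartle, MST and solvate families (the density exponent enters as
slope + 1), and relative-weighted linear least squares for the two models
that are linear in their parameters (Reddy–Garlapati, Sodeifian), for which
that seed is already the exact global optimum of the default loss. Warm
starts are clipped into the search box. Search boxes are physically
motivated: association numbers in (0.5, 12], temperature constants
|B| ≤ 5·10⁴ K, solvate density coefficient |M| ≤ 0.05 m³/kg, etc.; they can
be overridden per call or from the CLI's YAML config.

## Statistics and model selection

From the absolute residuals at the optimum: SSE = Σ(y₂ᵉˣᵖ−y₂ᶜᵃˡᶜ)²,
RMSE = √(SSE/N), R² against the mean-only model, adjusted
R²_adj = 1 − (1−R²)(N−1)/(N−Q−1), and

    AIC  = N ln(SSE/N) + 2Q,       AICc = AIC + 2Q(Q+1)/(N−Q−1),

with Q the number of fitted constants (3 for the classic density laws, 4–6
for the solvate family and the six-constant surfaces, 4 for SLE–Wilson).
This AIC base formula is the least-squares log-likelihood form; it
reproduces the reference study's printed AIC values from its printed SSE
exactly, which fixes the convention. AICc (appropriate for N < 40) ranks
the models; ties break toward fewer parameters, then name. A perfect fit
(SSE = 0, possible on noiseless synthetic data) maps to AIC = −∞, the
natural limit. SSE/RMSE are computed on absolute residuals of y₂ — the
selection criteria and the fitting loss intentionally differ, as they do in
the source analyses.

Enthalpies come from the van 't Hoff-type temperature constants:
ΔH_total = −B₁R (Chrastil) and −B₂R (reformulated), ΔH_sub = −B₄R
(Bartle), ΔH_solv = ΔH_total − ΔH_sub by construction. The MST
self-consistency diagnostic transforms every record to
T ln(y₂P) − C₃T and regresses against ρ₁: data coherent across isotherms
collapse onto a single line of slope ≈ B₃; for data generated exactly from
the MST form the collapse is exact (R² = 1).

## Synthetic data

`simulate_dataset` draws y₂ᵢ = model(θ, conditionᵢ)·exp(εᵢ) with
εᵢ ~ N(−cv²/2, cv) i.i.d. — multiplicative lognormal noise, because
solubility spans a decade and replicate scatter in static measurements is
reported as relative SD (typically ≤ 6 %; the default cv = 0.05 mirrors
that). The −cv²/2 mean correction makes E[y₂ᵒᵇˢ] equal the model value, so
recovery experiments probe estimator bias, not noise-model bias. The
default grid is the 24 reference conditions, so synthetic experiments share
the leverage structure of the real design. What the generator does **not**
emulate: the assay chain (loop volumes, absorbance), temperature/pressure
setpoint error, inter-isotherm drift, or correlated errors — passing
recovery tests therefore demonstrate estimator correctness under clean
multiplicative noise, not robustness to instrument systematics.
`selection_experiment` wraps the loop "simulate → fit candidates → record
the AICc winner" and reports win frequencies.

## Estimator precision on the reference grid

Zero-noise recovery is exact (to four significant digits and better) for
every registered model — all parameter sets are identifiable from the
24-point design. At 5 % noise the sampling precision differs sharply by
parameter, and the test suite asserts tolerances matched to it: Chrastil κ
is recovered with |bias| < 0.05 (50 replicates) and the median of 20
replicates lands within 5 % for the well-identified constants, while two
weakly identified directions get wider, pre-computed bands — the solvate
density coefficient M (per-replicate SD ≈ 26 % of its value, unbiased;
median tested at 20 %, ≈ 3 Monte-Carlo standard errors) and the Wilson
energy λ′₁₂ (dispersion ≈ 25 %, trading off against the molar-volume
constants over the narrow T_r range 1.01–1.11; 9-replicate median tested at
25 %). Holding those to 5 % would make the tests a coin flip on seed
choice rather than a check of the code.

## Numerical choices and degenerate inputs

* exp() arguments are guarded at 700; beyond that the model raises a
  diagnostic error (direct evaluation) or the point is penalized (fitting).
* Datasets are validated on load: supercritical state, y₂ ∈ (0, 1),
  monotone density within isotherms, y₂↔S consistency; violations name the
  offending row. Schema and parse errors name the column and cell.
* The Wilson model raises a domain error naming the condition when the
  molar-volume correlation αρ_r + β is non-positive.
* `rank_models` refuses to mix fits of different datasets (compared by
  their stored experimental vectors).
* AICc requires N > Q + 1 and says so.

## Known limitations

* No equation-of-state route (solute critical properties are typically
  unavailable for salts like HCQS — the reason expanded-liquid and
  empirical routes exist) and no density lookup; users supply ρ₁.
* The uncertainty column of the reference table is not used as regression
  weights, matching the source analysis; weighted fitting would be a
  one-line extension of the loss.
* No bootstrap confidence intervals on fitted constants.
* The solvate-complex constants L, M, N are treated as free constants; no
  attempt is made to decompose them into sublimation pressure, solvation
  enthalpy and fugacity-coefficient factors, which are not separately
  identifiable from solubility data alone.
* On the reference dataset the fully converged optimum of the two
  six-constant linear-in-parameters surfaces (Reddy–Garlapati, Sodeifian)
  is markedly better than the historically quoted fits of the same forms
  (e.g. Reddy–Garlapati AARD 6.35 % here; the corresponding
  squared-relative-loss problem is convex, so this optimum is unique);
  comparisons against older reported constants for those two models should
  therefore use fit quality, not constant-by-constant agreement.
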