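# Methods

## Scope and model

`soluthermo` analyses temperature-dependent saturation solubility of a
crystalline drug in water and in micellar surfactant solutions. The package
ships a worked dataset: mole-fraction solubility of simvastatin
(M = 418.57 g/mol) in water and in 1/5/10/20 mM aqueous solutions of six
non-ionic surfactants (Tween-80/20, Myrj-52/59, Brij-35/58), measured in
triplicate by the saturation shake-flask method at 300.2, 310.2 and
320.2 K, printed to 3 significant digits.

Four pieces of physics are implemented:

1. **Temperature correlation.** Two standard models of ln x versus T:

   - van't Hoff: `ln x = a + b/T` (b in kelvin);
   - Apelblat:   `ln x = A + B/T + C ln T`.

   Both are linear in their parameters in ln space and are fitted by
   ordinary unweighted least squares on ln x_e. The Apelblat model is often
   described as requiring nonlinear regression; written in ln space it does
   not, and the linear solve is deterministic and exactly reproduces what a
   converged nonlinear fit would find. Fitting in ln space (not x space) is
   the choice that reproduces the published goodness-of-fit numbers of the
   worked dataset, and is physically natural since measurement error on
   solubility is multiplicative.

2. **Apparent dissolution thermodynamics.** Following the Krug treatment,
   ln x_e is regressed on u = (1/T − 1/T_hm), where
   T_hm = n / Σ(1/T_i) is the mean harmonic temperature of the study
   (309.985 K for the worked design; the source analysis prints 309.98).
   Then

   - Δ_sol H⁰ = −R · slope,
   - Δ_sol G⁰ = −R · T_hm · intercept,
   - Δ_sol S⁰ = (Δ_sol H⁰ − Δ_sol G⁰) / T_hm,

   with R = 8.314 J/(mol K). The entropy is defined by the difference form
   so the Gibbs identity ΔG = ΔH − T_hm·ΔS holds exactly by construction;
   the algebraically equivalent route ΔS = R·a is used as a cross-check
   property in the tests. Because the u-regression is an affine
   reparameterization of the plain 1/T regression, `apparent_thermodynamics`
   and `thermo_from_vant_hoff` agree to rounding error; both are exposed.
   T_hm defaults to the harmonic mean of the dataset's temperatures, with an
   explicit override for replaying a stated reference value. Units follow
   field convention: kJ/mol for H and G, J/(mol K) for S.

3. **Ideal solubility.** From fusion calorimetry,

   ln x_idl = −ΔH_fus(T_fus−T)/(R·T_fus·T) + (ΔC_p/R)[(T_fus−T)/T + ln(T/T_fus)],

   valid for 0 < T ≤ T_fus, with x_idl(T_fus) = 1 exactly. When ΔC_p is not
   measured it defaults to the fusion entropy ΔS_fus = ΔH_fus/T_fus — the
   common substitution, and the one that reproduces the worked dataset's
   ideal-solubility row (ΔC_p = 68.72 J/(mol K) for simvastatin). Config
   accepts enthalpy in kJ/mol or J/mol; kJ input is converted once and
   logged.

4. **Solubilization and polarity.** The molar solubilization capacity
   S_c = (S_t − S_w)/(C_s − CMC) × 1000 (mM per M of micellized
   surfactant) requires the surfactant's critical micelle concentration;
   CMCs are deliberately *not* defaulted silently — a CMC of 0 is accepted
   but logged as a warning, since it counts all surfactant as micellized.
   Drug solubilities may be given in mol/L or as mole fractions, converted
   with the dilute-limit factor 55.49 mol/L (the molarity of water). Hansen
   solubility parameters are combined Euclidean-wise,
   δ² = δd² + δp² + δh²; `hansen_table_check` recomputes totals of an input
   table and flags rows whose stated total deviates by more than a relative
   tolerance (default 2 %, loose enough for 1-d.p. rounding, tight enough to
   catch inconsistent rows — in the packaged table exactly the solute row,
   whose stated components cannot produce its stated total).

## Goodness of fit

R² is computed on ln-space residuals; RMSD% is computed on back-transformed
solubilities as 100·sqrt(mean(((x_fit − x_e)/x_e)²)). The "overall RMSD" of
a table of fits is the arithmetic mean of per-sample RMSD% values. This
combination reproduces the published per-sample values of the worked
dataset. With exactly 3 points, a 3-parameter Apelblat fit is interpolatory
and its RMSD is 0 by construction; published nonzero 3-point Apelblat RMSDs
therefore imply unrounded or additional data and the packaged Apelblat
parameters are not comparable against them.

## Composition conversions

Mole fraction from dissolved masses is x = (m1/M1)/(m1/M1 + m2/M2). For
micellar media the single-solvent denominator is ambiguous; the package
supports both the "aqueous" convention (surfactant mass folded into the
water term — the default, matching how the worked dataset was reduced) and
a two-component convention counting water and surfactant moles separately
(`mole_fraction_two_component`). At ≤20 mM surfactant the two differ by
under 2 %. Concentration conversions (μg/mL ↔ x) assume solution density
equals solvent density, the dilute approximation; no activity or density
models are applied.

## Synthetic data generator

`SyntheticSpec`/`generate_curve` emulate the shake-flask design: 3
temperature levels at 300.2/310.2/320.2 K, triplicate replicates, and
multiplicative lognormal measurement noise — additive Gaussian noise of
standard deviation `noise_sd_ln` on ln x, default 0.014, the reported
relative standard uncertainty of the worked dataset's solubilities.
Replicates are averaged arithmetically on the x scale, exactly as replicate
rows are reduced on file input. One integer seed controls all randomness.

What the generator does *not* emulate: equilibration kinetics, assay
calibration error, temperature-control error, or error on the surfactant
concentration. Passing recovery tests therefore demonstrate the estimator
chain (fit → thermodynamics) is correct and well-calibrated under the
stated noise model, not that real shake-flask data meet that model.

`recovery_study` repeats generate → fit → thermodynamics and reports bias,
RMSE and spread of (a, b, ΔH, ΔG, ΔS) against truth. With single
replicates the spread of the fitted slope has the closed form
sd(b̂) = σ/sqrt(Σ(u_i−ū)²), u = 1/T, which the tests verify at 2000
replications (seconds of runtime); with m replicates averaged on the x
scale the effective ln-noise is ≈ σ/√m for small σ.

## Numerical choices

- Least squares is solved via `numpy.linalg.lstsq` (orthogonal
  factorization), not the normal equations; with regressors {1, 1/T, ln T}
  over a 20 K span the design is highly collinear (condition number of the
  column-scaled design ~1e5–1e8), and a `ConditioningWarning` fires above
  1e10. Rank-deficient designs raise.
- R is fixed at 8.314 J/(mol K) — the rounding used in the source
  analyses this package reproduces; using 8.31446 shifts derived
  thermodynamic values in the 4th digit.
- Temperatures are kelvin-only; values below 200 K are rejected as probable
  Celsius input rather than silently converted.
- Replicate rows sharing (sample, T) are averaged arithmetically before
  fitting; the count is logged.
- Results are written with 12 significant digits; write → read round-trips
  are lossless at that precision.
- Extrapolation outside a fit's temperature range is allowed but emits an
  `ExtrapolationWarning` (the worked dataset's 298.2 K water solubility is
  exactly such an extrapolation).

## Known limitations

- The entropy sign of near-athermal samples is not resolvable from 3-digit
  input data: in the packaged dataset the 5 mM Tween-20 refit gives
  Δ_sol S⁰ = −0.03 J/(mol K) where the unrounded analysis reports +0.39.
  The package reports what the data give; the classification flag for that
  sample differs from the published one.
- Solubilization capacities depend on CMCs the user must supply; without
  them the capacity is a lower bound.
- No activity-coefficient corrections, no enthalpy–entropy compensation
  analysis, no additional correlation models (Buchowski–Ksiazczak, NRTL,
  Wilson), no weighted or robust regression.
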