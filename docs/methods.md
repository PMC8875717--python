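# Methods

This note records the modelling conventions, numerical choices and known
limitations behind `terpsol`.  It is the package's own account of its
science; every number quoted here is recomputed by the test suite or the
acceptance script.

## System and data

The solute is dehydroabietic acid, a tricyclic aromatic diterpenoid
resin acid (C20H28O2, M = 300.442 g/mol).  Its solid-state constants are
the DSC onset melting temperature Tm = 443.22 K and fusion enthalpy
Δ_fus_H = 17.19 kJ/mol.  A second literature-adjacent value of
19.17 kJ/mol circulates for the same compound; the package default is
the DSC value, and `SoluteProperties` accepts any override.  Solvent
molar masses come from molecular formulas ((−)-α-pinene 136.234,
p-cymene 134.218, (−)-β-caryophyllene 204.351 g/mol).

The built-in data are 99 equilibrium records at 101.3 kPa: three
monosolvent and three equal-mass binary datasets of 12 temperatures each
(~295–340 K), plus three 9-point composition scans in which the mass
fraction w₁ of the first solvent ranges over 0.1–0.9.  The reported
relative standard uncertainty of the measurements is u_r(x) = 0.01.

## Solubility models and the SLE closure

The Apelblat, λh and van't Hoff models map T to x directly.  The λh
relation is evaluated through its exact algebraic inversion
x = λ/(exp(λh(1/T − 1/Tm)) − 1 + λ); a property test confirms the
round-trip to 10⁻¹² against the defining logarithmic form, and a Brent
root-finder oracle confirms the closed form numerically.

NRTL and UNIQUAC model the solute activity coefficient γ₁(x, T) of a
solute(1)/solvent(2) binary.  Neither model alone predicts solubility;
the package closes them with the simplified Schröder–van Laar relation

    ln(x·γ₁(x, T)) = −(Δ_fus_H/R)(1/T − 1/Tm),   R = 8.314 J/(mol·K),

neglecting the heat-capacity difference between subcooled liquid and
solid — consistent with ignoring ΔCp everywhere else in the analysis.
The equation is solved by a damped fixed-point iteration
x ← ½(x + x_ideal/γ₁(x)) from x_ideal, tolerance 10⁻¹⁰ on successive
iterates, at most 500 sweeps; a bisection oracle agrees to 10⁻⁸ across
random NRTL parameter draws.  The NRTL non-randomness factor is fixed at
α = 0.3.  Binary mixed solvents are treated as a single pseudo-component
(the 2-parameter models are fitted to binary-solvent data unchanged);
a ternary formulation is out of scope.

UNIQUAC needs pure-component structural parameters r (volume) and
q (surface).  These are assembled from standard UNIFAC first-order
subgroup constants via r = Σν·R_i, q = Σν·Q_i with the shipped group
assignments (e.g. the solute is 4 CH3 + 5 CH2 + 2 CH + 2 C + COOH +
3 ACH + 3 AC; a textbook check: n-hexane gives r = 4.4998, q = 3.856).
The coordination number is z = 10.  Because the source analysis never
printed its r/q, fit quality — not specific r/q values — is the
reproducibility surface for UNIQUAC.

Both activity models satisfy a central-difference Gibbs–Duhem check
x₁ d ln γ₁/dx₁ + x₂ d ln γ₂/dx₁ = 0 to 10⁻⁵ at interior compositions,
and the NRTL γ's are verified against numerical differentiation of the
excess-Gibbs-energy expression.

## Fitting objectives

Deviation metrics (RD, ARD, RMSD, RSS) are always computed in
mole-fraction space.  The fitting objective, however, is model-specific:

- **Apelblat, van't Hoff: ordinary least squares on ln x.**  These models
  are linear in their parameters after the log transform, and ln-OLS is
  what demonstrably generated the published reference values shipped
  with the data: it reproduces the tabulated Apelblat parameters to all
  printed digits (α-pinene: A = −48.47524, B = 521.07863, C = 7.78171)
  and the deviation metrics (100ARD = 0.29696, 10³RMSD = 0.49178),
  whereas the x-space optimum gives a slightly different curve
  (100ARD = 0.2897).  The same holds exactly for the van't Hoff tables.
- **λh, NRTL, UNIQUAC, Wilson rules: nonlinear least squares in x.**
  The generating convention for the published nonlinear fits is not
  identifiable (see Limitations); x-space is the package's choice,
  matching the space in which RMSD/RSS are defined.

`fit_model(..., objective=...)` overrides either default.  The optimiser
is SciPy trust-region least squares from a fixed multistart grid
(λ ∈ {0.1, 0.3, 1, 3} × h ∈ {Δ_fus_H/R, 1000, 3000, 6000} for λh;
±{500, 1000, 3000, 6000} J/mol on each interaction energy for the
γ-models; ±{0.5, 1, 2} on each Wilson λ), tolerances 10⁻¹⁴, ties broken
by lowest objective then lexicographic parameter order — fully
deterministic.  Bounds: λ ∈ (10⁻⁶, 50), h ∈ (1, 10⁶) K,
Δg/Δu ∈ ±5·10⁴ J/mol, Wilson λ ∈ ±50 excluding denominator
singularities.  A diagnostic (not an identity): ln-OLS and x-space
van't Hoff slopes agree within ~2 % on the built-in data (0.9 %, 1.7 %
and 0.03 % for the three monosolvents).

## Wilson mixing rules for binary solvents

The modified Wilson rule expresses the mixture solubility from the two
pure-solvent solubilities x₁(T), x₂(T) at the same temperature and two
cross parameters λ₁₂, λ₂₁.  The package evaluates x_i from each pure
solvent's fitted Apelblat correlation (its best monosolvent model).  The
Wilson–van't Hoff variant replaces ln x_i with A_i + B_i/T using the
pure-solvent van't Hoff parameters; our refit of it reproduces the
published RSS for p-cymene + α-pinene exactly (0.22952·10⁻⁴),
confirming that convention.

λ₁₂/λ₂₁ are composition-mixing parameters, best identified from data in
which composition actually varies.  The pipeline therefore calibrates
the modified Wilson rule on the matching composition-scan dataset when
one exists and scores the fixed-composition (w = 0.5) curve as an
out-of-sample prediction — correlating one portion of the data to
predict other compositions, which is the rule's stated use.  This
reproduces the qualitative result that the modified Wilson rule is the
weakest of the three binary models; fitting it directly to the w = 0.5
curves would instead make it the strongest and invert the model
ranking.  `fit_model(ds, "wilson", ...)` itself always fits whatever
dataset it is given.

## Model selection

AIC = N ln(RSS/N) + 2k with RSS in x-space.  The parameter count k
follows the bookkeeping verifiably used in the published comparison:
3 for Apelblat, 2 for λh/van't Hoff/Wilson rules, and 4 for NRTL and
UNIQUAC.  (Only k = 4 reproduces the published NRTL/UNIQUAC AIC values
from their own RSS; with k = 2 the published numbers would even change
their own best-model identity for β-caryophyllene.)  `FitResult.k_aic`
carries the count and can be overridden.  Akaike weights follow
ω_i = exp((AIC_min − AIC_i)/2)/Σ_j exp((AIC_min − AIC_j)/2).

With these conventions the best-model identities match the published
conclusion for all six fixed-composition systems: modified Apelblat for
α-pinene and p-cymene, λh for β-caryophyllene and both
p-cymene-containing binaries, Wilson–van't Hoff for
α-pinene + β-caryophyllene.

## Dissolution thermodynamics

T_hm is the harmonic mean n/Σ(1/T_i) — the only reading of the
(typographically garbled) defining formula that reproduces the published
Δ_sol_G⁰ values from the printed intercepts.  ln x is regressed by
unweighted OLS on (1/T − 1/T_hm); recentring leaves the slope invariant
and makes Δ_sol_G⁰ = −R·T_hm·intercept direct.  Quantities are computed
in J and reported in kJ/mol (ΔH, ΔG) and J/(mol·K) (ΔS) at 4 decimals.
δ_H and δ_TS use absolute values in numerator and denominator; on the
built-in data all ΔH, ΔS are positive, so the ratios are plain.  These
are apparent (x-based) quantities; no activity correction is applied.

## Hansen solubility parameters

The Fedors table stores per-group-occurrence cohesive energies E (J/mol)
and molar volumes V (cm³/mol, negative for the CH/C branch and ring
corrections); δ = sqrt(ΣνE/ΣνV) gives MPa^0.5.  For the solute inventory
this yields δ = 20.7089 MPa^0.5 (the reference tabulation prints
20.7144 from the same constants; the 0.006 gap is a rounding artefact in
the source, within the 0.01 reproduction band).  Mixed-solvent δ is the
fraction-weighted arithmetic mean of the pure δs; at the equal-mass
midpoint used here, mass-, mole- and volume-fraction bases coincide, so
the basis choice is flagged but unresolved for off-midpoint use.
δD/δP/δH component decompositions are supported only if component tables
are supplied; the shipped surface is total-δ only.

## Synthetic data

`simulate_dataset` draws x_i = model(T_i; θ)·(1 + ε_i) with
ε_i ~ N(0, σ²) — multiplicative noise because the measurement
uncertainty is relative (u_r(x) = 0.01, the default σ).  Samples outside
(0, 1) are rejected and redrawn.  The default grid is 12 temperatures
spanning 295–340 K, mirroring the measured designs.  One master seed
spawns per-replicate `SeedSequence` streams, so replicate r is
reproducible in isolation.

The generator emulates the error *magnitude* structure of the
measurements, not the measurement process: no temperature error, no
serial correlation along the heating ramp, no systematic bias near
saturation.  A green recovery test therefore establishes that the
estimation machinery is consistent and unbiased under the stated noise
model — not that the models are mechanistically correct for real data.
Recovery checks: noiseless round-trips recover parameters to 10⁻⁶
relative; the median refit ARD sits at the half-normal noise floor
σ·sqrt(2/π) within a factor of two; van't Hoff slope RMSE shrinks as the
grid doubles.

## Known limitations

- The published λh parameter sets are internally inconsistent with their
  own deviation metrics and calculated-solubility columns (the α-pinene
  pair gives a 1.05 % deviation at the first point alone, against a
  printed mean of 0.416 %); no fitting convention reproduces both.
  Refitting is treated as authoritative, and the published λh
  calculated-solubility column is not a reproduction target.
- Because our λh and UNIQUAC refits reach lower RSS than the published
  (under-converged) fits, the recomputed Akaike weight of the Apelblat
  model on α-pinene is ≈0.73 rather than the published 0.93; the ranking
  itself is unaffected.  This is a faithful-refit discrepancy, not a
  tolerance issue.
- The NRTL/UNIQUAC closure (Δ_fus_H value, r/q, possibly a different SLE
  relation) behind the published activity-model columns is unstated;
  forward evaluation of the published NRTL parameters reproduces the
  published calculated solubility only to ~2·10⁻³ in x.
- No ΔCp-corrected SLE, no ternary activity-coefficient formulation, no
  uncertainty quantification on fitted parameters, no Hansen-sphere
  (Ra/RED) computation, and no quantum-chemistry solubility prediction.
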