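# Methods

`trxstab` implements the equilibrium-thermodynamics and hydrodynamics
toolchain used to characterise the conformational stability of small
globular proteins — written around the three thioredoxins of *Pisum
sativum* (PsTRXh1, PsTRXh2, PsTRXf), whose published parameters serve
as the reference scenarios throughout.

## Spectral observables

Emission spectra (300–400 nm, 1-nm pitch by default; any strictly
increasing grid is accepted) are reduced to the intensity-weighted mean
emission wavelength

⟨λ⟩ = Σᵢ λᵢ Iᵢ / Σᵢ Iᵢ,

which is bounded by the grid extremes, invariant to intensity rescaling,
and far more sensitive to spectral shifts than the intensity at any one
wavelength. Curves assembled from spectra are sorted by condition on
ingest; duplicated conditions with conflicting signals raise instead of
averaging, so a fit is always reproducible from its input file.
Multi-probe overlays divide each curve by its value at the lowest
condition (idempotent, sign-preserving).

## Chemical denaturation

The two-state model combines the linear extrapolation model (LEM),
ΔG = m([U]₅₀ − [U]), with linear native/denatured baselines inside a
Boltzmann mixture:

X(U) = [X_N + X_D e^(−ΔG/RT)] / [1 + e^(−ΔG/RT)].

R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T defaults to 298.15 K (25 °C),
overridable. The apparent unfolded fraction at [U]₅₀ is exactly ½.

The three-state extension is a sequential N↔I↔U scheme with a constant
intermediate signal level α_I — the minimal extension consistent with
probe-dependent midpoints (far-UV CD reporting the loss of secondary
structure at a lower [GdmCl] than the fluorescence-reported tertiary
event, as in PsTRXh2). An equation for the published three-state
analysis is not available, so this functional form is this package's
own design choice. The joint fit shares (m₁, [U]₅₀,₁, m₂, [U]₅₀,₂)
across probes while each probe keeps its own baselines and intermediate
level; ordering [U]₅₀,₁ ≤ [U]₅₀,₂ is enforced by parameterising the
second midpoint as an offset with a non-negative bound. Whether the
original analysis shared baselines across probes is not stated; the
joint-fit option covers both readings (single curves are accepted too).

Identifiability: after a three-state fit the intermediate is declared
unresolved (and the two-state model recommended) when its population
never exceeds 5% over the scanned range, or when the nested two-state
fits already explain the data with no meaningful SSR improvement — the
latter catches the degenerate case where a spurious intermediate can be
parked anywhere on a genuinely two-state curve at zero cost.

## Thermal denaturation

ΔG(T) = ΔH(T_m)(1 − T/T_m) + ΔC_p[(T − T_m) − T ln(T/T_m)], inserted
into the same Boltzmann signal expression with baselines linear in
temperature. ΔC_p can be pinned (default 1.2 kcal mol⁻¹ K⁻¹, the usual
standard value) or floated; because the signal depends on ΔG only near
the transition, the fitted T_m is insensitive to the choice (checked to
< 0.1 °C on noisy synthetic data). Temperatures are Celsius at the
interface, Kelvin internally (offset 273.15). ΔS(T_m) = ΔH/T_m is
reported as a derived quantity. Fits are equilibrium-model fits; a
reversibility caveat is recorded in the result metadata because the
experimental transitions for two of the three proteins were not fully
reversible, and scan-rate-dependent irreversible models are out of
scope.

## DSC

Two-state excess heat capacity C_p,ex = ΔH²/(RT²)·K/(1+K)²,
K = e^(−ΔG/RT) with the van't Hoff ΔG; its temperature integral equals
ΔH exactly. The sequential three-state form is the analytic derivative
of the ensemble-average enthalpy of the N↔I↔U partition function
(verified in the tests against numerical differentiation). A free
overall amplitude absorbs partial irreversibility: a re-heating scan of
partly aggregated material shows the same T_max with a proportionally
smaller calorimetric enthalpy, so ΔH_vH (shape) and ΔH_cal (trapezoidal
integral) separate cleanly and their ratio is the standard two-state
diagnostic. Note the C_p,ex maximum sits slightly below T_m — the 1/T²
prefactor shifts it by ≈ 4R²T_m³/ΔH² (about 0.16 °C for ΔH ≈ 63
kcal/mol at 68.5 °C); tests account for this analytically. Traces with
a negative lobe deeper than 5% of the peak are rejected as failed
chemical-baseline subtraction.

## pH titrations

Single transitions use a base-10 (Henderson–Hasselbalch) sigmoid with
an optional Hill coefficient (default 1; no cooperativity model was
specified for the reference fits). Double transitions are a sum of two
sigmoids — not a product — because that shape reproduces the observed
ANS "bump" with independent signed amplitudes and nests the single
model exactly (A₂ = 0). pKa values are invariant to affine signal
rescaling, so raw and normalised curves give identical midpoints.

A fitted pKa is withheld (verdict `no_acid_baseline` /
`no_base_baseline`) when a plateau is supported by fewer than two
points more than one pH unit from the midpoint, or its standard error
exceeds half the amplitude — operationalising the experimental practice
of not reporting midpoints without baselines. Monotone drift with no
inflection (midpoint outside the scan, plateaus extrapolated beyond 3×
the observed span, or a straight line fitting as well as the sigmoid)
is reported as non-convergence.

## Hydrodynamics

SEC follows Ackers' treatment: σ = (V_e − V_o)/V_i and
R_s = a + b·erfc⁻¹(σ), where erfc⁻¹ is the inverse of the standard
complementary error function (scipy's `erfcinv`); the calibration is an
ordinary linear least-squares fit of R_s on erfc⁻¹(σ) with analytic
standard errors. σ outside (0, 1) marks protein–column interaction
(late elution at acidic pH) and is flagged rather than rejected.
Note an internal inconsistency in the reference data: the tabulated
experimental R_s of ~14 Å corresponds to an elution volume whose σ,
pushed through the tabulated calibration line, gives ≈ 21.7 Å. The
implementation follows the printed equations and flags the
disagreement; no constant was tuned to force agreement.

Theoretical estimators: anhydrous sphere radius
r₀ = (3Mv̄/4πN_Av)^⅓ with v̄ = 0.73 cm³ g⁻¹ by default (the average
for these proteins); folded-chain scaling R_s = 4.75·N^0.29; NMR
rotational correlation time τ_c ≈ 1/(5T₂) with its inherent ~10%
uncertainty; and the linear mass estimate MW = k·τ_c with
k = 2.0 kDa ns⁻¹ at 25 °C, a constant chosen because it reproduces the
three reference NMR mass estimates within ~1.5% (the mapping constant
is not published). Reference radii are printed to 1 Å (0.1 Å for r₀),
and two of them sit exactly at a rounding boundary, so comparisons
against printed values are made at one printed unit.

## ASA and m-value prediction

Surface-area tables (folded and extended, polar and non-polar, from a
structure-analysis server) are consumed as data; ΔASA = extended −
folded per polarity class, and the theoretical GdmCl m-value uses the
Myers/Pace regression m = 0.859 + 2.2×10⁻⁴·ΔASA_total (configurable
coefficients; the GdmCl linear variant is used because it reproduces
the published 3.6–3.8 kcal mol⁻¹ M⁻¹ range from these inputs).
`lem_consistency` reports |m·[U]₅₀ − ΔG|/ΔG as a quick cross-check of
reported free energies.

## Synthetic data

Every fitting stage is validated on forward-model data because no raw
traces are deposited. Generators emulate the experimental acquisition
settings: GdmCl 0–7 M (30 points by default), thermal scans 25–95 °C at
0.2 °C pitch, pH 2–13 at 0.5 steps, DSC on a 0.05 °C grid over
T_m ± 30 °C, and the four-protein SEC standards kit (16.4, 20.9, 30.5,
35.5 Å). Noise is homoscedastic Gaussian, parameterised as a fraction
of the signal amplitude (so scenarios transfer across probes) or in
absolute units; the same seed always reproduces the same data, and
ground truth is embedded in the file headers. Emission-spectrum series
are two-Gaussian band mixtures (folded band 335 nm, unfolded 351 nm,
σ = 10 nm — chosen so that band truncation at the 300/400 nm window
biases the centroid by < 0.01 nm) weighted by the unfolded fraction.

What the generators do not emulate: instrument artifacts (lamp drift,
thermal lag, aggregation exotherms), heteroscedastic or correlated
noise, slit-width effects, and any kinetic/irreversibility mechanism
beyond a global DSC amplitude factor. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to every pathology of real instrument data.

## Numerical choices

Nonlinear fits use damped least squares (Levenberg–Marquardt via lmfit)
with tight tolerances (ftol = xtol = 10⁻¹²) and five seeded restarts
jittering free parameters by 10%; the lowest-SSR solution wins.
Initialisation is data-driven: baselines from linear fits to the
lowest/highest 20% of the x-range, midpoints from the half-amplitude
crossing, transition slopes from the central finite difference (e.g.
m ≈ 4RT·|dX/dU|/amplitude at the midpoint). Standard errors come from
the covariance of the converged fit and are `None` when the covariance
is singular. Fixed parameters are recorded in the result alongside the
flags and derived quantities.

Monte-Carlo recovery checks run 100 seeded replicates per scenario at
2–3% amplitude noise and declare an estimator unbiased when the mean
deviates from truth by less than twice the Monte-Carlo standard error —
a 95% indistinguishable-from-zero band; a one-standard-error band would
fail about a third of the time for a perfectly unbiased estimator. The
exhaustive-grid cross-check fits five small curves with baselines
pinned and requires the optimiser's (m, [U]₅₀) to land within one
0.01-step of the brute-force SSR minimum.

## Known limitations

* Equilibrium models only: no kinetic DSC models, no global multi-pH
  surface fits, no inner-filter/Raman spectral corrections.
* ASA values are inputs; no structure-based surface computation.
* The three-state chemical functional form and the τ_c→MW constant are
  reconstructions (documented above), not published equations.
* The SEC experimental-radius inconsistency described above is flagged,
  not resolved.
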