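# Methods

## Model

Absorbed dose D (kGy) is the independent variable; concentrations are on a
relative scale where the unirradiated parent equals 100 ("rel. un.").

**Parent decay.** dC_a/dD = −αC_a with C_a(0) = C₀ gives
C_a(D) = C₀e^{−αD}. α (kGy⁻¹) aggregates every destruction channel — direct
ionization by primary electrons and attack by water-radiolysis species
(OH•, H•, e⁻_aq, H₂O₂) — into a single first-order rate in dose. The model
is agnostic about mechanism; dose is the only driver, so radical
concentrations, dose rate and solution chemistry are folded into α.

**Product formation/decay.** dC_p/dD = −βC_p + kC₀e^{−αD} with
C_p(D₀) = 0, where β (kGy⁻¹) is the product's own decomposition rate, k
(kGy⁻¹) the fraction of decomposing parent converted into this product, and
D₀ (kGy) a threshold dose below which the product is modelled as absent
(products needing several ionization events only appear at higher doses).
The closed form is

C_p(D) = H(D−D₀)·kC₀/(β−α)·[e^{−αD} − e^{(β−α)D₀}e^{−βD}],

computed internally in the cancellation-free form
kC₀·e^{−βD}·e^{(β−α)D₀}·expm1((β−α)(D−D₀))/(β−α), which remains accurate
for |β−α| → 0; at β = α exactly the removable singularity is filled with
the limit kC₀(D−D₀)e^{−βD}. Either Heaviside convention at D = D₀ yields
C_p(D₀) = 0 because the bracket vanishes there. The curve peaks at
D* = D₀ + ln(β/α)/(β−α) (D₀ + 1/α at β = α); when either rate is zero the
supremum is only approached asymptotically and `peak_dose` returns `inf`.

All rates are per kGy. The bundled coefficient magnitudes (e.g.
α = 1.28 for tetracycline) are only dimensionally consistent with kGy⁻¹ —
per Gy they would imply total destruction within a few Gy, contradicting
the observed 98–99% removal at 7000 Gy — so the data model uses kGy
throughout and treats any Gy-labelled input as requiring explicit
conversion (`gy_to_kgy`).

## Estimation

Fitting is sequential because the product ODE presumes the parent solution:
(C₀, α) are estimated first, then each product's (β, D₀, k) conditional on
them. Joint estimation across the full system is deliberately out of scope.

**Parent.** Unweighted nonlinear least squares (trust-region reflective,
α ≥ 0) on all replicate points, initialized from a log-linear regression on
the positive areas. C₀ is fixed at 100 by default (data normalized to the
dose-0 mean); freeing it is an option. Censored ("not detected") rows enter
as zeros. Standard errors come from the Gauss–Newton covariance with the
residual variance; the goodness measure R_corr is the Pearson correlation
between observed and fitted values, clipped to [0, 1] and flagged undefined
(NaN) for constant data.

A caveat documented here because the tests quantify it: with multiplicative
CV = 10% noise the unweighted estimator α̂ carries a small positive
second-order bias (≈ +2% relative for the fastest-decaying antibiotics,
α ≈ 2.2–2.5, where only one or two dose points remain informative). The
bias is a property of the unweighted objective under signal-proportional
noise, not of the optimizer; it is an order of magnitude smaller than a
single experiment's sampling SD.

**Product.** The Heaviside gate makes the objective non-smooth in D₀, so D₀
is profiled: a grid from 0 to the smallest dose with signal (default step
0.01 kGy), then bounded local refinement between the neighbouring grid
points, accepting the refined value only if the objective decreases (the
objective never increases during refinement; exact ties keep the smallest
D₀). At each D₀ candidate the model is linear in k, so k ≥ 0 is solved in
closed form and only β is optimized (log-grid scan plus bounded
minimization, β ∈ [1e−4, 100]). Standard errors use a central-difference
Jacobian in (β, D₀, k) at the optimum. On noiseless data the procedure
recovers generating parameters to ≤ 0.1% (D₀ limited by the grid plus
refinement).

**Marker inversion.** C_p is linear in C₀, so given a marker's known
kinetics the initial concentration is the exact linear least-squares
solution Ĉ₀ = Σyᵢfᵢ/Σfᵢ² with fᵢ the unit-C₀ prediction; the estimator is
unbiased under mean-zero noise (verified to within 2% over 1000 synthetic
campaigns). It is unidentifiable when every observed dose is at or below
D₀ (all fᵢ = 0), which is reported as an error.

## Dosimetry

Fricke dose: D = kΔS/(ρ·G(Fe³⁺)·l·ε) with k = 9.65×10⁶, ρ = 1.024 g/cm³,
G = 15.6 ions/100 eV (electrons up to 10 MeV), l = 1 cm,
ε = 2160 L mol⁻¹ cm⁻¹. The coefficient k absorbs the unit conversions of G
and ε; the defaults are taken as given and not re-derived. Session
charge→dose calibration is a zero-intercept regression
slope = ΣQD/ΣQ² (physics forces D = 0 at Q = 0); the bundled session log's
dose/charge ratios agree within 0.04%, which is what makes the plate charge
a usable routine dosimeter.

## Removal statistics

Removal per replicate is 100·(1 − area(D)/mean area(0)) with a Student-t
95% CI over replicates; censored rows count as 100% removal. The two-way
fixed-effects ANOVA (antibiotic × dose, with interaction) is computed
directly from the sums-of-squares decomposition — not delegated to a
library — and validated in tests against an independent brute-force oracle
and against statsmodels. Dose-0 cells (removal ≡ 0, zero variance) are
excluded. Tukey HSD uses q = |m_i − m_j|/√(MSE/m) with the error df from
the ANOVA and quantiles from the studentized-range distribution; a
permutation fallback (≥ 10⁴ label permutations within dose strata,
seed-controlled) is provided for settings where the distributional
assumptions are doubtful.

## Synthetic data

The generator emulates the measurement design: doses {0, 0.1, 1, 3, 7} kGy,
3 replicates, multiplicative Gaussian noise area = conc·(1+ε),
ε ~ N(0, CV²) truncated at −1, default CV = 10% with a hard cap at 20%
(the documented replicate scatter bound), and a detection limit at 0.1% of
the parent C₀ below which areas are recorded as censored "ND". Multiplicative
rather than additive noise because LC-MS peak-area variability scales with
signal. What it does *not* emulate: chromatographic peak shapes, m/z
spectra, retention-time drift, carry-over, matrix effects, or any
separation of instrument vs irradiation variability (a single CV covers
both). Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed error model, not robustness to real
instrumental artefacts.

The null-removal generator used for the type-I-error validation draws
replicate removal values as the shared dose-response curve (one α for all
antibiotics, default 1.28) plus iid homoscedastic Gaussian noise on the
removal scale, σ = 100·CV·mean_D e^{−αD} over the positive doses. This is a
deliberate design choice: computing removal against a noisy per-antibiotic
dose-0 baseline would inject a shared-denominator random effect at the
antibiotic level, and pushing multiplicative area noise through the removal
transform makes cell variances span four orders of magnitude across doses —
both violate the classical F test's error model, and the purpose of the
null generator is to validate the ANOVA implementation at its nominal
level, which requires data satisfying the test's own assumptions. Measured
rejection rate of the antibiotic-factor F test: 5.25% over 2000 simulations
(binomial SE ≈ 0.5%).

## Pathway energetics

DFT-derived quantities (C–H bond-dissociation energies per carbon position
of tetracycline; per-pathway reaction energies) are bundled as data and
never recomputed — quantum chemistry is out of scope. The module implements
the arithmetic: energy differences (products − reactants), minimum-energy
site selection with deterministic tie-breaking by carbon number, and
ionization-event bookkeeping. Markers are ranked by total ionization events
(direct + indirect), then detection dose, then fitted D₀ — fewer events
means the product forms at lower dose and tracks the parent more reliably.
Two pathway step lists are flagged `uncertain` where the narrative source
names fewer steps than the event count it states; the encoded counts follow
the stated totals. One product's catalogued detection dose (1 kGy) conflicts
with its narrative dose (3 kGy); both are stored (`table_dose_kGy`,
`text_dose_kGy`) rather than resolved. The late product 437.1205 peaks at
3.20 kGy — just outside the 0.1–3 kGy window in which the four 1-kGy
products peak; the tests pin its peak at the computed value instead of
forcing it into the window.

## Numerical choices and problem sizes

- Closed forms validated against fixed-step classic RK4 integration of the
  ODEs (step 5×10⁻³ kGy, global error ≪ 10⁻⁹ relative) over 500 random
  parameter draws with α, β ∈ [0.05, 5], including |β−α| ≤ 10⁻⁴;
  agreement required to 10⁻⁶ relative.
- Optimizer tolerances 10⁻¹² (ftol/xtol); D₀ grid 0.01 kGy with 10⁻¹⁰
  refinement tolerance.
- Monte-Carlo study sizes: 500 seeds for decay-rate recovery, 1000 for
  marker inversion, 2000 for the ANOVA type-I error — sizes chosen so the
  Monte-Carlo standard errors are comfortably below the asserted bounds.
- Degenerate inputs: constant series fit as α = 0 with R_corr flagged
  undefined; all-censored product series raise a no-signal error; doses at
  or below D₀ alone raise an unidentifiability error.

## Known limitations

- First-order-in-dose kinetics only; no alternative kinetic laws, no model
  selection, no Bayesian inference.
- Sequential (conditional) fitting propagates no parent-parameter
  uncertainty into product standard errors.
- Censored observations are treated as exact zeros in the least squares,
  not via a likelihood for left-censoring.
- The ANOVA requires a balanced design; unbalanced layouts are rejected
  rather than approximated.
- No raw chromatogram or mzML processing: the package starts from
  integrated peak areas.
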