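# ebeamkin

Dose–response kinetics of antibiotic degradation in water under
electron-beam irradiation.

Residual antibiotics in natural and waste water promote antimicrobial
resistance, and electron-beam irradiation (EBI) is one of the few treatment
technologies that degrades them without added reagents. `ebeamkin` is a
Python package for analysts working with LC-MS peak-area dose series from
irradiation experiments: it models how a parent antibiotic and its
degradation products respond to absorbed dose, recovers the kinetic
coefficients from replicate measurements, handles the supporting dosimetry,
and ranks degradation products as candidate *markers* from which the initial
contamination level of a water source can be reconstructed.

## The model

Absorbed dose D (kGy) plays the role of time. The parent antibiotic decays
exponentially,

    dC_a/dD = −α C_a          ⇒   C_a(D) = C₀ e^{−αD},

with decomposition rate α (kGy⁻¹) and C₀ the relative concentration of the
unirradiated solution (scaled to 100). A degradation product accumulates
from the parent and is itself destroyed by the beam; with a threshold dose
D₀ below which it is absent,

    dC_p/dD = −β C_p + k C₀ e^{−αD},   C_p(D₀) = 0,

whose solution is the Heaviside-gated biexponential

    C_p(D) = H(D−D₀) · kC₀/(β−α) · [e^{−αD} − e^{(β−α)D₀} e^{−βD}],

with the analytic limit kC₀(D−D₀)e^{−βD} at β = α. Removal at dose D is
100·(1 − e^{−αD}) percent; the product peaks at
D* = D₀ + ln(β/α)/(β−α).

Fitting is sequential, mirroring the model structure: (C₀, α) per antibiotic
first, then (β, D₀, k) per product with the parent law frozen. Because the
threshold makes the objective non-smooth in D₀, the fit profiles D₀ over a
grid (default 0.01 kGy) with local refinement; k, in which the model is
linear, is solved in closed form. Since C_p is linear in C₀, a marker series
inverts exactly: Ĉ₀ = Σyᵢfᵢ / Σfᵢ², where fᵢ is the unit-C₀ prediction —
this is how the initial contamination is reconstructed from a marker.

The package also includes Fricke ferrous-sulfate dosimetry
(D = kΔS/(ρ·G·l·ε)) with a zero-intercept charge→dose session calibration,
removal tables with Student-t confidence intervals, a hand-rolled balanced
two-way ANOVA with Tukey HSD, a catalogue of degradation products with
DFT-derived C–H bond-dissociation energies and ionization-event counts per
transformation pathway, and a synthetic-data generator that emulates the
triplicate measurement design (multiplicative noise, detection-limit
censoring).

## Worked example

```python
import numpy as np
import ebeamkin as ek

registry = ek.load_table3_registry()          # bundled fitted coefficients
doses = np.arange(0.0, 7.25, 0.25)
table = ek.simulate_noiseless(registry, doses)

parent = ek.AntibioticDecayModel(table, "tetracycline").fit()
print(parent.summary())

marker = ek.ProductFormationModel(table, "461.1549", parent).fit()
print(marker.summary())

est = ek.reconstruct_initial(table, "461.1549", registry.products["461.1549"])
print(est.summary())
```

prints

```
Antibiotic decay fit
============================================
analyte:        tetracycline
n obs:          29
C0 (rel. un.):  100 (fixed)
alpha (1/kGy):  1.28 +/- 4.97e-17
R_corr:         1.0000
SSE:            3.29581e-28
Degradation-product kinetics fit
============================================
analyte:       461.1549
n obs:         29
parent alpha:  1.28 (fixed)
parent C0:     100 (fixed)
beta (1/kGy):  0.65 +/- 4.62e-11
D0 (kGy):      0.98 +/- 2.93e-11
k (1/kGy):     0.14 +/- 1.08e-11
R_corr:        1.0000
SSE:           4.39387e-19
Initial-concentration reconstruction from marker '461.1549': C0 = 100 +/- 5.51e-15 (n = 29)
```

The decay rate α = 1.28 kGy⁻¹ means ~99.99% of the tetracycline is removed
at 7 kGy; the marker product appears above its threshold dose
D₀ = 0.98 kGy, peaks near 2.1 kGy and is itself destroyed at higher doses
(β = 0.65 kGy⁻¹); the reconstructed C₀ = 100 recovers the initial
contamination exactly on noiseless data.

The same workflow is available from a shell:

```bash
ebeamkin simulate --seed 1 --out campaign.csv
ebeamkin fit --input campaign.csv --out fits.json
ebeamkin removal --input campaign.csv --analytes tetracycline,doxycycline --out removal.json
ebeamkin dose --out calibration.json
ebeamkin rank-markers --out markers.json
```

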