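# Methods

## Scope and model structure

`photolim` analyses steady-state leaf measurements taken at 25 °C,
saturating light (PPFD 1500 μmol m⁻² s⁻¹) and ambient CO2
(C_a = 400 μmol mol⁻¹) for a factorial stress experiment on rice, wheat
(C3) and maize (C4): control, water deficit (WD), high growth
temperature (HT) and the combination (HT-WD), with 4–5 replicates per
cell. All kinetics are 25 °C values; no temperature-response functions
are applied anywhere.

### Fluorescence

ΦPSII = (F′m − Fs)/F′m and J = ΦPSII·PPFD·α·β. α is a measured numeric
input (typically 0.86–0.87 for these species); β is fixed by
photosynthetic type (0.5 for C3, 0.4 for maize) unless overridden per
record. ΦPSII is scale-invariant in the fluorescence yields; J is
linear in each argument.

### C3 diffusion (variable-J)

The RuBP-regeneration-limited FvCB rate
A_N = J(C_c − Γ*)/(4C_c + 8Γ*) − R_d inverts to
C_c = Γ*(J + 8(A_N + R_d))/(J − 4(A_N + R_d)), and Fick's law gives
g_m = A_N/(C_i − C_c). Records with J ≤ 4(A_N + R_d) are physically
incompatible with the electron-transport budget; they are **flagged and
excluded** from treatment means, never clipped, because clipping
silently biases g_m. Daytime respiration R_d inside the formula is
taken as R_dark/2 (configurable `rd_fraction`), mirroring the
A_G = A_N + R_dark/2 convention for gross assimilation: only pre-dawn
dark respiration is measured. Gross assimilation of a leaf with
negative A_N is clipped at 0 with a warning (a sanity guard only; such
records never enter g_m estimation).

### C4 bundle sheath

Maize is treated with constant mesophyll (g_m) and bundle-sheath (g_bs)
conductances. The mass balance C_m = C_i − A_N/g_m,
V_p = V_pmax·C_m/(C_m + K_p), R_m = 0.5·R_dark and
C_s = C_m + (V_p − A_N − R_m)/g_bs yields the bundle-sheath CO2 and the
leak rate g_bs(C_s − C_m). R_m = 0.5·R_dark is the common convention in
the C4 modelling literature (configurable `Rm_fraction`). The A_N–C_i
response is summarised by the rectangular hyperbola
A_N = A_max·C_i/(K + C_i) (least squares; a fit with K far below the
smallest observed C_i is flagged degenerate — the half-saturation point
is unidentified on a plateau). The PEP-carboxylation supply V_p can
come either from the Michaelis form above (default) or from the fitted
hyperbola evaluated at the operating C_m (`vp_source: hyperbola`);
both are exposed because the exact C4-model variant behind published
analyses of this design is not always recoverable.

Biochemical analysis in maize is restricted to the C3-cycle (Rubisco)
activity: the Rubisco-limited rate at C_s,
A_N = V_cmax(C_s − Γ*)/(C_s + K_m) − R_d. C4-cycle enzymes (PEPC, PPDK)
are out of scope.

### Rubisco biochemistry

¹⁴C assay arithmetic: μmol CO2 fixed = counts (kBq) / 15.54 kBq μmol⁻¹;
the rate is scaled to one minute (60 s reaction) and to one mg of total
soluble protein (TSP) via the aliquot volume (10 μL) and the extract's
TSP concentration. The activation state is initial/total activity;
ratios in (1, 1.05] are clipped to 1 with a warning (assay noise),
larger ratios raise. Rubisco amounts come from gel densitometry against
a purified-standard line (R² ≥ 0.95 required, 15 μg TSP per lane); Rca
amounts from immunoblots normalised per μg TSP against the 5/10/15 μg
control-extract dilution series (zero-intercept least squares), giving
amounts relative to control.

V_cmax = [Rubisco, g m⁻²] · (8 sites / 550 kg mol⁻¹) · activation ·
k_cat, with k_cat = 2.1, 2.2, 4.1 s⁻¹ (rice, wheat, maize; in vitro,
25 °C). Published activities are per mg TSP while V_cmax is per leaf
area, so a TSP-per-area bridge is needed; the pipeline accepts a
measured column or a config constant (default 5 g TSP m⁻², a typical
value for young cereal leaves) and records which was used in the
manifest.

### Limitation partitioning

At an operating point, total conductance g_tot = (1/g_s + 1/g_m)⁻¹
(g_s converted to CO2 units by /1.6) and the Rubisco-limited slope
dA/dC = V_cmax(Γ* + K_m)/(C + K_m)² define the weights

    l_s  = (g_tot/g_s)·dAdC/(g_tot + dAdC)
    l_mc = (g_tot/g_m)·dAdC/(g_tot + dAdC)
    l_b  =  g_tot/(g_tot + dAdC),        l_s + l_mc + l_b = 1 exactly.

Components are weights times log-changes from the control reference:
SL = l_s·(ln g_s,ref − ln g_s), etc., and DL = SL + MCL by definition.
The log form was chosen over raw fractional differences because
proportional perturbations then compose exactly; the raw-fraction
variant remains available (`decomposition: fraction`) for sensitivity
checks. At treatment level the weights are evaluated at **both** the
control and the stressed operating point and averaged (trapezoid rule
along the stress path); this keeps the weights summing to 1 exactly and
makes the decomposition second-order accurate — for 10% single-factor
perturbations the component sum matches the forward model's log decline
to ~0.1%, versus ~4% with reference-only weights. Negative components
(a stressed driver above its reference) are clipped at 0 with a counted
warning. For maize the slope is evaluated at C_s and the mesophyll term
uses the constant g_m, so MCL vanishes unless g_m is varied in a
sensitivity run.

Treatment-level decompositions use cell means (n = 4–5) with
nonparametric bootstrap standard errors (default 2000 resamples,
seeded; both treatments resampled independently).

### Statistics

Fixed-effects factorial ANOVA (species × irrigation × temperature, all
interactions) via OLS. Balanced designs give the exact orthogonal SS
partition; unbalanced cells (replicate loss) fall back to Type II sums
of squares with a logged warning — the design itself is balanced, so
the choice rarely matters. Duncan's multiple range test compares the
range of p ordered means against LSR_p = q(α_p, p, df)·√(MS_res/n) with
protection level α_p = 1 − (1−α)^(p−1), step-down (a non-significant
span protects its sub-spans), harmonic-mean n for unequal groups
(warned). The studentized-range quantile comes from numerical inversion
of scipy's distribution (cached — the ppf is expensive); a frozen
classical 5% table for df ∈ {5, 10, 20, 30} cross-checks the inversion,
and the p = 2 column is verified against the closed form √2·t. Trait
relationships are ordinary least squares with R² and the slope-t
p-value.

## Constants and provenance

Every kinetic constant carries exactly one provenance flag (`study`,
`literature-default`, `user`), recorded per species in the run
manifest. Shipped 25 °C defaults: Γ* = 42.75 μmol mol⁻¹,
K_c = 404.9 μmol mol⁻¹, K_o = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹
(hence K_m = K_c(1 + O/K_o) ≈ 710 μmol mol⁻¹); g_bs = 0.01 and
g_m(C4) = 1.0 mol m⁻² s⁻¹; V_pmax = 120 μmol m⁻² s⁻¹, K_p = 80 μmol
mol⁻¹; Rubisco 550 kg mol⁻¹ with 8 catalytic sites. All overridable in
`config.yaml`, globally or per species.

## Synthetic-data generator

The generator is first-class, tested code, not a fixture. It emulates
the factorial design with the printed control biochemistry as anchors:
Rubisco amount 0.49/0.34/0.15 mg mg⁻¹ TSP, initial activity
0.31/0.19/0.08 and total activity 0.36/0.44/0.13 μmol mg⁻¹ min⁻¹
(rice/wheat/maize), so the control activation states are 0.861, 0.432
and 0.615. Control g_s (0.35/0.30/0.20 mol H2O m⁻² s⁻¹), g_m
(0.30/0.25) and R_dark (~1.5) are literature-plausible values for these
crops under the stated conditions, since no per-treatment
gas-exchange table is available to seed them. Treatment multipliers
encode the qualitative pattern: WD halves g_s everywhere (enforced:
any WD scenario must keep g_s ≤ 60% of well-watered, the study's
stomatal-closure criterion), reduces g_m and Rubisco amount in rice and
amount in maize while raising maize activation slightly; HT halves the
activation state in all species; HT-WD combines both with rice hit
hardest (amount at 50% of control).

Coherence is enforced by construction: biochemistry is sampled first
and V_cmax computed from it, C3 leaves are solved through the forward
FvCB model (Rubisco-limited) and maize leaves through the bundle-sheath
balance, and fluorescence is generated backwards — the electron-use
identity J = (A_N + R_d)(4C_c + 8Γ*)/(C_c − Γ*) fixes ΦPSII, F′m is
drawn in [0.5, 0.8] and F_s solved — so every inverse stage has an
exact per-replicate ground truth. Maize electron transport uses a
fixed 6 e⁻ per net CO2 heuristic (C3 cycle plus PEP-regeneration ATP
surcharge). Noise is mean-preserving log-normal (positivity), truncated
at ±3σ; default CVs are 10% for conductances and amounts, 5% for the
activation state, matching the order of the reported standard errors.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: instrument noise correlated across
channels, leaks and diffusion artefacts in chamber measurements,
fluorescence signal contamination from deeper leaf layers, genuine
day-to-day and within-leaf variability, or any departure of the real
leaves from the FvCB / constant-conductance C4 models themselves. The
recovery tests certify the *inversions*, not the models.

## Numerical choices

Steady-state leaves are solved by bracketed root finding (brentq,
xtol 1e-10) on C_c (C3, between Γ* and C_a) or A_N (C4). The A–Ci
hyperbola is fitted with bounded least squares from a data-driven
start. CSV outputs use 17-significant-digit floats so that on-disk
tables round-trip exactly and identities (DL = SL + MCL) survive
re-parsing; readers use round-trip float parsing. Run manifests contain
no wall-clock timestamps so that identical seed + config reproduce
every output byte (timestamps go to the stderr log). Bootstrap seeds
are derived per species × treatment cell from the run seed via CRC32,
keeping cells independent and runs reproducible.

## Problem sizes

The shipped checks use sizes that keep the whole suite interactive:
50 simulated leaves per recovery check, 200 random instances for the
Duncan oracle, 200 simulated experiments for the power analysis, and
150–500 bootstrap resamples in pipeline tests (2000 in production
runs). These sizes were chosen as comfortably sufficient for the
properties being measured.

## Known limitations

- All analyses at 25 °C; the kinetic constants carry no temperature
  response (deliberate, matching the measurement protocol).
- The variable-J method assumes the fluorescence J reflects linear
  electron transport feeding carboxylation + oxygenation only;
  alternative electron sinks bias C_c upward.
- The C4 inversion inherits the constant-g_m/g_bs assumption; C_s is
  sensitive to g_bs (leak term ∝ 1/g_bs), though the *limitation*
  analysis is not, because the Rubisco-limited slope is nearly flat at
  bundle-sheath CO2 levels.
- BL is Rubisco-based only (amount × activation × k_cat); RuBP-
  regeneration or Pi-limited biochemistry is not separated out.
- Duncan's test is used for fidelity to the original analysis despite
  its liberal family-wise error; it is not recommended for new designs.
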