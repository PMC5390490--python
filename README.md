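# photolim

Quantitative analysis of photosynthetic limitations in C3 (rice, wheat)
and C4 (maize) cereal leaves under water deficit (WD) and high growth
temperature (HT), from leaf-level gas exchange, chlorophyll-a
fluorescence and Rubisco biochemistry.

## Who it is for

Plant ecophysiologists who have (or want to simulate) steady-state
gas-exchange + fluorescence records, A–Ci response curves and Rubisco
assay data for a factorial stress experiment, and who want to know *why*
photosynthesis declined: because CO2 could not reach the chloroplast
(stomatal and mesophyll limitation), or because the photosynthetic
machinery itself was impaired (biochemical limitation).

## What it computes

1. **Electron transport** from fluorescence:
   ΦPSII = (F′m − Fs)/F′m and J = ΦPSII · PPFD · α · β
   (β = 0.5 for the C3 species, 0.4 for maize).
2. **Variable-J mesophyll conductance** (C3): the chloroplast CO2
   mole fraction Cc = Γ\*(J + 8(A_N + R_d)) / (J − 4(A_N + R_d)) and
   g_m = A_N/(C_i − C_c).
3. **Bundle-sheath CO2** (maize): with constant g_m and g_bs,
   C_m = C_i − A_N/g_m, V_p = V_pmax·C_m/(C_m + K_p), and
   C_s = C_m + (V_p − A_N − R_m)/g_bs, plus a rectangular-hyperbola
   summary of the A_N–C_i response.
4. **Biochemical Vcmax**: Rubisco activities from ¹⁴C assay counts
   (specific radioactivity 15.54 kBq μmol⁻¹, 60 s reaction), activation
   state = initial/total activity, and
   V_cmax = [Rubisco] · (sites/M) · activation · k_cat with k_cat =
   2.1/2.2/4.1 s⁻¹ for rice/wheat/maize at 25 °C.
5. **Limitation partitioning** relative to the control treatment
   (Grassi–Magnani-type): weights l_s + l_mc + l_b = 1 at the operating
   point, components SL = l_s·Δln g_s, MCL = l_mc·Δln g_m,
   BL = l_b·Δln V_cmax, with DL = SL + MCL; bootstrap standard errors
   over replicates.
6. **Factorial statistics**: species × irrigation × temperature ANOVA,
   Duncan's multiple range test (P < 0.05), and the trait regressions
   (A_N vs. activation state, activation state vs. J, Rca/Rubisco vs.
   C_c or C_s).
7. **A synthetic-data generator** that emulates the full
   3 species × 4 treatments × 5 replicates design with self-consistent
   gas exchange, fluorescence and biochemistry, so every stage is
   testable with known ground truth.

## Worked example

```python
from photolim import for_species
from photolim.c3 import electron_use_j, solve_c3_leaf, variable_j_result

consts = for_species("rice")
AN, Ci, Cc = solve_c3_leaf(gs_co2=0.20, gm=0.25, Vcmax=80.0,
                           Rd=0.75, Ca=400.0, constants=consts)
J = electron_use_j(AN, 0.75, Cc, consts.gamma_star)
res = variable_j_result(AN, Ci, 1.5, J, consts)
print(round(res.Cc, 1), round(res.gm, 4))
```

prints `250.9 0.25`: the variable-J inversion recovers the chloroplast
CO2 (250.9 μmol mol⁻¹) and the mesophyll conductance (0.25 mol m⁻² s⁻¹)
that generated the observables. The scripts in `examples/` walk through
each capability the same way; `examples/06_full_pipeline.py` runs the
whole analysis on a simulated experiment and prints the limitation
table — diffusive limitation leads in the C3 species under water
deficit, biochemical limitation (via the halved Rubisco activation
state) dominates under high temperature in all three species.

## Command line

```sh
photolim simulate --seed 1 --out sim/
photolim run-all --input-dir sim/ --out results/ --seed 1
```

writes `derived_records.csv`, `limitations.csv`, `anova.csv`,
`duncan_letters.csv`, `regressions.csv`, `hyperbola_fits.csv` and a
deterministic `manifest.json` (config hash, seed, constant provenance,
warning counts). Outputs are byte-identical across reruns with the same
seed and config.

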