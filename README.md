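# lipidtherm

Thermodynamics of protein–lipid binding from native mass-spectrometry
titrations: sequential binding fits, van't Hoff analysis, and double /
triple mutant-cycle coupling energetics.

Native MS resolves every ligand-bound state of an intact protein complex in
a single spectrum. Titrating a lipid against a membrane protein at a series
of solution temperatures therefore yields, after deconvolution, the mole
fraction of each 0-, 1-, …, n-lipid-bound species at each titrant
concentration — enough to determine stepwise binding constants, and from
their temperature dependence the full thermodynamic signature of each
binding event. `lipidtherm` implements that analysis for sequential binding
equilibria, with the MsbA–Kdo2-lipid-A (KDL) system as its packaged worked
dataset: the lipopolysaccharide flippase MsbA, a panel of interior- and
exterior-site mutants, and the ADP/vanadate-trapped outward-facing state.

## The model

**Sequential binding.** `PL(n−1) + L ⇌ PL(n)` with stepwise association
constants `K_An = [PLn]/([PL(n−1)][L])`. Species mole fractions follow the
binding polynomial

    F_PLn = L_free^n ∏_{j≤n} K_Aj / (1 + Σ_i L_free^i ∏_{j≤i} K_Aj),

with the free lipid obtained from the mass balance
`L_free = L_total − P_total Σ_i i·F_PLi`, solved exactly (bracketed Brent).
Constants are fitted per replicate by minimising the pseudo-χ² =
ΣΣ (F_exp − F_calc)² in ln K_A space, and reported as K_D = 1/K_A
(mean ± SD, n = 3).

**van't Hoff analysis.** ΔG = RT ln K_D (1 M standard state). Linear form:
`ln K_A = −ΔH/R · 1/T + ΔS/R`. Nonlinear form with a constant
heat-capacity change ΔCp:

    ln K_A = (ΔH_T0 − T0·ΔCp)/R · (1/T0 − 1/T) + ΔCp/R · ln(T/T0) + ln K_0,

fitted by exact least squares (the model is linear in ΔH_T0, ΔCp, ln K_0).
Entropy is back-calculated, −TΔS = ΔG − ΔH, so ΔG = ΔH + (−TΔS) holds
row-wise by construction.

**Mutant cycles.** With ΔΔX = X_mutant − X_wild-type (X ∈ {ΔG, ΔH, −TΔS}),
the pairwise coupling is the deviation from additivity,
`ΔΔX_int = ΔΔX_PX + ΔΔX_PY − ΔΔX_PXY`; a positive ΔΔG_int means the two
residues cooperate to stabilise binding. The third-order (triple-cycle)
coupling is the change of a pairwise coupling when a third residue is
mutated — identical along all three background routes on consistent data.
Uncertainties propagate in quadrature.

## Worked example

`examples/03_mutant_cycles.py` recomputes coupling energetics from the
packaged difference tables:

```
R78/K299 (interior site) at 298 K:
  ddG_int    =    1.7 +/- 0.3 kJ/mol
  ddH_int    =  -25.9 +/- 14.6 kJ/mol
  dd-TdS_int =   27.6 +/- 14.7 kJ/mol
  -> cooperative, driven by coupling entropy over an enthalpic barrier

R188/R238/K243 (exterior site) third-order coupling at 298 K:
  pair coupling in WT background    =   0.8 kJ/mol
  pair coupling in R188A background =  -2.6 kJ/mol
  third-order ddG_int               =   3.4 +/- 0.4 kJ/mol
```

The interior pair R78/K299 couples favourably by 1.7 kJ/mol, an
entropy-driven stabilisation that pays a ~26 kJ/mol enthalpic penalty; the
exterior triad R188/R238/K243 carries a 3.4 kJ/mol third-order coupling.
`examples/04_synthetic_cycle_pipeline.py` runs the whole chain
(simulate → fit → van't Hoff → cycle) on a synthetic panel designed with
ΔΔG_int = 1.7 kJ/mol and recovers `1.72 ± 0.07` under triplicate 1% mole-
fraction noise. The other examples cover titration fitting and van't Hoff
analysis; a thin CLI (`lipidtherm fit|vanthoff|run|simulate-panel|report`)
wraps the same functions.

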