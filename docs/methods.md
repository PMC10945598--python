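# Methods

## Scope and data model

`lipidtherm` analyses native-MS lipid titrations of a membrane protein in
three stages: (1) stepwise binding constants from species mole fractions,
(2) thermodynamic signatures from the temperature dependence of those
constants, (3) coupling energetics between mutated residues from double and
triple mutant cycles. Spectral deconvolution is upstream of the package:
the input observable is the per-titration-point mole fraction of each
ligand-bound state (or raw deconvoluted intensities, normalised per point
on load). Concentrations are handled in μM throughout; conversion to the
1 M standard state happens only where free energies are formed.

## Sequential binding model

The species weights are the terms of the binding polynomial
`1 + Σ_i L_free^i ∏_{j≤i} K_Aj`, accumulated as a running product for
numerical stability; fractions are weights over their sum, which enforces
normalisation to machine precision and the stepwise ratio
`F_n/F_{n−1} = K_An·L_free` exactly.

**Free-lipid solve.** The mass-balance residual
`L + P_total·occupancy(L) − L_total` is strictly increasing in `L`, so the
root on `[0, L_total]` is found with Brent's method (xtol 1e-14). The
residual check is by the solver's convergence flag rather than a fixed
relative residual: at extreme trial constants visited by the optimiser the
residual's derivative is so large that the residual at the machine-exact
root cannot evaluate below ~1e-9, while the root itself is converged.

**Fitting.** Each replicate is fitted independently by
`scipy.optimize.least_squares` (Levenberg–Marquardt) on the flattened
fraction residuals, in ln K_A space so positivity holds by construction.
Starting points span K_D ∈ {0.1, 1, 10} μM per event (full grid), and the
lowest pseudo-χ² wins; the `multistart=False` path starts at 1 μM only and
is used in large Monte-Carlo studies where the objective is well behaved.
Fit quality is reported as pseudo-χ² and R² = 1 − SS_res/SS_tot computed
jointly over all fraction entries about their grand mean (the conventional
choice; the source tables report a single R² per fit without defining it).
Replicate statistics are the sample mean ± SD (ddof = 1). Titrations with
fewer informative points than binding events are refused; an event whose
occupancy never exceeds 1% across the titration triggers a rank-deficiency
warning rather than silent acceptance. The number of events is
user-supplied per variant (some mutants support only one or two events);
by default it is inferred from the number of species columns present.

## Thermodynamics

ΔG = RT ln K_D (K_D in molar; R = 8.314462618e-3 kJ/mol/K). The nonlinear
van't Hoff model assumes a temperature-independent ΔCp over the ~15–20 K
experimental window; being linear in (ΔH_T0, ΔCp, ln K_0), it is solved by
exact linear least squares, which makes the linear model its ΔCp = 0
special case bit-for-bit and makes the fitted curve invariant to the choice
of reference temperature. Model choice per (variant, event) is explicit
(`linear` / `nonlinear`) or `auto`, which keeps the heat-capacity term only
when it cuts the residual sum of squares by more than half with at least
four temperatures — a deliberately conservative rule, since three
parameters on four points otherwise fit noise.

Signatures are built per replicate (fit each replicate's K_D series, then
average), not by fitting replicate means: this matches how the packaged
tables report mean ± SD (n = 3) and lets the ΔG SD come from the replicate
scatter of ΔG itself rather than first-order propagation from the K_D SD.
−TΔS is back-calculated as ΔG − ΔH, so the additive identity is exact in
every emitted row. Temperatures are excluded from fitting only via an
explicit (variant, temperature) list — the source data omit one mutant's
highest temperature from the signature tables without stating a rule, so
exclusion is user input, never automatic. One ΔCp is reported per
(variant, event, replicate); the packaged signature table prints slightly
different ΔCp values per temperature row, a feature of its original
generation that this package does not attempt to reverse-engineer.

## Mutant cycles

Sign convention: ΔΔX = mutant − wild-type; ΔΔX_int = ΔΔX_PX + ΔΔX_PY −
ΔΔX_PXY, positive for favourable cooperation. The third-order coupling is
pairwise coupling in the wild-type background minus the same pairwise
coupling in the third-mutation background; computed from all eight corners
it is route-independent, and the implementation evaluates all three routes
and reports their spread (exactly zero on consistent tables; up to ~0.1
kJ/mol on independently rounded printed inputs, which is flagged, not
fatal). SDs combine in quadrature assuming independent corners — this
reproduces the printed uncertainties (e.g. 0.2/0.2/0.2 → 0.35 ≈ 0.4;
11.3/6.1/6.9 → 14.6) — so the correlation induced by the shared wild-type
corner is knowingly ignored. Cycles are computed only for binding events
present in every corner; missing corners raise, they are never imputed.

## Synthetic data generator

The generator runs the same model forward, so it emulates exactly the
statistical structure the analysis assumes: per-variant (ΔG_T0, ΔH_T0,
ΔCp) define K_A(T) through the nonlinear van't Hoff expression; exact mole
fractions come from the binding model with the mass balance solved to
machine precision; Gaussian noise of SD `fraction_noise_sd` is added to
the fractions (the post-deconvolution observable where replicate scatter
lives), clipped to [0, 1] and renormalised. Defaults mirror the study
conditions: protein at 0.39 μM, titrant 0–10 μM in 10 points (denser
below 2.5 μM where the tightest event turns over; the exact grid of the
source experiments is not recorded, so this is a documented assumption),
temperatures {288, 293, 298, 303} K ({293, 298, 303, 310} K for
trapped-state scenarios), n = 3 replicates, noise SD 0.01 — which yields
recovered K_D scatter of roughly 5–10% relative, matching the reported
K_D SDs. Output is bit-reproducible for a given seed.

Cycle panels store ΔG_T0 rather than ΔS (one fewer redundant parameter);
mutational shifts are additive on (ΔG, ΔH, ΔCp) at T0, pairwise couplings
are subtracted from double-mutant corners and the third-order term added to
the triple corner, so the designed couplings are recovered exactly by the
noiseless pipeline. Entropic couplings follow from c_G − c_H, keeping the
additive identity exact. Couplings are defined at T0; away from T0 the
free-energy coupling interpolates as c_H(1 − T/T0) + c_G·T/T0.

What the generator does not emulate: raw spectra, charge states, detector
response, deconvolution artefacts, lipid–detergent partitioning, or
systematic (non-Gaussian, correlated) errors between species. Passing
synthetic-recovery tests therefore validates the estimator chain under the
stated noise model, not robustness to those real-data effects.

## Numerical and validation choices

* Monte-Carlo study sizes: parameter-recovery coverage uses 100 seeded
  repetitions of a 4-temperature, 3-replicate panel at 7% lognormal K_D
  scatter (≥90% within ±10 kJ/mol on ΔH and ±2 kJ/mol/K on ΔCp); the
  designed-coupling study uses 200 seeded single-temperature panels at 1%
  fraction noise with a 1.96·SD coverage criterion; the free-ligand solver
  is checked against a dense-grid bisection oracle on randomized instances
  (K_D 0.1–50 μM, P_total 0.1–1 μM, L_total 0–20 μM).
* Degenerate inputs: zero titrant → all-apo fractions and zero free lipid;
  zero protein → free lipid equals total; single-point titrations are
  refused; duplicate temperatures in a van't Hoff series are an error.
* Printed-table comparisons in tests allow ±0.2 kJ/mol for one-decimal
  rounding of the inputs (±0.5 where the source prints integers).

## Known limitations

Non-sequential (independent-site or multi-class) binding models are out of
scope, as are Kirchhoff integration with temperature-dependent ΔCp,
statistical tests of whether a coupling differs from zero, and any
structural interpretation of the couplings. The pseudo-χ² weights all
species and points equally; heteroscedastic weighting would require
per-point uncertainty estimates the deconvolution step does not provide.
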