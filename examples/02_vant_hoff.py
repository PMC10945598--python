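"""van't Hoff analysis of the packaged wild-type K_D series.

Fits the nonlinear van't Hoff model (with a constant heat-capacity
change) to the replicate-mean K_D1 values of untrapped wild-type MsbA,
and the linear model to the vanadate-trapped series, then prints the
resulting thermodynamic signatures at 298 K.  A positive dH opposed by
a larger negative -TdS means binding is entropy-driven.
"""

from lipidtherm import datasets, vant_hoff_linear, vant_hoff_nonlinear
from lipidtherm.thermo import back_calc_entropy, delta_g_from_kd, enthalpy_at_temperature

# untrapped transporter: curvature in ln K_A vs 1/T -> nonlinear model
kd = datasets.load_kd_table("apo")
wt = kd[kd.variant == "WT"]
fit = vant_hoff_nonlinear(dict(zip(wt.temperature_K, 1.0 / wt.kd1_uM)), t0=298.0)
kd_298 = float(wt.loc[wt.temperature_K == 298, "kd1_uM"].iloc[0])
dg = delta_g_from_kd(kd_298, 298.0)
dh = enthalpy_at_temperature(fit, 298.0)
print("untrapped WT, first binding event at 298 K:")
print(f"  dG = {dg:6.1f} kJ/mol   (from K_D1 = {kd_298} uM)")
print(f"  dH = {dh:6.1f} kJ/mol   (nonlinear van't Hoff)")
print(f"  -TdS = {back_calc_entropy(dg, dh):6.1f} kJ/mol")
print(f"  dCp = {fit.delta_cp:6.1f} kJ/mol/K")

# vanadate-trapped state: straight van't Hoff plot -> linear model
kd = datasets.load_kd_table("trapped")
wt = kd[kd.variant == "WT"]
fit = vant_hoff_linear(dict(zip(wt.temperature_K, 1.0 / wt.kd1_uM)))
kd_298 = float(wt.loc[wt.temperature_K == 298, "kd1_uM"].iloc[0])
dg = delta_g_from_kd(kd_298, 298.0)
print("\nvanadate-trapped WT, first binding event at 298 K:")
print(f"  dG = {dg:6.1f} kJ/mol   (from K_D1 = {kd_298} uM)")
print(f"  dH = {fit.delta_h_t0:6.1f} kJ/mol   (linear van't Hoff, constant in T)")
print(f"  -TdS = {back_calc_entropy(dg, fit.delta_h_t0):6.1f} kJ/mol")
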