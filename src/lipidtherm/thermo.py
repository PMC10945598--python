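"""Binding thermodynamics from the temperature dependence of affinity.

Free energies come directly from dissociation constants referenced to
the 1 M standard state, ``dG = R T ln K_D[M]``.  Enthalpies come from
van't Hoff analysis of ``ln K_A`` against temperature: the linear form
assumes a temperature-independent dH, while the nonlinear form adds a
constant heat-capacity change dCp,

    ln K_A(T) = (dH_T0 - T0 dCp)/R * (1/T0 - 1/T) + dCp/R * ln(T/T0) + ln K_0,

which is linear in the parameters (dH_T0, dCp, ln K_0) and therefore
fitted by exact least squares.  The entropic term is back-calculated,
-T dS = dG - dH, so the additive identity dG = dH + (-T dS) holds by
construction in every emitted row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "R_KJ",
    "VantHoffFit",
    "delta_g_from_kd",
    "ka_molar_from_kd_uM",
    "vant_hoff_linear",
    "vant_hoff_nonlinear",
    "enthalpy_at_temperature",
    "back_calc_entropy",
    "build_thermo_signature",
]

#: Gas constant, kJ/(mol K)  (CODATA)
R_KJ = 8.314462618e-3

#: Column order of the thermodynamic-signature table.
THERMO_COLUMNS = [
    "variant",
    "n_event",
    "temperature_K",
    "dG_kJmol",
    "dG_sd",
    "dH_kJmol",
    "dH_sd",
    "mTdS_kJmol",
    "mTdS_sd",
    "dCp_kJmolK",
    "dCp_sd",
    "model",
]


@dataclass
class VantHoffFit:
    """van't Hoff fit for one binding event of one variant.

    ``delta_h_t0`` is the enthalpy at the reference temperature ``t0``
    (kJ/mol), ``delta_cp`` the heat-capacity change (kJ/mol/K, zero for
    the linear model), and ``ln_k0`` the log association constant at
    ``t0`` on the 1 M standard state.
    """

    model: str
    t0: float
    delta_h_t0: float
    delta_cp: float
    ln_k0: float
    ss_res: float
    n_temperatures: int

    def __post_init__(self) -> None:
        if self.model not in ("linear", "nonlinear"):
            raise ValueError("model must be 'linear' or 'nonlinear'")

    @property
    def delta_s_t0(self) -> float:
        """Entropy at t0 in kJ/mol/K, from dS = (dH - dG)/T."""
        return (self.delta_h_t0 - self.delta_g(self.t0)) / self.t0

    def delta_g(self, temperature: float) -> float:
        """dG(T) = -R T ln K_A(T) in kJ/mol (1 M standard state)."""
        return -R_KJ * temperature * self.predict_ln_ka(temperature)

    def predict_ln_ka(self, temperature):
        """Model ln K_A (1 M standard state) at the given temperature(s)."""
        t = np.asarray(temperature, dtype=float)
        return (
            (self.delta_h_t0 - self.t0 * self.delta_cp) / R_KJ * (1.0 / self.t0 - 1.0 / t)
            + self.delta_cp / R_KJ * np.log(t / self.t0)
            + self.ln_k0
        )


def delta_g_from_kd(kd_uM: float, temperature: float) -> float:
    """Standard binding free energy in kJ/mol from K_D in uM.

    Uses the 1 M standard state: ``dG = R T ln(K_D * 1e-6)``, negative
    for any sub-molar dissociation constant.
    """
    if kd_uM <= 0 or temperature <= 0:
        raise ValueError("K_D and temperature must be strictly positive")
    return R_KJ * temperature * float(np.log(kd_uM * 1e-6))


def ka_molar_from_kd_uM(kd_uM):
    """Association constant on the 1 M standard state from K_D in uM."""
    kd_uM = np.asarray(kd_uM, dtype=float)
    if np.any(kd_uM <= 0):
        raise ValueError("K_D must be strictly positive")
    return 1.0 / (kd_uM * 1e-6)


def _as_series(ka_series) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a {temperature: K_A per-uM} mapping to sorted arrays."""
    if isinstance(ka_series, dict):
        temps = np.array(sorted(ka_series), dtype=float)
        ka = np.array([ka_series[t] for t in temps], dtype=float)
    else:
        temps, ka = (np.asarray(a, dtype=float) for a in ka_series)
        order = np.argsort(temps)
        temps, ka = temps[order], ka[order]
    if np.any(ka <= 0) or np.any(temps <= 0):
        raise ValueError("temperatures and association constants must be positive")
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures in van't Hoff input")
    return temps, ka


def vant_hoff_linear(ka_series) -> VantHoffFit:
    """Linear van't Hoff fit: ln K_A = -dH/R * 1/T + dS/R.

    ``ka_series`` maps temperature (K) to the stepwise association
    constant in per-uM; constants are converted to the 1 M standard
    state before the log.  Requires at least two temperatures.  The
    reference temperature of the returned fit is the mean of the input
    temperatures.
    """
    temps, ka = _as_series(ka_series)
    if len(temps) < 2:
        raise ValueError("linear van't Hoff fit needs at least 2 temperatures")
    ln_ka = np.log(ka * 1e6)  # per-uM -> per-M
    design = np.column_stack([1.0 / temps, np.ones_like(temps)])
    (slope, intercept), *_ = np.linalg.lstsq(design, ln_ka, rcond=None)
    resid = ln_ka - design @ [slope, intercept]
    t0 = float(temps.mean())
    return VantHoffFit(
        model="linear",
        t0=t0,
        delta_h_t0=float(-R_KJ * slope),
        delta_cp=0.0,
        ln_k0=float(slope / t0 + intercept),
        ss_res=float(resid @ resid),
        n_temperatures=len(temps),
    )


def vant_hoff_nonlinear(ka_series, t0: float) -> VantHoffFit:
    """Nonlinear van't Hoff fit with a constant heat-capacity change.

    Least-squares estimate of (dH_T0, dCp, ln K_0) at the reference
    temperature ``t0``; the model is linear in these parameters so the
    solution is a direct linear least-squares solve.  Requires at least
    three distinct temperatures.
    """
    temps, ka = _as_series(ka_series)
    if len(temps) < 3:
        raise ValueError("nonlinear van't Hoff fit needs at least 3 temperatures")
    if not (temps.min() <= t0 <= temps.max()):
        raise ValueError(f"reference temperature {t0} K outside data range")
    ln_ka = np.log(ka * 1e6)
    x1 = (1.0 / t0 - 1.0 / temps) / R_KJ
    x2 = -t0 * x1 + np.log(temps / t0) / R_KJ
    design = np.column_stack([x1, x2, np.ones_like(temps)])
    theta, *_ = np.linalg.lstsq(design, ln_ka, rcond=None)
    resid = ln_ka - design @ theta
    return VantHoffFit(
        model="nonlinear",
        t0=float(t0),
        delta_h_t0=float(theta[0]),
        delta_cp=float(theta[1]),
        ln_k0=float(theta[2]),
        ss_res=float(resid @ resid),
        n_temperatures=len(temps),
    )


def enthalpy_at_temperature(fit: VantHoffFit, temperature: float) -> float:
    """dH(T) = dH_T0 + dCp (T - T0); constant for linear fits."""
    return fit.delta_h_t0 + fit.delta_cp * (temperature - fit.t0)


def back_calc_entropy(delta_g: float, delta_h: float) -> float:
    """Entropic term -T dS = dG - dH (kJ/mol)."""
    return delta_g - delta_h


def _select_fit(ka_series, t0: float, model: str) -> VantHoffFit:
    temps, _ = _as_series(ka_series)
    if model == "linear":
        return vant_hoff_linear(ka_series)
    if model == "nonlinear":
        return vant_hoff_nonlinear(ka_series, t0)
    if model == "auto":
        # keep the heat-capacity term only when it earns its extra
        # parameter: >50% residual reduction with >=4 temperatures
        lin = vant_hoff_linear(ka_series)
        if len(temps) < 4:
            return lin
        non = vant_hoff_nonlinear(ka_series, t0)
        if lin.ss_res > 0 and non.ss_res < 0.5 * lin.ss_res:
            return non
        return lin
    raise ValueError(f"unknown model {model!r}; use 'linear', 'nonlinear' or 'auto'")


def build_thermo_signature(
    kd_replicates: pd.DataFrame,
    t0: float = 298.0,
    model: str = "nonlinear",
    exclude: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-temperature thermodynamic signatures from replicate K_D values.

    ``kd_replicates`` is long format with columns ``variant, n_event,
    temperature_K, replicate, kd_uM``.  For every (variant, event),
    each replicate's K_D-vs-temperature series is fitted by the chosen
    van't Hoff model ('linear', 'nonlinear' or 'auto', optionally a
    ``{(variant, event): model}`` mapping), then per temperature:

    * dG from that replicate's K_D at that temperature,
    * dH from the replicate's fit evaluated at that temperature,
    * -T dS = dG - dH.

    Replicate means +/- sample SD (n-1) are reported; a single replicate
    yields SD 0.  ``exclude`` lists (variant, temperature_K) pairs to
    drop before fitting, for temperatures the user rejects explicitly.
    """
    required = {"variant", "n_event", "temperature_K", "replicate", "kd_uM"}
    missing = required - set(kd_replicates.columns)
    if missing:
        raise ValueError(f"kd_replicates is missing columns: {sorted(missing)}")
    df = kd_replicates.dropna(subset=["kd_uM"]).copy()
    for variant, temp in exclude or []:
        df = df[~((df["variant"] == variant) & (df["temperature_K"] == float(temp)))]

    records = []
    for (variant, event), grp in df.groupby(["variant", "n_event"], sort=True):
        reps = sorted(grp["replicate"].unique())
        temps = sorted(grp["temperature_K"].unique())
        per_rep: dict[int, tuple[VantHoffFit, dict[float, float]]] = {}
        for rep in reps:
            sub = grp[grp["replicate"] == rep]
            kd_by_t = dict(zip(sub["temperature_K"], sub["kd_uM"]))
            if len(kd_by_t) != len(temps):
                raise ValueError(
                    f"replicate {rep} of {variant} event {event} is missing "
                    "temperatures; replicate sets must be consistent"
                )
            ka_by_t = {t: 1.0 / kd for t, kd in kd_by_t.items()}
            m = model[(variant, event)] if isinstance(model, dict) else model
            fit_t0 = t0 if min(temps) <= t0 <= max(temps) else float(np.mean(temps))
            per_rep[rep] = (_select_fit(ka_by_t, fit_t0, m), kd_by_t)

        for temp in temps:
            dg = np.array([delta_g_from_kd(kd[temp], temp) for _, kd in per_rep.values()])
            dh = np.array(
                [enthalpy_at_temperature(f, temp) for f, _ in per_rep.values()]
            )
            mtds = dg - dh
            dcp = np.array([f.delta_cp for f, _ in per_rep.values()])
            models = {f.model for f, _ in per_rep.values()}
            nonlin = all(f.model == "nonlinear" for f, _ in per_rep.values())
            sd = (lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0)
            records.append(
                {
                    "variant": variant,
                    "n_event": int(event),
                    "temperature_K": temp,
                    "dG_kJmol": dg.mean(),
                    "dG_sd": sd(dg),
                    "dH_kJmol": dh.mean(),
                    "dH_sd": sd(dh),
                    "mTdS_kJmol": mtds.mean(),
                    "mTdS_sd": sd(mtds),
                    "dCp_kJmolK": dcp.mean() if nonlin else np.nan,
                    "dCp_sd": sd(dcp) if nonlin else np.nan,
                    "model": "/".join(sorted(models)),
                }
            )
    return pd.DataFrame.from_records(records, columns=THERMO_COLUMNS)
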