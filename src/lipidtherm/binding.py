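"""Sequential ligand-binding equilibria and titration fitting.

A protein P binds up to ``n`` copies of a lipid L in discrete, sequential
steps, ``PL(n-1) + L <=> PL(n)``, each governed by a stepwise association
constant ``K_An = [PL(n)] / ([PL(n-1)] [L])``.  Native mass spectrometry
resolves every bound state in one spectrum, so the observable is the mole
fraction of each species along a titration of total lipid.  This module
evaluates the binding polynomial, solves the free-lipid mass balance, and
fits stepwise constants to measured mole fractions by minimising a
pseudo-chi-square (the plain sum of squared fraction residuals).

Concentrations are in micromolar throughout; association constants are
per-micromolar (their reciprocals are the familiar K_D values in uM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationSeries",
    "BindingConstants",
    "BindingFit",
    "species_fractions",
    "solve_free_ligand",
    "predict_mole_fractions",
    "pseudo_chi2",
    "fit_binding_constants",
    "fit_replicates",
    "kd_from_ka",
    "ka_from_kd",
    "read_titration_csv",
    "fit_summary_table",
]

#: Required columns of the long-format titration CSV.
TITRATION_COLUMNS = [
    "variant",
    "temperature_K",
    "replicate",
    "protein_total_uM",
    "ligand_total_uM",
    "n_bound",
    "mole_fraction",
]


@dataclass
class TitrationSeries:
    """One titration: a single variant at one temperature, one replicate.

    ``fractions[i, n]`` is the mole fraction of the species with ``n``
    lipids bound at titration point ``i``.  Rows are renormalised to sum
    to one on construction; a row that misses unity by more than 1e-6
    before renormalisation raises ``ValueError``.
    """

    variant: str
    temperature: float
    protein_total: float
    ligand_total: np.ndarray
    fractions: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or len(self.ligand_total) != len(self.fractions):
            raise ValueError("fractions must be (n_points, n_species) matching ligand_total")
        if np.any(self.ligand_total < 0):
            raise ValueError("ligand_total must be non-negative")
        if np.any(np.diff(self.ligand_total) <= 0):
            raise ValueError("ligand_total must be strictly increasing")
        if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-9):
            raise ValueError("mole fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each mole-fraction vector must sum to 1 within 1e-6")
        self.fractions = self.fractions / sums[:, None]

    @property
    def n_species(self) -> int:
        return self.fractions.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.ligand_total)


@dataclass
class BindingConstants:
    """Stepwise association constants (per uM) at one temperature."""

    ka: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.ka = np.atleast_1d(np.asarray(self.ka, dtype=float))
        if np.any(self.ka <= 0):
            raise ValueError("association constants must be strictly positive")

    @property
    def n_events(self) -> int:
        return len(self.ka)

    @property
    def kd(self) -> np.ndarray:
        return 1.0 / self.ka


@dataclass
class BindingFit:
    """Result of fitting one titration replicate."""

    constants: BindingConstants
    pseudo_chi2: float
    r_squared: float
    converged: bool
    n_data: int
    series: TitrationSeries | None = field(default=None, repr=False)


def species_fractions(ka, l_free: float) -> np.ndarray:
    """Mole fractions of the 0..n lipid-bound species at free lipid ``l_free``.

    Evaluates the binding polynomial: the statistical weight of the
    n-bound species is ``l_free**n * prod(ka[:n])`` and fractions are the
    weights over their sum, so ``F[n] / F[n-1] == ka[n-1] * l_free``.
    """
    ka = np.atleast_1d(np.asarray(ka, dtype=float))
    if np.any(ka <= 0):
        raise ValueError("association constants must be strictly positive")
    if l_free < 0:
        raise ValueError("free ligand concentration must be non-negative")
    # weights[n] = l_free^n * K_A1 ... K_An, accumulated to stay stable
    weights = np.concatenate([[1.0], np.cumprod(ka * l_free)])
    return weights / weights.sum()


def _bound_per_protein(ka: np.ndarray, l_free: float) -> float:
    """Mean number of lipids bound per protein at ``l_free``."""
    f = species_fractions(ka, l_free)
    return float(np.arange(len(f)) @ f)


def solve_free_ligand(ka, protein_total: float, ligand_total: float) -> float:
    """Free lipid concentration satisfying the titration mass balance.

    Solves ``l_free + protein_total * sum(i * F_i(l_free)) == ligand_total``
    for ``l_free`` on ``[0, ligand_total]``.  The residual is strictly
    increasing in ``l_free``, so a bracketed Brent search converges
    unconditionally.
    """
    ka = np.atleast_1d(np.asarray(ka, dtype=float))
    if protein_total < 0 or ligand_total < 0:
        raise ValueError("concentrations must be non-negative")
    if ligand_total == 0:
        return 0.0
    if protein_total == 0:
        return float(ligand_total)

    def residual(l_free: float) -> float:
        return l_free + protein_total * _bound_per_protein(ka, l_free) - ligand_total

    l_free, info = brentq(
        residual, 0.0, ligand_total, xtol=1e-14, rtol=8.9e-16, maxiter=200, full_output=True
    )
    if not info.converged:
        raise RuntimeError(
            f"free-ligand solve did not converge: residual {residual(l_free):.3e} "
            f"at l_free={l_free:.6g} after {info.iterations} iterations"
        )
    return float(l_free)


def predict_mole_fractions(ka, protein_total: float, ligand_total_series) -> np.ndarray:
    """Model mole fractions at each point of a titration.

    Returns an ``(n_points, n_events + 1)`` matrix; each row sums to one
    and the row at zero total lipid is ``(1, 0, ..., 0)``.
    """
    ka = np.atleast_1d(np.asarray(ka, dtype=float))
    ligand_total_series = np.asarray(ligand_total_series, dtype=float)
    out = np.empty((len(ligand_total_series), len(ka) + 1))
    for i, l_total in enumerate(ligand_total_series):
        l_free = solve_free_ligand(ka, protein_total, l_total)
        out[i] = species_fractions(ka, l_free)
    return out


def pseudo_chi2(f_exp, f_calc) -> float:
    """Sum of squared mole-fraction residuals over all points and species."""
    f_exp = np.asarray(f_exp, dtype=float)
    f_calc = np.asarray(f_calc, dtype=float)
    if f_exp.shape != f_calc.shape:
        raise ValueError(f"shape mismatch: {f_exp.shape} vs {f_calc.shape}")
    return float(np.sum((f_exp - f_calc) ** 2))


def _r_squared(f_exp: np.ndarray, f_calc: np.ndarray) -> float:
    ss_res = np.sum((f_exp - f_calc) ** 2)
    ss_tot = np.sum((f_exp - f_exp.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")


# K_D starting guesses (uM) spanned per event by the multistart grid.
_START_KDS = (0.1, 1.0, 10.0)


def fit_binding_constants(
    series: TitrationSeries,
    n_events: int | None = None,
    *,
    multistart: bool = True,
) -> BindingFit:
    """Fit stepwise association constants to one titration replicate.

    The fit minimises the pseudo-chi-square between measured and model
    mole fractions, with the free-lipid mass balance solved exactly at
    every evaluation.  Optimisation runs in ``ln K_A`` space so the
    constants stay positive by construction.  With ``multistart`` (the
    default), starting K_D values spanning 0.1-10 uM per event are tried
    and the lowest pseudo-chi-square wins; otherwise only the 1 uM start
    is used.
    """
    if n_events is None:
        n_events = series.n_species - 1
    if n_events not in (1, 2, 3):
        raise ValueError("n_events must be 1, 2 or 3")
    if series.n_species != n_events + 1:
        raise ValueError(
            f"series has {series.n_species} species columns but n_events={n_events}"
        )
    informative = np.count_nonzero(series.ligand_total > 0)
    if informative < n_events + 1:
        raise ValueError(
            f"need at least {n_events + 1} non-zero titration points to fit "
            f"{n_events} events; got {informative}"
        )

    f_exp = series.fractions

    def residuals(log_ka: np.ndarray) -> np.ndarray:
        f_calc = predict_mole_fractions(
            np.exp(log_ka), series.protein_total, series.ligand_total
        )
        return (f_calc - f_exp).ravel()

    starts = (
        itertools.product(_START_KDS, repeat=n_events) if multistart else [(1.0,) * n_events]
    )
    best = None
    for start_kd in starts:
        x0 = np.log(1.0 / np.asarray(start_kd))
        sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None

    ka = np.exp(best.x)
    f_calc = predict_mole_fractions(ka, series.protein_total, series.ligand_total)
    chi2 = pseudo_chi2(f_exp, f_calc)
    if not best.success:
        warnings.warn(
            f"binding fit for {series.variant} at {series.temperature} K did not "
            f"report convergence (status {best.status})",
            RuntimeWarning,
            stacklevel=2,
        )
    max_occupancy = predict_mole_fractions(ka, series.protein_total, series.ligand_total)[
        :, -1
    ].max()
    if max_occupancy < 0.01:
        warnings.warn(
            f"occupancy of the {n_events}-bound state never exceeds 1%; the last "
            "binding event is weakly constrained (possible rank deficiency)",
            RuntimeWarning,
            stacklevel=2,
        )
    return BindingFit(
        constants=BindingConstants(ka=ka, temperature=series.temperature),
        pseudo_chi2=chi2,
        r_squared=_r_squared(f_exp, f_calc),
        converged=bool(best.success),
        n_data=f_exp.size,
        series=series,
    )


def fit_replicates(
    replicates: list[TitrationSeries], n_events: int | None = None, **kwargs
) -> list[BindingFit]:
    """Fit each replicate independently (replicate statistics downstream)."""
    return [fit_binding_constants(s, n_events, **kwargs) for s in replicates]


def kd_from_ka(constants: BindingConstants) -> np.ndarray:
    """Stepwise dissociation constants K_D = 1/K_A, in uM."""
    return constants.kd


def ka_from_kd(kd) -> np.ndarray:
    """Stepwise association constants (per uM) from K_D values (uM)."""
    kd = np.atleast_1d(np.asarray(kd, dtype=float))
    if np.any(kd <= 0):
        raise ValueError("dissociation constants must be strictly positive")
    return 1.0 / kd


# ---------------------------------------------------------------------------
# CSV interfaces


def read_titration_csv(path_or_buffer, intensity: bool = False) -> list[TitrationSeries]:
    """Read long-format titration data into TitrationSeries objects.

    Expects the columns ``variant, temperature_K, replicate,
    protein_total_uM, ligand_total_uM, n_bound, mole_fraction`` (or
    ``intensity`` in place of ``mole_fraction`` with ``intensity=True``,
    in which case per-point intensities are normalised to fractions).
    Fractions are renormalised within each titration point on load.
    """
    df = pd.read_csv(path_or_buffer)
    value_col = "intensity" if intensity else "mole_fraction"
    required = TITRATION_COLUMNS[:-1] + [value_col]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("titration CSV contains no data rows")

    series_list = []
    for (variant, temp, rep), grp in df.groupby(
        ["variant", "temperature_K", "replicate"], sort=True
    ):
        wide = grp.pivot_table(
            index="ligand_total_uM", columns="n_bound", values=value_col, aggfunc="first"
        ).sort_index()
        fractions = wide.to_numpy(dtype=float)
        if np.isnan(fractions).any():
            bad = wide.index[np.isnan(fractions).any(axis=1)].tolist()
            raise ValueError(
                f"incomplete species set for {variant} at {temp} K, replicate {rep}, "
                f"ligand_total {bad}"
            )
        fractions = fractions / fractions.sum(axis=1, keepdims=True)
        series_list.append(
            TitrationSeries(
                variant=str(variant),
                temperature=float(temp),
                protein_total=float(grp["protein_total_uM"].iloc[0]),
                ligand_total=wide.index.to_numpy(dtype=float),
                fractions=fractions,
                replicate=int(rep),
            )
        )
    return series_list


def fit_summary_table(fits: list[BindingFit]) -> pd.DataFrame:
    """Replicate mean +/- SD of K_D per (variant, temperature), wide format.

    Mirrors the conventional dissociation-constant table: one row per
    variant and temperature with ``KD{n}_uM``/``KD{n}_sd`` columns and
    the goodness of fit of the poorest replicate.
    """
    rows: dict[tuple[str, float], list[BindingFit]] = {}
    for f in fits:
        key = (f.series.variant, f.series.temperature)
        rows.setdefault(key, []).append(f)

    records = []
    for (variant, temp), group in sorted(rows.items()):
        rec: dict[str, object] = {"variant": variant, "temperature_K": temp}
        n_events = max(f.constants.n_events for f in group)
        for n in range(1, 4):
            if n <= n_events:
                kds = np.array([f.constants.kd[n - 1] for f in group])
                rec[f"KD{n}_uM"] = kds.mean()
                rec[f"KD{n}_sd"] = kds.std(ddof=1) if len(kds) > 1 else 0.0
            else:
                rec[f"KD{n}_uM"] = np.nan
                rec[f"KD{n}_sd"] = np.nan
        worst = min(group, key=lambda f: f.r_squared)
        rec["R2_worst"] = worst.r_squared
        rec["chi2_worst"] = worst.pseudo_chi2
        records.append(rec)
    return pd.DataFrame.from_records(records)
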