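"""Double and triple thermodynamic mutant-cycle algebra.

A double mutant cycle compares a protein P, single mutants PX and PY,
and the double mutant PXY.  With mutant-minus-wild-type differences
ddX = X_mut - X_P (X any of dG, dH, -TdS), the interaction (coupling)
term is the deviation from additivity,

    ddX_int = ddX_PX + ddX_PY - ddX_PXY,

positive when the two residues cooperate favourably.  A triple cycle is
the second-order difference: the change of a pairwise coupling when a
third residue is mutated,

    ddX_int3 = ddX_int(X,Y | P) - ddX_int(X,Y | PZ),

which is independent of which of the three mutations plays the role of
Z (path independence) when all corners come from one consistent table.

Uncertainties are propagated in quadrature throughout, treating the
corner measurements as independent.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "propagate_sd",
    "delta_delta",
    "double_cycle_coupling",
    "triple_cycle_coupling",
    "cycle_consistency_check",
    "double_cycle_from_signature",
    "triple_cycle_from_signature",
    "coupling_from_deltas",
]

#: Quantity name -> (value column, sd column) in signature tables.
_SIGNATURE_COLS = {
    "G": ("dG_kJmol", "dG_sd"),
    "H": ("dH_kJmol", "dH_sd"),
    "mTdS": ("mTdS_kJmol", "mTdS_sd"),
}

#: Quantity name -> (value column, sd column) in delta (ddX) tables.
_DELTA_COLS = {
    "G": ("ddG", "ddG_sd"),
    "H": ("ddH", "ddH_sd"),
    "mTdS": ("ddmTdS", "ddmTdS_sd"),
}


class Measurement(NamedTuple):
    """A value with its standard deviation (kJ/mol)."""

    value: float
    sd: float = 0.0

    def __add__(self, other: "Measurement") -> "Measurement":
        return Measurement(self.value + other.value, propagate_sd([self.sd, other.sd]))

    def __sub__(self, other: "Measurement") -> "Measurement":
        return Measurement(self.value - other.value, propagate_sd([self.sd, other.sd]))


def propagate_sd(sds) -> float:
    """Quadrature combination of independent standard deviations."""
    sds = np.asarray(sds, dtype=float)
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    return float(np.sqrt(np.sum(sds**2)))


def delta_delta(x_mutant: Measurement, x_wild_type: Measurement) -> Measurement:
    """Mutant-minus-wild-type difference with quadrature SD."""
    x_mutant, x_wild_type = Measurement(*x_mutant), Measurement(*x_wild_type)
    return x_mutant - x_wild_type


def double_cycle_coupling(
    ddx_px: Measurement, ddx_py: Measurement, ddx_pxy: Measurement
) -> Measurement:
    """Pairwise coupling ddX_int = ddX_PX + ddX_PY - ddX_PXY."""
    ddx_px, ddx_py, ddx_pxy = (Measurement(*m) for m in (ddx_px, ddx_py, ddx_pxy))
    return Measurement(
        ddx_px.value + ddx_py.value - ddx_pxy.value,
        propagate_sd([ddx_px.sd, ddx_py.sd, ddx_pxy.sd]),
    )


def triple_cycle_coupling(
    pair_int_wild_background: Measurement, pair_int_mutant_background: Measurement
) -> Measurement:
    """Third-order coupling: pairwise coupling in the wild-type background
    minus the same pairwise coupling in the third-mutation background."""
    a = Measurement(*pair_int_wild_background)
    b = Measurement(*pair_int_mutant_background)
    return a - b


def cycle_consistency_check(
    g_int: Measurement, h_int: Measurement, mtds_int: Measurement, tol: float = 1e-9
) -> dict:
    """Check the identity ddG_int = ddH_int + dd(-TdS)_int.

    Returns the residual and whether it is within ``tol``.  On
    full-precision inputs the residual is zero by construction; on
    values rounded for printing it reports the rounding residual rather
    than failing.
    """
    residual = g_int.value - (h_int.value + mtds_int.value)
    return {"residual": residual, "consistent": abs(residual) <= tol, "tol": tol}


# ---------------------------------------------------------------------------
# Table-driven helpers


def _lookup(
    signature: pd.DataFrame, variant: str, event: int, temperature: float, quantity: str
) -> Measurement:
    col, sd_col = _SIGNATURE_COLS[quantity]
    rows = signature[
        (signature["variant"] == variant)
        & (signature["n_event"] == event)
        & (signature["temperature_K"] == temperature)
    ]
    if len(rows) != 1:
        raise KeyError(
            f"expected exactly one signature row for {variant!r}, event {event}, "
            f"{temperature} K; found {len(rows)}"
        )
    return Measurement(float(rows[col].iloc[0]), float(rows[sd_col].iloc[0]))


def double_cycle_from_signature(
    signature: pd.DataFrame,
    wild_type: str,
    mutant_x: str,
    mutant_y: str,
    double_mutant: str,
    event: int,
    temperature: float,
    quantities: tuple[str, ...] = ("G", "H", "mTdS"),
) -> dict[str, dict]:
    """Full double-cycle analysis from a thermodynamic-signature table.

    For each requested quantity, computes the three mutant-minus-wild-type
    differences and their coupling.  Returns
    ``{quantity: {"dd": {label: Measurement}, "int": Measurement}}``.
    """
    out: dict[str, dict] = {}
    for q in quantities:
        wt = _lookup(signature, wild_type, event, temperature, q)
        dd = {
            label: delta_delta(_lookup(signature, label, event, temperature, q), wt)
            for label in (mutant_x, mutant_y, double_mutant)
        }
        out[q] = {
            "dd": dd,
            "int": double_cycle_coupling(dd[mutant_x], dd[mutant_y], dd[double_mutant]),
        }
    return out


def triple_cycle_from_signature(
    signature: pd.DataFrame,
    wild_type: str,
    singles: dict[str, str],
    doubles: dict[frozenset, str],
    triple: str,
    event: int,
    temperature: float,
    quantity: str = "G",
    route_tol: float = 1e-9,
) -> dict:
    """Third-order coupling from all eight corners, along all three routes.

    ``singles`` maps mutation names (e.g. "X") to variant labels and
    ``doubles`` maps frozensets of two mutation names to the
    corresponding double-mutant labels.  Each route treats one mutation
    as the background and computes the pairwise coupling of the other
    two in the wild-type and in that background, then differences them.
    Routes agree exactly on a consistent table; if they disagree beyond
    ``route_tol`` (as they may on independently rounded inputs) a
    warning entry is set rather than raising.
    """
    names = sorted(singles)
    if len(names) != 3 or set(map(frozenset, doubles)) != {
        frozenset(p) for p in ((names[0], names[1]), (names[0], names[2]), (names[1], names[2]))
    }:
        raise ValueError("triple cycle needs 3 singles and the 3 matching doubles")

    def meas(label: str) -> Measurement:
        return _lookup(signature, label, event, temperature, quantity)

    routes = {}
    for z in names:
        x, y = (n for n in names if n != z)
        # pairwise coupling of (x, y) in the wild-type background ...
        wt = meas(wild_type)
        dd = lambda label: delta_delta(meas(label), wt)  # noqa: E731
        int_wt = double_cycle_coupling(
            dd(singles[x]), dd(singles[y]), dd(doubles[frozenset((x, y))])
        )
        # ... and in the z background, where corners gain the z mutation
        bg = meas(singles[z])
        ddz = lambda label: delta_delta(meas(label), bg)  # noqa: E731
        int_bg = double_cycle_coupling(
            ddz(doubles[frozenset((x, z))]), ddz(doubles[frozenset((y, z))]), ddz(triple)
        )
        routes[z] = {
            "pair": (x, y),
            "int_wild_background": int_wt,
            "int_mutant_background": int_bg,
            "coupling": triple_cycle_coupling(int_wt, int_bg),
        }

    values = [r["coupling"].value for r in routes.values()]
    spread = max(values) - min(values)
    return {
        "routes": routes,
        "coupling": Measurement(float(np.mean(values)), routes[names[0]]["coupling"].sd),
        "route_spread": spread,
        "routes_agree": spread <= route_tol,
    }


def coupling_from_deltas(
    deltas: pd.DataFrame,
    mutant_x: str,
    mutant_y: str,
    double_mutant: str,
    temperature: float,
    background: str = "WT",
    quantities: tuple[str, ...] = ("G", "H", "mTdS"),
    **filters,
) -> dict[str, Measurement]:
    """Pairwise couplings from a table of ddX differences.

    ``deltas`` holds mutant-minus-background differences with columns
    ``background, variant, temperature_K, ddG, ddG_sd, ...`` (extra
    key/value pairs in ``filters``, e.g. ``condition="trapped"`` or
    ``event=1``, restrict the rows first).  This is the entry point when
    coupling analysis starts from a published difference table rather
    than from raw titrations.
    """
    df = deltas
    for col, val in filters.items():
        df = df[df[col] == val]
    df = df[(df["background"] == background) & (df["temperature_K"] == temperature)]

    def pick(variant: str, q: str) -> Measurement:
        col, sd_col = _DELTA_COLS[q]
        rows = df[df["variant"] == variant]
        if len(rows) != 1:
            raise KeyError(
                f"expected one delta row for {variant!r} in background {background!r} "
                f"at {temperature} K (filters {filters}); found {len(rows)}"
            )
        return Measurement(float(rows[col].iloc[0]), float(rows[sd_col].iloc[0]))

    return {
        q: double_cycle_coupling(
            pick(mutant_x, q), pick(mutant_y, q), pick(double_mutant, q)
        )
        for q in quantities
    }
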