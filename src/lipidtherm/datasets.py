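"""Packaged reference tables for MsbA-KDL binding.

Published replicate-mean measurements for Kdo2-lipid A (KDL) binding to
the E. coli lipopolysaccharide flippase MsbA and a panel of binding-site
mutants, in two conformational states: the untrapped transporter
("apo") and the ADP/vanadate-trapped outward-facing state ("trapped").

Three tables are shipped:

* :func:`load_kd_table` - stepwise equilibrium dissociation constants
  (mean +/- SD, n=3) per variant, temperature and binding event, with
  the goodness of fit of the poorest replicate.
* :func:`load_thermo_table` - per-temperature thermodynamic signatures
  (dG, dH, -TdS, dCp; mean +/- SD).
* :func:`load_coupling_table` - mutant-minus-background differences
  (ddG, ddH, dd(-TdS)) for mutant-cycle analysis, including blocks where
  the background is itself a single mutant (for triple cycles), plus
  the reported pairwise couplings for double-mutant rows.

These are analysis inputs for the worked examples and for validating
the cycle algebra; raw titration spectra are not included.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_kd_table", "load_thermo_table", "load_coupling_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_kd_table(condition: str | None = None) -> pd.DataFrame:
    """Stepwise K_D values (uM, mean +/- SD) per variant and temperature.

    ``condition`` filters to ``"apo"`` or ``"trapped"`` if given.
    """
    df = _read("msba_kdl_kd.csv")
    return df if condition is None else df[df["condition"] == condition].reset_index(drop=True)


def load_thermo_table(condition: str | None = None) -> pd.DataFrame:
    """Thermodynamic signatures (kJ/mol) per variant, temperature, event."""
    df = _read("msba_kdl_thermo.csv")
    return df if condition is None else df[df["condition"] == condition].reset_index(drop=True)


def load_coupling_table(condition: str | None = None) -> pd.DataFrame:
    """Mutant-minus-background ddX differences for cycle analysis."""
    df = _read("msba_kdl_coupling.csv")
    return df if condition is None else df[df["condition"] == condition].reset_index(drop=True)
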