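"""End-to-end analysis: titrations -> binding constants -> thermodynamic
signatures -> mutant-cycle couplings.

The stages are independently usable library functions; ``run_pipeline``
chains them under a single :class:`AnalysisConfig` and returns a
:class:`ReportBundle` whose tables use the documented CSV schemas.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, cycles, thermo

logger = logging.getLogger("lipidtherm")

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_fit",
    "replicate_kd_table",
    "run_vant_hoff",
    "run_cycles",
    "run_pipeline",
    "summarize_signature",
    "plot_signature",
]

CYCLE_COLUMNS = [
    "pair",
    "background",
    "temperature_K",
    "ddG",
    "ddG_sd",
    "ddH",
    "ddH_sd",
    "ddmTdS",
    "ddmTdS_sd",
    "ddG_int",
    "ddG_int_sd",
    "ddH_int",
    "ddH_int_sd",
    "ddmTdS_int",
    "ddmTdS_int_sd",
    "order",
]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``n_events`` maps variant labels to the number of sequential binding
    events fitted for that variant (variants absent from the mapping use
    ``default_n_events``).  ``exclude`` lists (variant, temperature_K)
    pairs dropped before van't Hoff fitting.  ``model`` is 'linear',
    'nonlinear' or 'auto', optionally per (variant, event).  ``cycles``
    holds cycle definitions: mappings with keys ``wild_type``,
    ``mutant_x``, ``mutant_y``, ``double_mutant`` (double) or
    ``wild_type``, ``singles``, ``doubles``, ``triple`` (triple), plus
    ``event`` and ``temperatures``.
    """

    input_path: str | None = None
    n_events: dict[str, int] = field(default_factory=dict)
    default_n_events: int | None = None
    t0: float = 298.0
    model: str | dict = "nonlinear"
    exclude: list[tuple[str, float]] = field(default_factory=list)
    cycles: list[dict] = field(default_factory=list)
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw["exclude"] = [tuple(x) for x in raw.get("exclude", [])]
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus a run log."""

    fit_table: pd.DataFrame
    kd_replicates: pd.DataFrame
    thermo_table: pd.DataFrame
    cycle_table: pd.DataFrame
    log: list[str]

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fit_table.to_csv(out / "binding_fits.csv", index=False)
        self.kd_replicates.to_csv(out / "kd_replicates.csv", index=False)
        self.thermo_table.to_csv(out / "thermo_signatures.csv", index=False)
        self.cycle_table.to_csv(out / "cycle_couplings.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def run_fit(
    titrations: pd.DataFrame | str,
    n_events: dict[str, int] | None = None,
    default_n_events: int | None = None,
) -> list[binding.BindingFit]:
    """Fit every replicate titration in a long-format table or CSV path."""
    if isinstance(titrations, (str, Path)):
        series_list = binding.read_titration_csv(titrations)
    else:
        import io

        buf = io.StringIO()
        titrations.to_csv(buf, index=False)
        buf.seek(0)
        series_list = binding.read_titration_csv(buf)
    n_events = n_events or {}
    fits = []
    for s in series_list:
        n = n_events.get(s.variant, default_n_events)
        fits.append(binding.fit_binding_constants(s, n))
        logger.info(
            "fit %s %gK rep%d: chi2=%.3g R2=%.4f converged=%s",
            s.variant,
            s.temperature,
            s.replicate,
            fits[-1].pseudo_chi2,
            fits[-1].r_squared,
            fits[-1].converged,
        )
    return fits


def replicate_kd_table(fits: list[binding.BindingFit]) -> pd.DataFrame:
    """Long-format per-replicate K_D table for van't Hoff analysis."""
    records = [
        {
            "variant": f.series.variant,
            "n_event": n + 1,
            "temperature_K": f.series.temperature,
            "replicate": f.series.replicate,
            "kd_uM": f.constants.kd[n],
        }
        for f in fits
        for n in range(f.constants.n_events)
    ]
    return pd.DataFrame.from_records(records)


def run_vant_hoff(
    kd_replicates: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Thermodynamic signatures from per-replicate K_D values."""
    return thermo.build_thermo_signature(
        kd_replicates, t0=config.t0, model=config.model, exclude=config.exclude
    )


def _cycle_rows_double(signature, spec, temperature) -> list[dict]:
    res = cycles.double_cycle_from_signature(
        signature,
        spec["wild_type"],
        spec["mutant_x"],
        spec["mutant_y"],
        spec["double_mutant"],
        spec.get("event", 1),
        temperature,
    )
    rows = []
    for label in (spec["mutant_x"], spec["mutant_y"], spec["double_mutant"]):
        row = {
            "pair": label,
            "background": spec["wild_type"],
            "temperature_K": temperature,
            "order": "double",
        }
        for q, (col, _) in zip(("G", "H", "mTdS"), cycles._DELTA_COLS.values()):
            m = res[q]["dd"][label]
            row[col], row[col + "_sd"] = m.value, m.sd
            if label == spec["double_mutant"]:
                mi = res[q]["int"]
                row[col + "_int"], row[col + "_int_sd"] = mi.value, mi.sd
        rows.append(row)
    return rows


def _cycle_rows_triple(signature, spec, temperature) -> list[dict]:
    rows = []
    for quantity in ("G", "H", "mTdS"):
        res = cycles.triple_cycle_from_signature(
            signature,
            spec["wild_type"],
            spec["singles"],
            {frozenset(k.split("+")): v for k, v in spec["doubles"].items()},
            spec["triple"],
            spec.get("event", 1),
            temperature,
            quantity=quantity,
        )
        col, _ = cycles._DELTA_COLS[quantity]
        for z, r in res["routes"].items():
            label = f"{'/'.join(r['pair'])} | {z}"
            existing = next(
                (row for row in rows if row["pair"] == label), None
            )
            row = existing or {
                "pair": label,
                "background": spec["wild_type"],
                "temperature_K": temperature,
                "order": "triple",
            }
            row[col + "_int"], row[col + "_int_sd"] = (
                r["coupling"].value,
                r["coupling"].sd,
            )
            if existing is None:
                rows.append(row)
    return rows


def run_cycles(signature: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Evaluate every configured mutant cycle against a signature table."""
    rows: list[dict] = []
    for spec in config.cycles:
        temps = spec.get("temperatures")
        if temps is None:
            temps = sorted(signature["temperature_K"].unique())
        for temperature in temps:
            if "triple" in spec:
                rows.extend(_cycle_rows_triple(signature, spec, temperature))
            else:
                rows.extend(_cycle_rows_double(signature, spec, temperature))
    return pd.DataFrame.from_records(rows, columns=CYCLE_COLUMNS)


def run_pipeline(
    config: AnalysisConfig, titrations: pd.DataFrame | None = None
) -> ReportBundle:
    """Chain fit -> van't Hoff -> cycles and assemble the report bundle.

    ``titrations`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``config.input_path`` is read.
    """
    log = [f"config {config.content_hash()}"]
    if titrations is None:
        if config.input_path is None:
            raise ValueError("no input: provide titrations or config.input_path")
        titrations = config.input_path
    fits = run_fit(titrations, config.n_events, config.default_n_events)
    if not all(f.converged for f in fits):
        bad = [f.series.variant for f in fits if not f.converged]
        log.append(f"WARNING: non-converged fits for {sorted(set(bad))}")
    fit_table = binding.fit_summary_table(fits)
    log.append(f"fit: {len(fits)} replicate titrations, {len(fit_table)} variant/temperature rows")
    kd_reps = replicate_kd_table(fits)
    signature = run_vant_hoff(kd_reps, config)
    log.append(f"vanthoff: {len(signature)} signature rows (t0={config.t0} K)")
    cycle_table = run_cycles(signature, config)
    log.append(f"cycles: {len(cycle_table)} rows from {len(config.cycles)} cycle definitions")
    bundle = ReportBundle(
        fit_table=fit_table,
        kd_replicates=kd_reps,
        thermo_table=signature,
        cycle_table=cycle_table,
        log=log,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def summarize_signature(thermo_table: pd.DataFrame) -> pd.DataFrame:
    """Stacked-bar-ready records of dG / dH / -TdS per variant and event.

    One record per (variant, event, temperature) with the three terms;
    the additive identity dG = dH + (-TdS) is asserted on each row.
    """
    out = thermo_table[
        ["variant", "n_event", "temperature_K", "dG_kJmol", "dH_kJmol", "mTdS_kJmol"]
    ].copy()
    resid = out["dG_kJmol"] - (out["dH_kJmol"] + out["mTdS_kJmol"])
    # printed tables carry rounding; full-precision tables close exactly
    if np.abs(resid).max() > 0.2:
        raise ValueError(
            "thermodynamic identity dG = dH + (-TdS) violated beyond rounding "
            f"(max residual {np.abs(resid).max():.3g} kJ/mol)"
        )
    return out.reset_index(drop=True)


def plot_signature(thermo_table: pd.DataFrame, temperature: float, ax=None):
    """Grouped bars of dG, dH and -TdS per variant at one temperature."""
    import matplotlib.pyplot as plt

    data = summarize_signature(thermo_table)
    data = data[data["temperature_K"] == temperature]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * data["variant"].nunique() + 2, 4))
    width = 0.27
    for i, (label, col) in enumerate(
        [("dG", "dG_kJmol"), ("dH", "dH_kJmol"), ("-TdS", "mTdS_kJmol")]
    ):
        grouped = data.groupby("variant", sort=False)[col].first()
        ax.bar(np.arange(len(grouped)) + (i - 1) * width, grouped, width, label=label)
    ax.set_xticks(range(data["variant"].nunique()))
    ax.set_xticklabels(data["variant"].unique(), rotation=45, ha="right")
    ax.set_ylabel("kJ/mol")
    ax.set_title(f"Binding thermodynamics at {temperature:g} K")
    ax.axhline(0, color="k", lw=0.8)
    ax.legend()
    return ax
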