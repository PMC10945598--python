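"""Synthetic titration panels with known thermodynamic ground truth.

The generator runs the analysis model forward: per-variant, per-event
parameters (dG_T0, dH_T0, dCp at a reference temperature T0) give an
association constant at any temperature through the nonlinear van't
Hoff expression; exact species mole fractions then follow from the
sequential binding model with the free-lipid mass balance solved
exactly; finally Gaussian noise is added to the mole fractions (the
observable that carries replicate scatter after spectral
deconvolution), clipped to [0, 1] and renormalised.

Panels for mutant-cycle studies are built from a wild-type baseline
with additive per-mutation shifts and explicit pairwise (and optional
third-order) interaction terms, so the coupling recovered by the full
pipeline has a known design value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TITRATION_COLUMNS, predict_mole_fractions
from .thermo import R_KJ

__all__ = [
    "EventThermo",
    "GroundTruth",
    "NoiseModel",
    "CycleDesign",
    "ka_from_thermo",
    "generate_titration_series",
    "generate_variant_panel",
    "make_cycle_truth",
    "truth_table",
    "DEFAULT_LIGAND_GRID",
    "DEFAULT_TEMPERATURES",
]

#: Default titrant grid, uM: 10 points from 0 to 10 uM, denser at the
#: low end where the tightest binding event turns over.
DEFAULT_LIGAND_GRID = np.array([0.0, 0.2, 0.5, 1.0, 1.5, 2.5, 4.0, 6.0, 8.0, 10.0])

#: Default temperature set, K.
DEFAULT_TEMPERATURES = (288.0, 293.0, 298.0, 303.0)

#: Default total protein concentration, uM.
DEFAULT_PROTEIN_UM = 0.39


@dataclass(frozen=True)
class EventThermo:
    """Thermodynamic parameters of one binding event at T0 (kJ/mol[/K])."""

    dg_t0: float
    dh_t0: float
    dcp: float = 0.0


@dataclass
class GroundTruth:
    """Per-variant, per-event thermodynamic truth at a common T0."""

    t0: float
    variants: dict[str, list[EventThermo]]

    def n_events(self, variant: str) -> int:
        return len(self.variants[variant])


@dataclass(frozen=True)
class NoiseModel:
    """Replicate structure and mole-fraction noise of a synthetic panel."""

    fraction_noise_sd: float = 0.01
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_noise_sd < 0:
            raise ValueError("fraction_noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def ka_from_thermo(
    truth: GroundTruth, variant: str, event: int, temperature: float
) -> float:
    """Stepwise association constant (per uM) at ``temperature``.

    Forward-evaluates the nonlinear van't Hoff expression from the
    event's (dG_T0, dH_T0, dCp): ln K_0 = -dG_T0/(R T0), then dH(T) and
    dS(T) extrapolate with the constant dCp.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    ev = truth.variants[variant][event - 1]
    t0 = truth.t0
    ln_k0 = -ev.dg_t0 / (R_KJ * t0)
    ln_ka = (
        (ev.dh_t0 - t0 * ev.dcp) / R_KJ * (1.0 / t0 - 1.0 / temperature)
        + ev.dcp / R_KJ * np.log(temperature / t0)
        + ln_k0
    )
    return float(np.exp(ln_ka) * 1e-6)  # per-M -> per-uM


def _variant_ka(truth: GroundTruth, variant: str, temperature: float) -> np.ndarray:
    return np.array(
        [
            ka_from_thermo(truth, variant, ev, temperature)
            for ev in range(1, truth.n_events(variant) + 1)
        ]
    )


def generate_titration_series(
    truth: GroundTruth,
    variant: str,
    temperature: float,
    noise: NoiseModel,
    protein_total: float = DEFAULT_PROTEIN_UM,
    ligand_totals=DEFAULT_LIGAND_GRID,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy replicate titrations for one variant at one temperature.

    Returns a long-format DataFrame in the titration CSV schema.  Exact
    model fractions receive i.i.d. Gaussian noise of SD
    ``noise.fraction_noise_sd``, are clipped to [0, 1] and renormalised
    per titration point.  Output is bit-reproducible for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    ligand_totals = np.asarray(ligand_totals, dtype=float)
    ka = _variant_ka(truth, variant, temperature)
    exact = predict_mole_fractions(ka, protein_total, ligand_totals)

    records = []
    for rep in range(1, noise.n_replicates + 1):
        noisy = exact + rng.normal(0.0, noise.fraction_noise_sd, size=exact.shape)
        noisy = np.clip(noisy, 0.0, 1.0)
        noisy /= noisy.sum(axis=1, keepdims=True)
        for i, l_tot in enumerate(ligand_totals):
            for n in range(exact.shape[1]):
                records.append(
                    (variant, temperature, rep, protein_total, l_tot, n, noisy[i, n])
                )
    return pd.DataFrame.from_records(records, columns=TITRATION_COLUMNS)


@dataclass
class CycleDesign:
    """Specification of a mutant-cycle panel with designed couplings.

    ``mutations`` maps mutation labels to additive shifts applied to the
    wild-type baseline (one EventThermo-shaped shift per event).
    ``couplings`` maps frozensets of two mutation labels to pairwise
    interaction terms (c_G, c_H) per event, defined at T0 with the sign
    convention that a positive c_G is recovered as a positive ddG_int.
    ``triple_coupling`` optionally adds a third-order term for the set
    of all three mutations.  The entropic coupling follows from
    c_G - c_H so the additive identity stays exact.
    """

    wild_type: list[EventThermo]
    mutations: dict[str, list[EventThermo]]
    couplings: dict[frozenset, list[tuple[float, float]]] = field(default_factory=dict)
    triple_coupling: list[tuple[float, float]] | None = None
    t0: float = 298.0

    def variant_label(self, muts: tuple[str, ...]) -> str:
        return " ".join(muts) if muts else "WT"


def make_cycle_truth(design: CycleDesign) -> GroundTruth:
    """Expand a cycle design into per-corner ground-truth parameters.

    Every subset of the mutations becomes a variant: parameters are the
    wild-type baseline plus the sum of single-mutation shifts, minus the
    pairwise coupling for each included pair, plus the third-order term
    when all three mutations are present (so the triple-cycle coupling
    recovered along any route equals the designed value).
    """
    names = sorted(design.mutations)
    n_ev = len(design.wild_type)
    variants: dict[str, list[EventThermo]] = {}
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            params = []
            for ev in range(n_ev):
                dg = design.wild_type[ev].dg_t0
                dh = design.wild_type[ev].dh_t0
                dcp = design.wild_type[ev].dcp
                for m in combo:
                    shift = design.mutations[m][ev]
                    dg += shift.dg_t0
                    dh += shift.dh_t0
                    dcp += shift.dcp
                for pair in itertools.combinations(combo, 2):
                    c = design.couplings.get(frozenset(pair))
                    if c is not None:
                        dg -= c[ev][0]
                        dh -= c[ev][1]
                if len(combo) == 3 and design.triple_coupling is not None:
                    dg += design.triple_coupling[ev][0]
                    dh += design.triple_coupling[ev][1]
                params.append(EventThermo(dg_t0=dg, dh_t0=dh, dcp=dcp))
            variants[design.variant_label(combo)] = params
    return GroundTruth(t0=design.t0, variants=variants)


def generate_variant_panel(
    truth: GroundTruth,
    noise: NoiseModel,
    temperatures=DEFAULT_TEMPERATURES,
    protein_total: float = DEFAULT_PROTEIN_UM,
    ligand_totals=DEFAULT_LIGAND_GRID,
) -> pd.DataFrame:
    """Titration data for every variant at every temperature.

    A single random generator seeded from ``noise.seed`` drives all
    variants, so the panel is reproducible as a whole.  Returns a
    long-format DataFrame in the titration CSV schema.
    """
    rng = np.random.default_rng(noise.seed)
    frames = [
        generate_titration_series(
            truth,
            variant,
            temp,
            noise,
            protein_total=protein_total,
            ligand_totals=ligand_totals,
            rng=rng,
        )
        for variant in truth.variants
        for temp in temperatures
    ]
    return pd.concat(frames, ignore_index=True)


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth parameters as a tidy table, for test assertions."""
    records = [
        {
            "variant": variant,
            "n_event": ev + 1,
            "t0_K": truth.t0,
            "dG_t0_kJmol": p.dg_t0,
            "dH_t0_kJmol": p.dh_t0,
            "dCp_kJmolK": p.dcp,
            "kd_t0_uM": 1e6 * np.exp(p.dg_t0 / (R_KJ * truth.t0)),
        }
        for variant, params in truth.variants.items()
        for ev, p in enumerate(params)
    ]
    return pd.DataFrame.from_records(records)
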