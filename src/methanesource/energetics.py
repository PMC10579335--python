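"""Gibbs-energy profiling of methanogenic catabolisms down a sediment column.

Nine methanogenic reactions are evaluated: hydrogenotrophic (CO₂ reduction
with H₂), acetoclastic, formatotrophic, and six methylotrophic pathways
(methanol reduction with H₂, methanol/methylamine/dimethylamine/
trimethylamine/DMS disproportionation). Because several are
disproportionations that move different numbers of carbons per formula unit,
all Gibbs energies are normalized per mole of carbon transferred (kJ/mol C),
negative = exergonic.

ΔG_r = ΔG°(T) + RT·ln Q, with ΔG°(T) from Hess's law over a shipped table of
standard formation properties and a constant-ΔH (van't Hoff / Gibbs–
Helmholtz) temperature correction. Activities are molal concentrations times
Davies activity coefficients for charged species (γ = 1 for neutral species
by default). Unmeasured substrates are spanned by configurable concentration
ranges, giving an envelope (min, mean, max) of ΔG at each depth.
"""

from __future__ import annotations

import importlib.resources
import io as _io
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "R_KJ",
    "T0_K",
    "ReactionSpec",
    "SpeciesThermo",
    "SubstrateRange",
    "reaction_library",
    "load_species_thermo",
    "load_substrate_ranges",
    "standard_gibbs",
    "activity_coefficient",
    "gibbs_energy",
    "gibbs_envelope",
    "below_detection_policy",
    "downcore_energetics",
    "find_zero_crossing",
    "co2_fraction",
    "MEASURED_SPECIES",
]

R_KJ = 8.31446261815324e-3  # gas constant, kJ/(mol K)
T0_K = 298.15

#: Elemental composition and charge of every species the reactions use,
#: for the automated balance audit.
SPECIES_FORMULA: dict[str, dict[str, float]] = {
    "H2": {"H": 2},
    "CO2": {"C": 1, "O": 2},
    "CH4": {"C": 1, "H": 4},
    "H2O": {"H": 2, "O": 1},
    "H+": {"H": 1, "charge": 1},
    "acetate": {"C": 2, "H": 3, "O": 2, "charge": -1},
    "formate": {"C": 1, "H": 1, "O": 2, "charge": -1},
    "methanol": {"C": 1, "H": 4, "O": 1},
    "methylamine": {"C": 1, "H": 5, "N": 1},
    "dimethylamine": {"C": 2, "H": 7, "N": 1},
    "trimethylamine": {"C": 3, "H": 9, "N": 1},
    "NH4+": {"N": 1, "H": 4, "charge": 1},
    "DMS": {"C": 2, "H": 6, "S": 1},
    "HS-": {"H": 1, "S": 1, "charge": -1},
}

#: Species whose in-situ concentrations a porewater profile provides.
MEASURED_SPECIES = ("CH4", "CO2", "H2", "NH4+", "HS-")


@dataclass(frozen=True)
class SpeciesThermo:
    species: str
    phase: str
    charge: int
    dG_f: float  # kJ/mol, 25 C, 1 bar
    dH_f: float  # kJ/mol, 25 C, 1 bar
    source: str = ""


@dataclass(frozen=True)
class SubstrateRange:
    """Concentration bounds (mol/kg) for an unmeasured substrate."""

    species: str
    min_conc: float
    max_conc: float

    def __post_init__(self) -> None:
        if not (0 < self.min_conc <= self.max_conc):
            raise ValueError(
                f"{self.species}: need 0 < min <= max, got "
                f"[{self.min_conc}, {self.max_conc}]"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """A catabolic reaction: signed stoichiometry (negative = reactant)."""

    id: int
    name: str
    stoichiometry: Mapping[str, float]
    carbon_transferred: float
    note: str = ""

    def balance(self) -> dict[str, float]:
        """Net element/charge totals; all zero for a balanced reaction."""
        totals: dict[str, float] = {}
        for sp, coeff in self.stoichiometry.items():
            formula = SPECIES_FORMULA[sp]
            for el, n in formula.items():
                totals[el] = totals.get(el, 0.0) + coeff * n
        return totals

    def is_balanced(self, tol: float = 1e-9) -> bool:
        return all(abs(v) <= tol for v in self.balance().values())

    def unmeasured_substrates(self) -> list[str]:
        return [
            sp
            for sp, c in self.stoichiometry.items()
            if c < 0 and sp not in MEASURED_SPECIES and sp not in ("H+", "H2O")
        ]


def reaction_library() -> list[ReactionSpec]:
    """The nine methanogenic catabolisms.

    Three stoichiometries are corrected relative to commonly printed forms
    (see each reaction's ``note``): methanol reduction yields water, not H₂,
    and the methylamine substrates are the neutral aqueous amines CH₃NH₂,
    (CH₃)₂NH and (CH₃)₃N, under which the printed coefficients balance
    exactly. Formate disproportionation requires 2 H₂O on the product side.
    """
    return [
        ReactionSpec(1, "hydrogenotrophic",
                     {"H2": -4, "CO2": -1, "CH4": 1, "H2O": 2}, 1),
        ReactionSpec(2, "acetoclastic",
                     {"acetate": -1, "H+": -1, "CH4": 1, "CO2": 1}, 2),
        ReactionSpec(3, "formatotrophic",
                     {"formate": -4, "H+": -4, "CH4": 1, "CO2": 3, "H2O": 2}, 4,
                     note="2 H2O required on the product side for O/H balance"),
        ReactionSpec(4, "methanol reduction with H2",
                     {"methanol": -1, "H2": -1, "CH4": 1, "H2O": 1}, 1,
                     note="product corrected from H2 to H2O for O balance"),
        ReactionSpec(5, "methanol disproportionation",
                     {"methanol": -4, "CH4": 3, "CO2": 1, "H2O": 2}, 4),
        ReactionSpec(6, "methylamine disproportionation",
                     {"methylamine": -4, "H+": -4, "H2O": -2,
                      "CH4": 3, "CO2": 1, "NH4+": 4}, 4,
                     note="substrate taken as neutral CH3NH2(aq)"),
        ReactionSpec(7, "dimethylamine disproportionation",
                     {"dimethylamine": -2, "H+": -2, "H2O": -2,
                      "CH4": 3, "CO2": 1, "NH4+": 2}, 4,
                     note="substrate taken as neutral (CH3)2NH(aq)"),
        ReactionSpec(8, "trimethylamine disproportionation",
                     {"trimethylamine": -4, "H+": -4, "H2O": -6,
                      "CH4": 9, "CO2": 3, "NH4+": 4}, 12,
                     note="substrate taken as neutral (CH3)3N(aq)"),
        ReactionSpec(9, "DMS disproportionation",
                     {"DMS": -2, "H2O": -2,
                      "CH4": 3, "CO2": 1, "HS-": 2, "H+": 2}, 4),
    ]


def load_species_thermo() -> dict[str, SpeciesThermo]:
    """Load the shipped standard-state thermodynamic table."""
    ref = importlib.resources.files("methanesource.data").joinpath(
        "species_thermo.csv"
    )
    df = pd.read_csv(_io.StringIO(ref.read_text()), comment="#")
    return {
        r.species: SpeciesThermo(
            r.species, r.phase, int(r.charge), float(r.dGf_kJ), float(r.dHf_kJ),
            str(r.source),
        )
        for r in df.itertuples()
    }


def load_substrate_ranges() -> dict[str, SubstrateRange]:
    """Load the shipped default substrate concentration ranges."""
    ref = importlib.resources.files("methanesource.data").joinpath(
        "substrate_ranges.yaml"
    )
    raw = yaml.safe_load(ref.read_text())
    return {
        sp: SubstrateRange(sp, float(v["min"]), float(v["max"]))
        for sp, v in raw.items()
    }


def standard_gibbs(
    rxn: ReactionSpec,
    T: float,
    table: Optional[Mapping[str, SpeciesThermo]] = None,
) -> float:
    """Standard-state ΔG° of a reaction at temperature T (kelvin), kJ/mol.

    Hess's law over formation Gibbs energies at 25 °C, extrapolated in T via
    the Gibbs–Helmholtz relation with constant reaction enthalpy:
    ΔG°(T) = ΔG°(T0)·(T/T0) + ΔH°(T0)·(1 − T/T0).
    """
    if not (273.0 <= T <= 473.0):
        raise ValueError(f"T = {T} K outside supported 273–473 K")
    if table is None:
        table = load_species_thermo()
    missing = [sp for sp in rxn.stoichiometry if sp not in table]
    if missing:
        raise KeyError(f"species missing from thermodynamic table: {missing}")
    dG0 = sum(c * table[sp].dG_f for sp, c in rxn.stoichiometry.items())
    dH0 = sum(c * table[sp].dH_f for sp, c in rxn.stoichiometry.items())
    return dG0 * (T / T0_K) + dH0 * (1.0 - T / T0_K)


def activity_coefficient(charge: int, ionic_strength: float, T: float = T0_K) -> float:
    """Davies-equation activity coefficient.

    log₁₀ γ = −A·z²·(√I/(1+√I) − 0.3·I), with the Debye–Hückel A parameter's
    mild temperature dependence from a standard fit (A = 0.509 at 25 °C).
    Neutral species return γ = 1 (salting-out is left to the caller).
    """
    if ionic_strength < 0:
        raise ValueError(f"ionic strength must be >= 0, got {ionic_strength}")
    if charge == 0 or ionic_strength == 0:
        return 1.0
    t = T - 273.15
    A = 0.4918 + 6.6098e-4 * t + 5.0273e-6 * t * t
    sqI = np.sqrt(ionic_strength)
    log10g = -A * charge * charge * (sqI / (1.0 + sqI) - 0.3 * ionic_strength)
    return float(10.0 ** log10g)


def gibbs_energy(
    rxn: ReactionSpec,
    T: float,
    P: float = 1.0,
    activities: Optional[Mapping[str, float]] = None,
    table: Optional[Mapping[str, SpeciesThermo]] = None,
) -> float:
    """In-situ Gibbs energy of a reaction, kJ per mol carbon transferred.

    ΔG_r = [ΔG°(T) + RT·ln Q] / n_C. Water activity defaults to 1; pressure
    is accepted for interface symmetry but the (second-order) molar-volume
    correction is not applied.
    """
    if activities is None:
        activities = {}
    lnQ = 0.0
    for sp, coeff in rxn.stoichiometry.items():
        a = activities.get(sp, 1.0 if sp == "H2O" else None)
        if a is None:
            raise KeyError(f"no activity supplied for species {sp!r}")
        if a <= 0:
            raise ValueError(f"activity of {sp!r} must be > 0, got {a}")
        lnQ += coeff * np.log(a)
    dG = standard_gibbs(rxn, T, table) + R_KJ * T * lnQ
    return dG / rxn.carbon_transferred


def below_detection_policy(
    below_detection: bool,
    measured_activity: Optional[float] = None,
    standin_activity: float = 1e-7,
) -> tuple[float, bool]:
    """Resolve an activity for a possibly below-detection measurement.

    Returns ``(activity, imputed)``. Below-detection species get the
    configured stand-in activity (default 1e-7, the convention for methane);
    measured values pass through unchanged.
    """
    if below_detection:
        return standin_activity, True
    if measured_activity is None:
        raise ValueError("measured_activity required when not below detection")
    return measured_activity, False


def gibbs_envelope(
    rxn: ReactionSpec,
    T: float,
    measured_activities: Mapping[str, float],
    ranges: Mapping[str, SubstrateRange],
    gammas: Optional[Mapping[str, float]] = None,
    table: Optional[Mapping[str, SpeciesThermo]] = None,
    mean_rule: str = "geometric",
) -> tuple[float, float, float]:
    """(min, mean, max) ΔG over the unmeasured-substrate concentration box.

    Substrates are reactants, so setting all of them to their maximum
    concentration gives the most negative (min) ΔG and vice versa. The
    central value uses the geometric mean of each range (log-uniform centre)
    by default, or the arithmetic mean with ``mean_rule='arithmetic'``.
    """
    unmeasured = rxn.unmeasured_substrates()
    missing = [sp for sp in unmeasured if sp not in ranges]
    if missing:
        raise KeyError(f"no substrate range configured for: {missing}")
    if gammas is None:
        gammas = {}

    def conc_at(level: str) -> dict[str, float]:
        out = dict(measured_activities)
        for sp in unmeasured:
            r = ranges[sp]
            if level == "min":
                c = r.min_conc
            elif level == "max":
                c = r.max_conc
            elif mean_rule == "geometric":
                c = float(np.sqrt(r.min_conc * r.max_conc))
            elif mean_rule == "arithmetic":
                c = 0.5 * (r.min_conc + r.max_conc)
            else:
                raise ValueError(f"unknown mean_rule {mean_rule!r}")
            out[sp] = c * gammas.get(sp, 1.0)
        return out

    dg_at_max = gibbs_energy(rxn, T, activities=conc_at("max"), table=table)
    dg_at_mid = gibbs_energy(rxn, T, activities=conc_at("mean"), table=table)
    dg_at_min = gibbs_energy(rxn, T, activities=conc_at("min"), table=table)
    lo, mid, hi = sorted([dg_at_max, dg_at_mid, dg_at_min])
    return lo, mid, hi


def co2_fraction(pH: float, pK1: float = 6.35, pK2: float = 10.33) -> float:
    """Fraction of dissolved inorganic carbon present as CO₂(aq) at given pH."""
    h = 10.0 ** (-pH)
    K1, K2 = 10.0**-pK1, 10.0**-pK2
    return 1.0 / (1.0 + K1 / h + K1 * K2 / (h * h))


def _row_activities(
    row: pd.Series, gammas: Mapping[str, float], standin: float
) -> tuple[dict[str, float], bool]:
    """Measured-species activities for one profile row; flags imputation."""
    imputed = False
    acts: dict[str, float] = {"H+": 10.0 ** (-float(row["pH"]))}
    for sp, col in (
        ("CH4", "CH4_molkg"),
        ("H2", "H2_molkg"),
        ("NH4+", "NH4_molkg"),
        ("HS-", "HS_molkg"),
    ):
        bd = bool(row.get(f"{col}_bd", False)) or not np.isfinite(row[col]) or row[col] <= 0
        a, was_imputed = below_detection_policy(
            bd, None if bd else float(row[col]) * gammas.get(sp, 1.0), standin
        )
        imputed = imputed or was_imputed
        acts[sp] = a
    # ΣCO2 -> CO2(aq) via pH speciation
    dic = float(row["DIC_molkg"])
    bd = bool(row.get("DIC_molkg_bd", False)) or not np.isfinite(dic) or dic <= 0
    a, was_imputed = below_detection_policy(
        bd,
        None if bd else dic * co2_fraction(float(row["pH"])) * gammas.get("CO2", 1.0),
        standin,
    )
    acts["CO2"] = a
    return acts, imputed or was_imputed


def downcore_energetics(
    profile: pd.DataFrame,
    ranges: Optional[Mapping[str, SubstrateRange]] = None,
    table: Optional[Mapping[str, SpeciesThermo]] = None,
    standin_activity: float = 1e-7,
    mean_rule: str = "geometric",
) -> pd.DataFrame:
    """Gibbs-energy envelopes of all nine reactions at every profile depth.

    ``profile`` needs columns: depth_mbsf, temperature_C, pH, ionic_strength,
    CH4_molkg, DIC_molkg, H2_molkg, NH4_molkg, HS_molkg (plus optional
    ``*_bd`` below-detection flags, ``pressure_bar`` and ``site``).

    Returns a tidy frame: site, depth_mbsf, reaction_id, reaction,
    dG_min/dG_mean/dG_max (kJ/mol C), imputed flag, error (per-row failures
    are recorded, not raised).
    """
    if ranges is None:
        ranges = load_substrate_ranges()
    if table is None:
        table = load_species_thermo()
    reactions = reaction_library()
    records = []
    for _, row in profile.iterrows():
        site = row.get("site", "")
        depth = float(row["depth_mbsf"])
        try:
            T = float(row["temperature_C"]) + 273.15
            I = float(row["ionic_strength"])
            gammas = {
                sp: activity_coefficient(SPECIES_FORMULA[sp].get("charge", 0), I, T)
                for sp in SPECIES_FORMULA
                if sp != "H+"
            }
            acts, imputed = _row_activities(row, gammas, standin_activity)
        except (KeyError, ValueError) as exc:
            for rxn in reactions:
                records.append(
                    dict(site=site, depth_mbsf=depth, reaction_id=rxn.id,
                         reaction=rxn.name, dG_min=np.nan, dG_mean=np.nan,
                         dG_max=np.nan, imputed=False, error=str(exc))
                )
            continue
        for rxn in reactions:
            try:
                lo, mid, hi = gibbs_envelope(
                    rxn, T, acts, ranges, gammas=gammas, table=table,
                    mean_rule=mean_rule,
                )
                records.append(
                    dict(site=site, depth_mbsf=depth, reaction_id=rxn.id,
                         reaction=rxn.name, dG_min=lo, dG_mean=mid, dG_max=hi,
                         imputed=imputed, error="")
                )
            except (KeyError, ValueError) as exc:
                records.append(
                    dict(site=site, depth_mbsf=depth, reaction_id=rxn.id,
                         reaction=rxn.name, dG_min=np.nan, dG_mean=np.nan,
                         dG_max=np.nan, imputed=imputed, error=str(exc))
                )
    return pd.DataFrame.from_records(records)


def find_zero_crossing(
    depths: np.ndarray | pd.Series, dG: np.ndarray | pd.Series
) -> Optional[float]:
    """Shallowest depth where ΔG crosses from negative to positive.

    Linear interpolation between the bracketing samples; None if ΔG never
    changes sign from − to +. Points with ΔG exactly 0 count as crossings.
    """
    d = np.asarray(depths, dtype=float)
    g = np.asarray(dG, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two points")
    order = np.argsort(d)
    d, g = d[order], g[order]
    for i in range(len(d) - 1):
        if g[i] < 0 <= g[i + 1]:
            if g[i + 1] == g[i]:
                return float(d[i + 1])
            return float(d[i] + (0.0 - g[i]) * (d[i + 1] - d[i]) / (g[i + 1] - g[i]))
        if g[i] == 0 and g[i + 1] > 0:
            return float(d[i])
    return None
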