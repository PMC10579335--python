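"""Synthetic down-core geochemistry and isotope tables with known truth.

The generator emulates the structure of porewater profiles from organic-rich
sill-intruded sediment columns: sulfate decays sigmoidally to zero at the
sulfate–methane transition zone (SMTZ), methane accumulates below it in
Gaussian-shaped peaks, sulfide peaks at the SMTZ, and temperature rises
linearly with a site-specific geothermal gradient. Forward-mixed methane
isotope measurements are produced by the exact isotopologue mixing operator
with a known microbial fraction at every depth, so inversion routines can be
validated against ground truth.

These functional forms are deliberately simple stand-ins; they reproduce the
down-core *structure* real profiles show, not any particular dataset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .isotopes import (
    DEFAULT_FRAME,
    IsotopeComposition,
    IsotopologueVector,
    ReferenceFrame,
    composition_to_isotopologues,
    isotopologues_to_composition,
)
from .mixing import QUANTITIES, Endmember, mix

__all__ = [
    "SiteTemplate",
    "TruthRecord",
    "load_site_templates",
    "composite_nonmicrobial",
    "generate_profile",
    "generate_mixed_measurements",
    "DEFAULT_NOISE_SIGMA",
    "METHANE_LOD_MOLKG",
]

#: 1σ measurement noise (‰) at the scale of modern clumped-methane mass
#: spectrometry: tight bulk deltas, looser doubly substituted anomalies.
DEFAULT_NOISE_SIGMA = {"d13C": 0.1, "dD": 0.5, "D13CH3D": 0.3, "D12CH2D2": 1.5}

#: Porewater methane detection limit (mol/kg); below it the profile flags
#: the value and energetics falls back to the stand-in activity.
METHANE_LOD_MOLKG = 2e-5


@dataclass(frozen=True)
class SiteTemplate:
    """Archetype of one drill site's down-core structure."""

    name: str
    smtz_depth: float
    thermal_gradient: float  # degC/km
    sill_depth: Optional[float]
    methane_peaks: tuple[tuple[float, float], ...]  # (depth mbsf, peak mM)
    sulfate_surface: float  # mM
    max_depth: float
    surface_T: float = 3.0
    water_depth: float = 1600.0
    pmm_at_smtz: float = 0.8
    pmm_at_bottom: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.smtz_depth < self.max_depth):
            raise ValueError(
                f"{self.name}: need 0 < smtz_depth < max_depth, got "
                f"{self.smtz_depth}, {self.max_depth}"
            )
        if self.thermal_gradient <= 0:
            raise ValueError(f"{self.name}: thermal gradient must be > 0")
        for f in (self.pmm_at_smtz, self.pmm_at_bottom):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{self.name}: truth fractions must be in [0,1]")

    def temperature(self, depth: np.ndarray) -> np.ndarray:
        return self.surface_T + self.thermal_gradient / 1000.0 * np.asarray(depth)

    def true_fraction(self, depth: np.ndarray) -> np.ndarray:
        """Ground-truth microbial fraction: linear decline through the MZ."""
        d = np.asarray(depth, dtype=float)
        span = self.max_depth - self.smtz_depth
        f = self.pmm_at_smtz + (self.pmm_at_bottom - self.pmm_at_smtz) * (
            (d - self.smtz_depth) / span
        )
        return np.clip(f, min(self.pmm_at_smtz, self.pmm_at_bottom),
                       max(self.pmm_at_smtz, self.pmm_at_bottom))


def load_site_templates() -> dict[str, SiteTemplate]:
    """The three shipped archetypes: no_sill, deep_cooled_sill, shallow_hot_sill."""
    ref = importlib.resources.files("methanesource.data").joinpath(
        "site_templates.yaml"
    )
    raw = yaml.safe_load(ref.read_text())
    out = {}
    for name, t in raw.items():
        out[name] = SiteTemplate(
            name=name,
            smtz_depth=float(t["smtz_depth"]),
            thermal_gradient=float(t["thermal_gradient"]),
            sill_depth=None if t["sill_depth"] is None else float(t["sill_depth"]),
            methane_peaks=tuple((float(d), float(c)) for d, c in t["methane_peaks"]),
            sulfate_surface=float(t["sulfate_surface"]),
            max_depth=float(t["max_depth"]),
            surface_T=float(t.get("surface_T", 3.0)),
            water_depth=float(t.get("water_depth", 1600.0)),
            pmm_at_smtz=float(t.get("pmm_at_smtz", 0.8)),
            pmm_at_bottom=float(t.get("pmm_at_bottom", 0.2)),
        )
    return out


def composite_nonmicrobial(
    thermogenic: Endmember,
    abiotic: Endmember,
    frame: ReferenceFrame = DEFAULT_FRAME,
) -> Endmember:
    """An equal thermogenic–abiotic blend as the non-microbial endmember.

    The default ground truth treats the non-microbial methane as an ambiguous
    mix of the two candidate sources — the situation the pooled two-model
    inversion is built for. The blend is exact in isotopologue space; the
    sampling box spans the union of the two parents' boxes.
    """
    central = mix(thermogenic.central, abiotic.central, 0.5, frame)
    low = {q: min(thermogenic.bounds(q)[0], abiotic.bounds(q)[0]) for q in QUANTITIES}
    high = {q: max(thermogenic.bounds(q)[1], abiotic.bounds(q)[1]) for q in QUANTITIES}
    return Endmember(label="nonmicrobial", central=central, low=low, high=high)


@dataclass(frozen=True)
class TruthRecord:
    """Everything needed to recompute a generated measurement table."""

    depths: tuple[float, ...]
    true_f: tuple[float, ...]
    microbial: Endmember
    nonmicrobial: Endmember
    noise_sigma: Mapping[str, float]
    seed: int


def _noisy(rng: np.random.Generator, x: np.ndarray, sigma: float) -> np.ndarray:
    """Multiplicative lognormal noise with log-scale sigma."""
    if sigma == 0:
        return x
    return x * rng.lognormal(0.0, sigma, size=np.shape(x))


def generate_profile(
    template: SiteTemplate,
    n_depths: int = 30,
    seed: int = 0,
    noise_sigma: float = 0.05,
) -> pd.DataFrame:
    """Synthetic porewater geochemistry profile for one site archetype.

    Deterministic analytic curves with seeded multiplicative lognormal noise
    on the concentrations (``noise_sigma`` is the log-scale σ; 0 disables).
    Columns follow the dialect :func:`methanesource.energetics.downcore_energetics`
    reads; concentrations are mol/kg, ``CH4_molkg_bd`` flags methane below
    the detection limit.
    """
    if n_depths < 2:
        raise ValueError(f"n_depths must be >= 2, got {n_depths}")
    rng = np.random.default_rng(seed)
    d = np.linspace(1.0, template.max_depth, n_depths)
    smtz = template.smtz_depth

    # sulfate: logistic decay vanishing (<5% of surface) at the SMTZ
    so4 = template.sulfate_surface * 1e-3 / (
        1.0 + np.exp((d - 0.68 * smtz) / (smtz / 10.0))
    )
    # methane: Gaussian peaks over a diffusive background, accumulating only
    # below the SMTZ (anaerobic methane oxidation keeps the sulfate zone at
    # trace levels); the onset sits just under the SMTZ
    rise = 1.0 / (1.0 + np.exp(-(d - 1.2 * smtz) / (smtz / 40.0)))
    ch4 = np.full_like(d, 1e-7) + 2e-4 * rise
    for pd_, pk in template.methane_peaks:
        ch4 = ch4 + pk * 1e-3 * np.exp(-(((d - pd_) / 20.0) ** 2)) * rise
    # sulfide: peaks at the SMTZ where the two fluxes meet
    hs = 1e-6 + 2e-3 * np.exp(-(((d - smtz) / (0.3 * smtz)) ** 2))
    # dissolved H2: nM at the cold seafloor, rising with temperature toward
    # tens-to-hundreds of nM (thermodynamic poise plus thermogenic H2 at
    # depth); DIC and ammonium accumulate with depth
    T = template.temperature(d)
    h2 = 10.0 ** (-9.0 + (T - template.surface_T) / 55.0)
    dic = 8e-3 + 22e-3 * (d / template.max_depth)
    nh4 = 5e-4 + 9e-3 * (d / template.max_depth)

    so4 = _noisy(rng, so4, noise_sigma)
    ch4 = _noisy(rng, ch4, noise_sigma)
    hs = _noisy(rng, hs, noise_sigma)
    h2 = _noisy(rng, h2, noise_sigma)
    dic = _noisy(rng, dic, noise_sigma)
    nh4 = _noisy(rng, nh4, noise_sigma)

    return pd.DataFrame(
        {
            "site": template.name,
            "depth_mbsf": d,
            "temperature_C": template.temperature(d),
            "pressure_bar": (template.water_depth + d) * 0.101,
            "pH": 7.8,
            "ionic_strength": 0.7,
            "CH4_molkg": ch4,
            "CH4_molkg_bd": ch4 < METHANE_LOD_MOLKG,
            "DIC_molkg": dic,
            "H2_molkg": h2,
            "SO4_molkg": so4,
            "HS_molkg": hs,
            "NH4_molkg": nh4,
        }
    )


def generate_mixed_measurements(
    depths: Sequence[float],
    true_f: Sequence[float] | Callable[[np.ndarray], np.ndarray],
    microbial: Endmember,
    nonmicrobial: Endmember,
    noise_sigma: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    site: str = "synthetic",
    frame: ReferenceFrame = DEFAULT_FRAME,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Forward-mixed isotope measurement table with known microbial fraction.

    For each depth the observation is ``mix(microbial, nonmicrobial, f)`` at
    the endmembers' central compositions, perturbed by Gaussian noise with
    the per-quantity σ (defaults to :data:`DEFAULT_NOISE_SIGMA`). A Bernard
    ratio consistent with the microbial fraction is attached as C1/C2/C3
    columns. Returns the table in the dialect ``pmm_profile`` consumes,
    plus the :class:`TruthRecord`.
    """
    if noise_sigma is None:
        noise_sigma = DEFAULT_NOISE_SIGMA
    d = np.asarray(depths, dtype=float)
    f = np.asarray(true_f(d) if callable(true_f) else true_f, dtype=float)
    if f.shape != d.shape:
        raise ValueError("true_f must give one fraction per depth")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("true fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for depth, fi in zip(d, f):
        comp = mix(microbial.central, nonmicrobial.central, float(fi), frame)
        row = {"site": site, "depth_mbsf": depth, "true_f": fi}
        for q in QUANTITIES:
            s = float(noise_sigma.get(q, 0.0))
            v = getattr(comp, q)
            row[q] = v + rng.normal(0.0, s) if s > 0 else v
            row[f"sigma_{q}"] = s
        # microbial gas is dry: Bernard ratio rises steeply with f
        row["C2"] = row["C3"] = 0.5
        row["C1"] = 10.0 ** (1.5 + 2.5 * fi)
        rows.append(row)
    table = pd.DataFrame(rows)
    truth = TruthRecord(
        depths=tuple(d),
        true_f=tuple(f),
        microbial=microbial,
        nonmicrobial=nonmicrobial,
        noise_sigma=dict(noise_sigma),
        seed=seed,
    )
    return table, truth
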