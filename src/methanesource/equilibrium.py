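"""Temperature-dependent equilibrium clumped-isotopologue values.

At thermodynamic equilibrium the abundances of ¹³CH₃D and ¹²CH₂D₂ exceed
their stochastic values by an amount that decreases monotonically with
temperature, so the clumped anomalies double as geothermometers. Calibrations
are shipped as data (polynomials in 1/T) and are pluggable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "EquilibriumCalibration",
    "load_calibration",
    "equilibrium_capdelta",
    "equilibrium_temperature",
]


@dataclass(frozen=True)
class EquilibriumCalibration:
    """Polynomial calibration of equilibrium Δ values against 1/T.

    ``coefficients_*`` are ascending powers of 1/T (kelvin), constant first.
    """

    name: str
    coefficients_13CH3D: tuple[float, ...]
    coefficients_12CH2D2: tuple[float, ...]
    valid_T_range: tuple[float, float]
    citation: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.valid_T_range
        if not (0 < lo < hi):
            raise ValueError(f"invalid T range {self.valid_T_range}")
        # Audit the physical shape of both curves on a 1 K grid: positive
        # and monotonically decreasing toward the high-T (stochastic) limit.
        T = np.arange(lo, hi, 1.0)
        for label, coeffs in (
            ("13CH3D", self.coefficients_13CH3D),
            ("12CH2D2", self.coefficients_12CH2D2),
        ):
            d = _polyval_invT(np.asarray(coeffs, dtype=float), T)
            if not np.all(d > 0):
                raise ValueError(f"{self.name}: Δ{label}(T) not positive on range")
            if not np.all(np.diff(d) < 0):
                raise ValueError(f"{self.name}: Δ{label}(T) not monotone decreasing")


def _polyval_invT(coeffs: np.ndarray, T: np.ndarray | float) -> np.ndarray | float:
    x = 1.0 / np.asarray(T, dtype=float)
    # ascending coefficients -> evaluate sum c_k x^k
    return np.polynomial.polynomial.polyval(x, coeffs)


def load_calibration(name: str = "eldridge2019") -> EquilibriumCalibration:
    """Load a shipped calibration by name from the package data file."""
    ref = importlib.resources.files("methanesource.data").joinpath(
        "equilibrium_calibrations.yaml"
    )
    entries = yaml.safe_load(ref.read_text())
    if name not in entries:
        raise KeyError(
            f"unknown calibration {name!r}; available: {sorted(entries)}"
        )
    e = entries[name]
    return EquilibriumCalibration(
        name=name,
        coefficients_13CH3D=tuple(float(c) for c in e["coefficients_13CH3D"]),
        coefficients_12CH2D2=tuple(float(c) for c in e["coefficients_12CH2D2"]),
        valid_T_range=tuple(float(t) for t in e["valid_T_range_K"]),
        citation=e.get("citation", ""),
    )


def equilibrium_capdelta(
    T: float | np.ndarray, cal: EquilibriumCalibration
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Equilibrium (Δ¹³CH₃D, Δ¹²CH₂D₂) in ‰ at absolute temperature T (K)."""
    lo, hi = cal.valid_T_range
    Ta = np.asarray(T, dtype=float)
    if np.any(Ta < lo) or np.any(Ta > hi):
        raise ValueError(f"T outside calibration range [{lo}, {hi}] K")
    d13 = _polyval_invT(np.asarray(cal.coefficients_13CH3D), Ta)
    d22 = _polyval_invT(np.asarray(cal.coefficients_12CH2D2), Ta)
    if np.isscalar(T) or Ta.ndim == 0:
        return float(d13), float(d22)
    return d13, d22


def equilibrium_temperature(
    D13CH3D: float,
    cal: EquilibriumCalibration,
    species: str = "13CH3D",
) -> float:
    """Invert an equilibrium Δ value (‰) to temperature (K).

    The calibration curve is strictly decreasing, so the root of
    Δ(T) − value is unique; it is bracketed on the valid range and found by
    bisection (brentq) to better than 0.01 K.
    """
    coeffs = {
        "13CH3D": cal.coefficients_13CH3D,
        "12CH2D2": cal.coefficients_12CH2D2,
    }.get(species)
    if coeffs is None:
        raise ValueError(f"species must be '13CH3D' or '12CH2D2', got {species!r}")
    lo, hi = cal.valid_T_range
    carr = np.asarray(coeffs, dtype=float)

    def f(T: float) -> float:
        return float(_polyval_invT(carr, T)) - D13CH3D

    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise ValueError(
            f"Δ = {D13CH3D}‰ outside calibration span "
            f"[{float(_polyval_invT(carr, hi)):.4f}, "
            f"{float(_polyval_invT(carr, lo)):.4f}]‰"
        )
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    return float(brentq(f, lo, hi, xtol=0.005))
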