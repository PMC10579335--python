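"""Bulk and clumped methane isotope bookkeeping.

Conversions between delta notation (δ¹³C vs. VPDB, δD vs. VSMOW, and the
clumped anomalies Δ¹³CH₃D and Δ¹²CH₂D₂ vs. the stochastic distribution) and
mole fractions of the five measured methane isotopologues: ¹²CH₄, ¹³CH₄,
¹²CH₃D, ¹³CH₃D and ¹²CH₂D₂.

The stochastic distribution is the isotopologue abundance pattern expected if
¹³C and D assort randomly over methane molecules given the bulk atom ratios.
With atom ratios R13 = ¹³C/¹²C and RD = D/H, the relative abundances per
¹²CH₄ molecule are R13 (¹³CH₄), 4·RD (¹²CH₃D), 4·R13·RD (¹³CH₃D) and 6·RD²
(¹²CH₂D₂); the factors 4 and 6 are the number of distinct substitution sites.
A clumped anomaly Δ multiplies the doubly substituted abundance by
(Δ/1000 + 1). Isotopologues with three or more rare substitutions are
neglected (relative abundance below ~1e-10 for natural methane).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ReferenceFrame",
    "IsotopeComposition",
    "IsotopologueVector",
    "delta_to_ratio",
    "ratio_to_delta",
    "composition_to_isotopologues",
    "isotopologues_to_composition",
    "VPDB_R13C",
    "VSMOW_RD",
]

# Community-standard reference atom ratios.
VPDB_R13C = 0.011180  # 13C/12C of Vienna Pee Dee Belemnite
VSMOW_RD = 0.00015576  # D/H of Vienna Standard Mean Ocean Water


@dataclass(frozen=True)
class ReferenceFrame:
    """Reference atom ratios anchoring the delta scales."""

    R13_std: float = VPDB_R13C
    RD_std: float = VSMOW_RD

    def __post_init__(self) -> None:
        for name, value in (("R13_std", self.R13_std), ("RD_std", self.RD_std)):
            if not (0.0 < value < 0.1):
                raise ValueError(f"{name} must be in (0, 0.1), got {value}")


DEFAULT_FRAME = ReferenceFrame()


@dataclass(frozen=True)
class IsotopeComposition:
    """One methane gas in delta/clumped notation.

    Parameters
    ----------
    d13C, dD : float
        Bulk isotope ratios, ‰ vs. VPDB and VSMOW.
    D13CH3D, D12CH2D2 : float
        Clumped anomalies, ‰ vs. the stochastic distribution.
    sigma_* : float, optional
        1σ measurement errors (‰), non-negative.
    """

    d13C: float
    dD: float
    D13CH3D: float = 0.0
    D12CH2D2: float = 0.0
    sigma_d13C: Optional[float] = None
    sigma_dD: Optional[float] = None
    sigma_D13CH3D: Optional[float] = None
    sigma_D12CH2D2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("d13C", "dD", "D13CH3D", "D12CH2D2"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v <= -1000.0:
                raise ValueError(
                    f"{name} = {v}‰ implies a non-positive isotope ratio"
                )
        for name in ("sigma_d13C", "sigma_dD", "sigma_D13CH3D", "sigma_D12CH2D2"):
            s = getattr(self, name)
            if s is not None and (not np.isfinite(s) or s < 0):
                raise ValueError(f"{name} must be >= 0 when given, got {s}")

    def sigmas(self) -> dict[str, Optional[float]]:
        return {
            "d13C": self.sigma_d13C,
            "dD": self.sigma_dD,
            "D13CH3D": self.sigma_D13CH3D,
            "D12CH2D2": self.sigma_D12CH2D2,
        }

    def values(self) -> dict[str, float]:
        return {
            "d13C": self.d13C,
            "dD": self.dD,
            "D13CH3D": self.D13CH3D,
            "D12CH2D2": self.D12CH2D2,
        }


@dataclass(frozen=True)
class IsotopologueVector:
    """Mole fractions of the five measured methane isotopologues.

    Fractions are of total methane; their sum may fall short of 1 by the
    (negligible) abundance of more highly substituted isotopologues.
    """

    x_12CH4: float
    x_13CH4: float
    x_12CH3D: float
    x_13CH3D: float
    x_12CH2D2: float

    def __post_init__(self) -> None:
        total = 0.0
        for name in ("x_12CH4", "x_13CH4", "x_12CH3D", "x_13CH3D", "x_12CH2D2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            total += v
        if total > 1.0 + 1e-12:
            raise ValueError(f"mole fractions sum to {total} > 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_12CH4, self.x_13CH4, self.x_12CH3D, self.x_13CH3D, self.x_12CH2D2]
        )

    @classmethod
    def from_array(cls, a: np.ndarray) -> "IsotopologueVector":
        return cls(*(float(v) for v in a))

    @property
    def remainder(self) -> float:
        """Mass-balance remainder: heavier isotopologues not tracked."""
        return 1.0 - float(self.as_array().sum())


def delta_to_ratio(delta: float, reference_ratio: float) -> float:
    """Convert a delta value (‰) to an absolute isotope ratio.

    R = R_std · (δ/1000 + 1).
    """
    if reference_ratio <= 0:
        raise ValueError(f"reference_ratio must be > 0, got {reference_ratio}")
    delta = float(delta)
    if delta <= -1000.0:
        raise ValueError(f"delta = {delta}‰ would give a non-positive ratio")
    return reference_ratio * (delta / 1000.0 + 1.0)


def ratio_to_delta(ratio: float, reference_ratio: float) -> float:
    """Convert an absolute isotope ratio to a delta value (‰)."""
    if reference_ratio <= 0:
        raise ValueError(f"reference_ratio must be > 0, got {reference_ratio}")
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    return (ratio / reference_ratio - 1.0) * 1000.0


def _relative_abundances(
    comp: IsotopeComposition, frame: ReferenceFrame
) -> np.ndarray:
    """Isotopologue abundances relative to ¹²CH₄ = 1 (unnormalized)."""
    r13 = delta_to_ratio(comp.d13C, frame.R13_std)
    rd = delta_to_ratio(comp.dD, frame.RD_std)
    for name in ("D13CH3D", "D12CH2D2"):
        if getattr(comp, name) <= -1000.0:  # already enforced, kept for clarity
            raise ValueError(f"{name} <= -1000‰")
    g13 = comp.D13CH3D / 1000.0 + 1.0
    g22 = comp.D12CH2D2 / 1000.0 + 1.0
    return np.array([1.0, r13, 4.0 * rd, 4.0 * r13 * rd * g13, 6.0 * rd**2 * g22])


def composition_to_isotopologues(
    comp: IsotopeComposition, frame: ReferenceFrame = DEFAULT_FRAME
) -> IsotopologueVector:
    """Expand a delta/clumped composition into isotopologue mole fractions.

    Atom ratios come from the bulk deltas; molecular abundances follow from
    random assembly over the four hydrogen sites and one carbon site, then
    the doubly substituted species are scaled by their Δ anomalies, and the
    five tracked species are normalized to mole fractions.
    """
    rel = _relative_abundances(comp, frame)
    return IsotopologueVector.from_array(rel / rel.sum())


def isotopologues_to_composition(
    vec: IsotopologueVector, frame: ReferenceFrame = DEFAULT_FRAME
) -> IsotopeComposition:
    """Exact inverse of :func:`composition_to_isotopologues`."""
    if vec.x_12CH4 <= 0:
        raise ValueError("x_12CH4 must be > 0 to recover isotope ratios")
    r13 = vec.x_13CH4 / vec.x_12CH4
    rd = vec.x_12CH3D / (4.0 * vec.x_12CH4)
    if r13 <= 0 or rd <= 0:
        raise ValueError("singly substituted fractions must be > 0")
    g13 = vec.x_13CH3D / (4.0 * r13 * rd * vec.x_12CH4)
    g22 = vec.x_12CH2D2 / (6.0 * rd**2 * vec.x_12CH4)
    return IsotopeComposition(
        d13C=ratio_to_delta(r13, frame.R13_std),
        dD=ratio_to_delta(rd, frame.RD_std),
        D13CH3D=(g13 - 1.0) * 1000.0,
        D12CH2D2=(g22 - 1.0) * 1000.0,
    )
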