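"""Genetic classification of methane in isotopic and chemical space.

Three diagrams are supported, each with a set of polygonal source fields
loaded from versioned vertex files:

* ``cd``      — bulk δ¹³C vs. δD space;
* ``clumped`` — Δ¹³CH₃D vs. Δ¹²CH₂D₂ space (plus the temperature-dependent
  equilibrium band built from a calibration);
* ``bernard`` — δ¹³C vs. log₁₀[C1/(C2+C3)], the Bernard diagram.

Fields genuinely overlap, so classification returns the set of all fields
containing a point (boundary inclusive); an empty set means unclassified.
"""

from __future__ import annotations

import importlib.resources
import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.polygon import orient

from .equilibrium import EquilibriumCalibration, equilibrium_capdelta

__all__ = [
    "SourceField",
    "HydrocarbonComposition",
    "DIAGRAMS",
    "load_fields",
    "bernard_ratio",
    "classify",
    "equilibrium_band",
]

DIAGRAMS = ("cd", "clumped", "bernard")
_FILES = {
    "cd": "cd_diagram.csv",
    "clumped": "clumped_diagram.csv",
    "bernard": "bernard_diagram.csv",
}


@dataclass(frozen=True)
class SourceField:
    """One labelled genetic field: a simple polygon in diagram coordinates."""

    label: str
    space: str
    polygon: Polygon | LineString
    provenance: str = ""

    def __post_init__(self) -> None:
        geom = self.polygon
        if isinstance(geom, Polygon):
            if len(geom.exterior.coords) - 1 < 3:
                raise ValueError(f"{self.label}: polygon needs >= 3 vertices")
            if not geom.is_valid or not geom.is_simple:
                raise ValueError(f"{self.label}: polygon not simple/valid")

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive containment."""
        return bool(self.polygon.covers(Point(x, y)))


@dataclass(frozen=True)
class HydrocarbonComposition:
    """C1 (methane), C2 (ethane), C3 (propane) concentrations, any one unit."""

    C1: float
    C2: float
    C3: float

    def __post_init__(self) -> None:
        for name in ("C1", "C2", "C3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def bernard_ratio(h: HydrocarbonComposition) -> float:
    """The Bernard ratio C1/(C2+C3); high values indicate microbial gas."""
    denom = h.C2 + h.C3
    if denom <= 0:
        raise ZeroDivisionError("C2 + C3 must be > 0 for the Bernard ratio")
    return h.C1 / denom


def load_fields(space: str) -> list[SourceField]:
    """Load the shipped source-field polygons for one diagram.

    Every polygon is audited at load: simple, valid, >= 3 vertices, and
    re-oriented counter-clockwise.
    """
    if space not in DIAGRAMS:
        raise ValueError(f"unknown diagram {space!r}; expected one of {DIAGRAMS}")
    ref = importlib.resources.files("methanesource.data.polygons").joinpath(
        _FILES[space]
    )
    text = ref.read_text()
    provenance = "\n".join(
        line for line in text.splitlines() if line.startswith("#")
    )
    df = pd.read_csv(_io.StringIO(text), comment="#")
    fields = []
    for label, grp in df.groupby("label", sort=False):
        poly = orient(Polygon(zip(grp["x"], grp["y"])))
        fields.append(SourceField(str(label), space, poly, provenance))
    return fields


def classify(
    x: float,
    y: float,
    space: str,
    fields: list[SourceField] | None = None,
) -> set[str]:
    """Labels of every source field containing the point (may be empty)."""
    if fields is None:
        fields = load_fields(space)
    if space not in DIAGRAMS:
        raise ValueError(f"unknown diagram {space!r}; expected one of {DIAGRAMS}")
    if not (np.isfinite(x) and np.isfinite(y)):
        return set()
    return {f.label for f in fields if f.space == space and f.contains(x, y)}


def equilibrium_band(
    cal: EquilibriumCalibration,
    width: float = 1.5,
    n_points: int = 200,
) -> SourceField:
    """The isotopologue-equilibrium band in Δ–Δ space.

    The locus of equilibrium (Δ¹³CH₃D, Δ¹²CH₂D₂) pairs over the calibration
    temperature range, thickened by ``width`` (‰, isotropic in plot
    coordinates). Samples inside the band are consistent with internal
    isotopologue equilibrium; width 0 gives the bare curve (containment only
    for points exactly on it).
    """
    if width < 0:
        raise ValueError(f"width must be >= 0, got {width}")
    lo, hi = cal.valid_T_range
    T = np.linspace(lo, hi, n_points)
    d13, d22 = equilibrium_capdelta(T, cal)
    curve = LineString(np.column_stack([d13, d22]))
    geom = curve if width == 0 else curve.buffer(width)
    return SourceField(
        label="equilibrium-band",
        space="clumped",
        polygon=geom,
        provenance=f"equilibrium curve of calibration {cal.name!r} ± {width}‰",
    )
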