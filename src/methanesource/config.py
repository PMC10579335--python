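"""Configuration loading: endmembers, substrate ranges, run settings."""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import yaml

from .isotopes import IsotopeComposition
from .mixing import QUANTITIES, Endmember

__all__ = ["load_endmembers", "load_yaml"]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _endmember_from_dict(label: str, d: dict) -> Endmember:
    central = IsotopeComposition(**{q: float(d["central"][q]) for q in QUANTITIES})
    low = {q: float(v) for q, v in d.get("low", {}).items()}
    high = {q: float(v) for q, v in d.get("high", {}).items()}
    return Endmember(label=label, central=central, low=low, high=high)


def load_endmembers(path: Optional[str | Path] = None) -> dict[str, Endmember]:
    """Load endmember definitions from a YAML file.

    Without a path, the shipped defaults are used: reconstructions placed at
    the centroids of published genetic source fields (see the data file's
    provenance header). The file maps each label (microbial, thermogenic,
    abiotic) to ``central`` plus optional ``low``/``high`` bounding boxes.
    """
    if path is None:
        ref = importlib.resources.files("methanesource.data").joinpath(
            "endmembers.yaml"
        )
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = load_yaml(path)
    return {label: _endmember_from_dict(label, d) for label, d in raw.items()}
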