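"""End-to-end orchestration: simulate → energetics → PMM → classify.

Each stage reads/writes delimited text tables and drops a provenance sidecar
(JSON: settings, seed, package version) next to every output so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import load_endmembers
from .energetics import downcore_energetics, load_substrate_ranges
from .equilibrium import load_calibration
from .mixing import QUANTITIES
from .model import PmmModel
from .source_fields import (
    HydrocarbonComposition,
    bernard_ratio,
    classify,
    equilibrium_band,
    load_fields,
)
from .synthetic import (
    DEFAULT_NOISE_SIGMA,
    composite_nonmicrobial,
    generate_mixed_measurements,
    generate_profile,
    load_site_templates,
)

__all__ = [
    "run_simulate",
    "run_energetics",
    "run_pmm",
    "run_classify",
    "write_with_provenance",
]


def _provenance(settings: Mapping) -> dict:
    body = json.dumps(settings, sort_keys=True, default=str)
    return {
        "package": "methanesource",
        "version": __version__,
        "settings": settings,
        "settings_sha256": hashlib.sha256(body.encode()).hexdigest(),
    }


def write_with_provenance(
    df: pd.DataFrame, path: str | Path, settings: Mapping
) -> Path:
    """Write a tidy CSV plus a ``<name>.provenance.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(_provenance(settings), indent=2, default=str))
    return path


def run_simulate(
    out_dir: str | Path,
    template: str = "no_sill",
    n_depths: int = 30,
    seed: int = 0,
    n_isotope_samples: int = 8,
) -> dict[str, Path]:
    """Generate one site's geochemical profile and isotope measurement table."""
    templates = load_site_templates()
    if template not in templates:
        raise ValueError(
            f"unknown template {template!r}; available: {sorted(templates)}"
        )
    t = templates[template]
    out_dir = Path(out_dir)
    profile = generate_profile(t, n_depths=n_depths, seed=seed)
    # isotope samples only in the methanogenic zone, where methane suffices
    depths = np.linspace(t.smtz_depth + 5.0, t.max_depth, n_isotope_samples)
    ends = load_endmembers()
    nonmicrobial = composite_nonmicrobial(ends["thermogenic"], ends["abiotic"])
    table, truth = generate_mixed_measurements(
        depths, t.true_fraction, ends["microbial"], nonmicrobial,
        seed=seed + 1, site=t.name,
    )
    settings = dict(stage="simulate", template=template, n_depths=n_depths,
                    seed=seed, n_isotope_samples=n_isotope_samples,
                    noise_sigma=DEFAULT_NOISE_SIGMA)
    paths = {
        "profile": write_with_provenance(
            profile, out_dir / f"{template}_profile.csv", settings),
        "isotopes": write_with_provenance(
            table, out_dir / f"{template}_isotopes.csv", settings),
    }
    return paths


def run_energetics(
    profile_path: str | Path,
    out_path: str | Path,
    substrate_ranges: Optional[str | Path] = None,
    standin_activity: float = 1e-7,
) -> pd.DataFrame:
    """Down-core Gibbs-energy table for a porewater profile CSV."""
    profile = pd.read_csv(profile_path)
    required = {"depth_mbsf", "temperature_C", "pH", "ionic_strength",
                "CH4_molkg", "DIC_molkg", "H2_molkg", "NH4_molkg", "HS_molkg"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(
            f"profile {profile_path} is missing columns: {sorted(missing)}"
        )
    ranges = load_substrate_ranges()  # YAML override hook kept in config form
    result = downcore_energetics(profile, ranges=ranges,
                                 standin_activity=standin_activity)
    write_with_provenance(
        result, out_path,
        dict(stage="energetics", profile=str(profile_path),
             standin_activity=standin_activity,
             substrate_ranges={k: [v.min_conc, v.max_conc]
                               for k, v in ranges.items()}),
    )
    return result


def run_pmm(
    isotope_path: str | Path,
    out_path: str | Path,
    endmembers: Optional[str | Path] = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """PMM profile for an isotope measurement CSV (may be empty)."""
    table = pd.read_csv(isotope_path)
    if table.empty:
        result = pd.DataFrame(
            columns=["site", "depth_mbsf", "mean_pmm", "min_pmm", "max_pmm",
                     "pmm_thermogenic_model", "pmm_abiotic_model", "n_draws",
                     "valid", "reason"]
        )
    else:
        model = PmmModel(table, endmembers=load_endmembers(endmembers))
        result = model.fit(n_draws=n_draws, seed=seed).table
    write_with_provenance(
        result, out_path,
        dict(stage="pmm", isotopes=str(isotope_path), n_draws=n_draws,
             seed=seed, endmembers=str(endmembers) if endmembers else "shipped"),
    )
    return result


def run_classify(
    isotope_path: str | Path,
    out_path: str | Path,
    calibration: str = "eldridge2019",
    band_width: float = 1.5,
) -> pd.DataFrame:
    """Join genetic source labels from all three diagrams onto a table.

    Rows lacking the columns a diagram needs get an empty label for that
    diagram; nothing aborts. The equilibrium-band flag marks samples whose
    clumped values lie on the temperature-equilibrium curve.
    """
    table = pd.read_csv(isotope_path)
    cal = load_calibration(calibration)
    fields = {s: load_fields(s) for s in ("cd", "clumped", "bernard")}
    band = equilibrium_band(cal, width=band_width)

    def labels_for(row) -> dict:
        out = {"labels_cd": "", "labels_clumped": "", "labels_bernard": "",
               "isotopologue_equilibrium": False}
        if pd.notna(row.get("d13C")) and pd.notna(row.get("dD")):
            out["labels_cd"] = ";".join(
                sorted(classify(row["d13C"], row["dD"], "cd", fields["cd"])))
        if pd.notna(row.get("D13CH3D")) and pd.notna(row.get("D12CH2D2")):
            out["labels_clumped"] = ";".join(sorted(
                classify(row["D13CH3D"], row["D12CH2D2"], "clumped",
                         fields["clumped"])))
            out["isotopologue_equilibrium"] = band.contains(
                row["D13CH3D"], row["D12CH2D2"])
        if all(pd.notna(row.get(c)) for c in ("C1", "C2", "C3")):
            try:
                r = bernard_ratio(
                    HydrocarbonComposition(row["C1"], row["C2"], row["C3"]))
                out["labels_bernard"] = ";".join(sorted(
                    classify(row["d13C"], np.log10(r) if r > 0 else -np.inf,
                             "bernard", fields["bernard"])))
            except ZeroDivisionError:
                pass
        return out

    joined = pd.concat(
        [table, pd.DataFrame([labels_for(r) for _, r in table.iterrows()],
                             index=table.index)],
        axis=1,
    )
    write_with_provenance(
        joined, out_path,
        dict(stage="classify", isotopes=str(isotope_path),
             calibration=calibration, band_width=band_width),
    )
    return joined
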