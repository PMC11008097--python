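"""End-to-end composite-model workflows driven by a config file.

A run config is flat INI-style key/value text: a ``[global]`` section
with the temperature grid and pressure, and one ``[polymorph:NAME]``
section per phase naming its composite model and ingredient files::

    [global]
    tmax = 400
    tstep = 5
    pressure = 0.0

    [polymorph:alpha]
    spec = M4
    low_ev = alpha_low_ev.csv
    low_phonons = alpha_low_phonons.yaml
    high_ev = alpha_high_ev.csv
    high_phonons = alpha_high_phonons.yaml

Outputs (deterministic for fixed inputs): one thermo CSV per polymorph,
a ΔG/ΔH ranking CSV + JSON summary when exactly two polymorphs are
given, and a structured log echoing every default in effect.
"""

from __future__ import annotations

import configparser
import json
import logging
from pathlib import Path

import numpy as np

from .composite import Ingredients, assemble_composite
from .exceptions import InputError
from .io import read_ev_curve, read_phonons, write_thermo_table
from .ranking import rank_polymorphs
from .thermo import composite_thermo

__all__ = ["run_workflow"]

log = logging.getLogger(__name__)


def _load_ingredients(section, base: Path) -> Ingredients:
    def path(key):
        rel = section.get(key)
        return None if rel is None else base / rel

    ev = path("low_ev")
    ph = path("low_phonons")
    hev = path("high_ev")
    hph = path("high_phonons")
    low = Ingredients(
        ev=read_ev_curve(ev) if ev else None,
        phonons=read_phonons(ph) if ph else None,
    )
    high = Ingredients(
        ev=read_ev_curve(hev) if hev else None,
        phonons=read_phonons(hph) if hph else None,
        v0=section.getfloat("high_v0", fallback=None),
        e0=section.getfloat("high_e0", fallback=None),
    )
    return low, high


def run_workflow(config_path, out_dir) -> dict:
    """Run the configured composite workflows and write all outputs.

    Returns the JSON summary (also written to ``summary.json``).
    """
    config_path = Path(config_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = config_path.parent

    cfg = configparser.ConfigParser()
    if not cfg.read(config_path):
        raise InputError(f"cannot read config file {config_path}")

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cqha")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    g = cfg["global"] if cfg.has_section("global") else {}
    tmax = float(g.get("tmax", 400.0))
    tstep = float(g.get("tstep", 5.0))
    pressure = float(g.get("pressure", 0.0))
    tfus = g.get("tfus")
    temperatures = np.arange(0.0, tmax + 0.5 * tstep, tstep)
    log.info("temperature grid 0..%g K step %g K, pressure %g GPa",
             tmax, tstep, pressure)

    poly_sections = [s for s in cfg.sections() if s.startswith("polymorph:")]
    if not poly_sections:
        raise InputError("config names no [polymorph:NAME] sections")

    tables = {}
    z_seen = {}
    for sec_name in poly_sections:
        name = sec_name.split(":", 1)[1]
        sec = cfg[sec_name]
        spec = sec.get("spec", "M1")
        low, high = _load_ingredients(sec, base)
        model = assemble_composite(spec, low, high)
        z_seen[name] = model.z_molecules
        log.info("polymorph %s: model %s, Z=%d, ΔV0=%.4f Å³",
                 name, spec, model.z_molecules, model.delta_v0)
        table = composite_thermo(model, temperatures, pressure)
        tables[name] = table
        write_thermo_table(table, out_dir / f"{name}_thermo.csv")

    if len(set(z_seen.values())) > 1:
        raise InputError(f"inconsistent Z between polymorph inputs: {z_seen}")

    summary = {
        "polymorphs": sorted(tables),
        "pressure_GPa": pressure,
        "t_max_K": tmax,
    }
    if len(tables) == 2:
        (name_a, ta), (name_b, tb) = sorted(tables.items())
        t_range = (0.0, float(tfus)) if tfus else None
        result = rank_polymorphs(ta, tb, t_range=t_range, labels=(name_a, name_b))
        _write_ranking(result, out_dir / "ranking.csv")
        summary["ranking"] = {
            "labels": list(result.polymorph_labels),
            "relationship": result.relationship,
            "crossing_temperatures_K": list(result.crossing_temperatures),
            "delta_g_298K_kJ_mol": float(
                np.interp(298.15, result.temperatures, result.delta_g)
            ),
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    root.removeHandler(handler)
    handler.close()
    return summary


def _write_ranking(result, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# polymorphs: {result.polymorph_labels[1]} relative to "
                 f"{result.polymorph_labels[0]}\n")
        fh.write(f"# relationship: {result.relationship}\n")
        fh.write("temperature_K,delta_g_kJ_mol,delta_h_kJ_mol,t_delta_s_kJ_mol\n")
        for row in zip(result.temperatures, result.delta_g, result.delta_h,
                       result.t_delta_s):
            fh.write(",".join(repr(float(x)) for x in row) + "\n")
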