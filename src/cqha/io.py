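"""Readers and writers for the toolkit's file formats.

Formats (one shipped example of each under ``examples/data/``):

* **E(V) curves** — CSV with ``volume``/``energy`` columns, ``#`` comment
  metadata lines (``level``, ``z_molecules``, ``units``); volumes in Å³,
  energies in a declarable unit converted to kJ mol⁻¹ on read.
* **Phonon sets** — YAML: per-volume blocks of q-points, each with an
  optional fractional coordinate ``q``, a ``weight`` and a flat
  ``frequencies`` list in THz (negative = imaginary).
* **Thermo tables** — CSV with unit-stamped header comments; round-trips
  bit-identically through :func:`read_thermo_table`.
* **Structures** — CIF, read through gemmi, with molecules perceived via
  the covalent-radius criterion.
* **Dimer manifests / pair energies** — CSV keyed by a dimer id.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml

from .constants import energy_factor
from .datamodel import (
    CrystalStructure,
    DimerRecord,
    EVCurve,
    GruneisenTable,
    PhononSet,
    QPoint,
    ThermoTable,
)
from .exceptions import InputError
from .molecules import DEFAULT_BOND_MARGIN, perceive_molecules

__all__ = [
    "read_ev_curve", "write_ev_curve",
    "read_phonons", "write_phonons",
    "read_structure",
    "read_thermo_table", "write_thermo_table",
    "write_gruneisen_table",
    "read_dimers_csv", "write_dimers_csv", "read_pair_energies_csv",
    "write_dimer_xyz",
]

def _read_comment_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip().lower()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# E(V) curves
# ---------------------------------------------------------------------------

def read_ev_curve(path, units: str | None = None) -> EVCurve:
    """Read an E(V) CSV; energies are converted to kJ mol⁻¹ per cell.

    The energy unit comes from the ``units`` argument, falling back to a
    ``# units:`` metadata line, then to kJ/mol.  Rows are sorted by
    volume; duplicate volumes and fewer than 5 rows are errors, and a
    minimum at an endpoint only warns (the fit will reject it later).
    """
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#")
    vcol = next((c for c in df.columns if "vol" in c.lower()), None)
    ecol = next((c for c in df.columns if "energ" in c.lower()), None)
    if vcol is None or ecol is None:
        raise InputError("E(V) CSV needs columns naming volume and energy")
    if len(df) < 5:
        raise InputError("insufficient points: E(V) curve needs >= 5 rows")
    v = df[vcol].to_numpy(float)
    e = df[ecol].to_numpy(float)
    order = np.argsort(v, kind="stable")
    v, e = v[order], e[order]
    if np.any(np.diff(v) == 0):
        raise InputError("duplicate volume in E(V) file")
    unit = units or meta.get("units", "kJ/mol")
    e = e * energy_factor(unit)
    curve = EVCurve(
        v, e,
        level_label=meta.get("level", ""),
        z_molecules=int(meta.get("z_molecules", 1)),
    )
    if not curve.has_interior_minimum:
        warnings.warn("unbracketed minimum: lowest energy at a grid endpoint",
                      stacklevel=2)
    return curve


def write_ev_curve(curve: EVCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# level: {curve.level_label}\n")
        fh.write(f"# z_molecules: {curve.z_molecules}\n")
        fh.write("# units: kJ/mol\n")
        fh.write("volume_A3,energy\n")
        for v, e in zip(curve.volumes, curve.energies):
            fh.write(f"{float(v)!r},{float(e)!r}\n")


# ---------------------------------------------------------------------------
# phonon sets
# ---------------------------------------------------------------------------

def read_phonons(path) -> PhononSet:
    """Read a YAML phonon file into a :class:`PhononSet`.

    Q-point weights per volume must sum to 1 within 1e-6 (they are
    renormalized when closer than that, rejected otherwise).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "volumes" not in doc:
        raise InputError("phonon file lacks a 'volumes' list")
    volumes = []
    blocks = []
    for entry in doc["volumes"]:
        volumes.append(float(entry["volume"]))
        qpoints = []
        weights = [float(q["weight"]) for q in entry["qpoints"]]
        wsum = sum(weights)
        if abs(wsum - 1.0) >= 1e-6:
            raise InputError(f"bad weights: q-point weights sum to {wsum}")
        for q, w in zip(entry["qpoints"], weights):
            coords = q.get("q")
            qpoints.append(QPoint(
                w / wsum,
                np.asarray(q["frequencies"], dtype=float),
                q=None if coords is None else tuple(float(c) for c in coords),
            ))
        blocks.append(tuple(qpoints))
    return PhononSet(np.array(volumes), tuple(blocks),
                     level_label=str(doc.get("level", "")))


def write_phonons(phonons: PhononSet, path) -> None:
    doc = {
        "level": phonons.level_label,
        "volumes": [
            {
                "volume": float(v),
                "qpoints": [
                    {
                        **({} if q.q is None else {"q": [float(c) for c in q.q]}),
                        "weight": float(q.weight),
                        "frequencies": [float(f) for f in q.frequencies],
                    }
                    for q in block
                ],
            }
            for v, block in zip(phonons.volumes, phonons.qpoints)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# crystal structures (CIF)
# ---------------------------------------------------------------------------

def read_structure(path, bond_margin: float = DEFAULT_BOND_MARGIN) -> CrystalStructure:
    """Read a CIF and perceive molecules.

    Atoms closer than r_cov(i) + r_cov(j) + ``bond_margin`` (periodic
    images included) are bonded; molecules are the connected components.
    """
    import gemmi

    small = gemmi.read_small_structure(str(path))
    cell = small.cell
    if cell.volume <= 0 or not small.sites:
        raise InputError("not a crystal: CIF lacks cell parameters or atom sites")
    # orth.mat maps fractional column vectors to Cartesian (x = M·f), so
    # the lattice vectors a, b, c are its columns; we store them as rows.
    cell_vectors = np.array(cell.orth.mat.tolist(), dtype=float).T
    elements = []
    frac = []
    for site in small.get_all_unit_cell_sites():
        elements.append(site.element.name)
        frac.append([site.fract.x, site.fract.y, site.fract.z])
    struct = CrystalStructure(cell_vectors, tuple(elements), np.array(frac))
    return perceive_molecules(struct, bond_margin)


# ---------------------------------------------------------------------------
# thermo tables
# ---------------------------------------------------------------------------

_THERMO_HEADER = (
    "temperature_K,v_eq_A3_cell,g_kJ_mol,h_kJ_mol,s_J_K_mol,"
    "cp_J_K_mol,cv_J_K_mol,alpha_p_K,kappa_t_GPa\n"
)


def write_thermo_table(table: ThermoTable, path) -> None:
    """One row per temperature with fixed column order and unit-stamped
    header; bit-identical round trip through :func:`read_thermo_table`."""
    with open(path, "w") as fh:
        fh.write(f"# pressure_GPa: {table.pressure!r}\n")
        fh.write(f"# zpe_kJ_mol: {table.zpe!r}\n")
        fh.write(f"# z_molecules: {table.z_molecules}\n")
        fh.write(_THERMO_HEADER)
        cols = (table.temperatures, table.v_eq, table.g, table.h, table.s,
                table.cp, table.cv, table.alpha_p, table.kappa_t)
        for row in zip(*cols):
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_thermo_table(path) -> ThermoTable:
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise InputError("nothing to write: thermo table file has no rows")
    return ThermoTable(
        pressure=float(meta.get("pressure_gpa", 0.0)),
        temperatures=df.iloc[:, 0].to_numpy(float),
        v_eq=df.iloc[:, 1].to_numpy(float),
        g=df.iloc[:, 2].to_numpy(float),
        h=df.iloc[:, 3].to_numpy(float),
        s=df.iloc[:, 4].to_numpy(float),
        cp=df.iloc[:, 5].to_numpy(float),
        cv=df.iloc[:, 6].to_numpy(float),
        alpha_p=df.iloc[:, 7].to_numpy(float),
        kappa_t=df.iloc[:, 8].to_numpy(float),
        zpe=float(meta.get("zpe_kj_mol", 0.0)),
        z_molecules=int(meta.get("z_molecules", 1)),
    )


# ---------------------------------------------------------------------------
# Grüneisen tables, dimer manifests
# ---------------------------------------------------------------------------

def write_gruneisen_table(table: GruneisenTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# v_ref_A3: {table.v_ref!r}\n")
        fh.write("qpoint,rank,nu0_THz,gamma,fit_residual_THz\n")
        for iq, block in enumerate(table.modes):
            for r, m in enumerate(block):
                fh.write(f"{iq},{r},{m.nu0!r},{m.gamma!r},{m.fit_residual!r}\n")


def write_dimers_csv(dimers, path) -> None:
    with open(path, "w") as fh:
        fh.write("dimer_id,mol_i,mol_j,tx,ty,tz,min_distance_A,multiplicity,"
                 "pair_energy_kJ_mol\n")
        for k, d in enumerate(dimers):
            eps = "" if d.pair_energy is None else repr(d.pair_energy)
            fh.write(f"{k},{d.mol_i},{d.mol_j},{d.translation[0]},"
                     f"{d.translation[1]},{d.translation[2]},"
                     f"{float(d.min_distance)!r},{d.multiplicity},{eps}\n")


def read_dimers_csv(path) -> list[DimerRecord]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        eps = row.get("pair_energy_kJ_mol")
        out.append(DimerRecord(
            mol_i=int(row["mol_i"]),
            mol_j=int(row["mol_j"]),
            translation=(int(row["tx"]), int(row["ty"]), int(row["tz"])),
            min_distance=float(row["min_distance_A"]),
            multiplicity=int(row["multiplicity"]),
            pair_energy=None if pd.isna(eps) else float(eps),
        ))
    return out


def read_pair_energies_csv(path) -> dict[int, float]:
    """Map dimer_id → ε_ij (kJ mol⁻¹) from a two-column CSV."""
    df = pd.read_csv(path, comment="#")
    idc = next((c for c in df.columns if "id" in c.lower()), df.columns[0])
    ec = next((c for c in df.columns if "energ" in c.lower()), df.columns[-1])
    return {int(r[idc]): float(r[ec]) for _, r in df.iterrows()}


def write_dimer_xyz(structure, record, path) -> None:
    """Write the representative dimer geometry as a plain XYZ file."""
    from .molecules import unwrap_molecules

    mols = unwrap_molecules(structure)
    elems_i, coords_i = mols[record.mol_i]
    elems_j, coords_j = mols[record.mol_j]
    shift = np.asarray(record.translation, float) @ structure.cell_vectors
    coords_j = coords_j + shift
    with open(path, "w") as fh:
        fh.write(f"{len(elems_i) + len(elems_j)}\n")
        fh.write(f"dimer {record.mol_i}-{record.mol_j} t={record.translation} "
                 f"min_d={record.min_distance:.4f} A\n")
        for e, c in zip(elems_i + elems_j,
                        np.concatenate([coords_i, coords_j])):
            fh.write(f"{e} {c[0]:.8f} {c[1]:.8f} {c[2]:.8f}\n")
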