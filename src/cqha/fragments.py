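"""Fragment-based lattice energies from monomers and dimers.

All molecular pairs with a closest atom–atom contact inside a cutoff
(8 Å by default, configurable) are enumerated over periodic images,
collapsed into symmetry-unique records with multiplicities, and combined
with externally computed monomer and pair interaction energies into the
per-cell lattice energy

    E_lat = Σ_i (E_i − E_i^gas) + ½ · Σ_unique m_ij · ε_ij ,

where the monomer sum runs over the molecules of one unit cell, m_ij
counts the anchored image pairs a unique record represents and the ½
prevents double counting.
"""

from __future__ import annotations

import itertools
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import CrystalStructure, DimerRecord
from .exceptions import InputError
from .molecules import unwrap_molecules

__all__ = [
    "DEFAULT_CUTOFF",
    "enumerate_dimers",
    "evaluate_pair_energies",
    "assemble_lattice_energy",
    "ranking_correction",
]

#: Default closest-contact dimer cutoff, Å.
DEFAULT_CUTOFF = 8.0

_FINGERPRINT_TOL = 1e-4  # Å, distance rounding for symmetry detection


def _translation_bounds(cell: np.ndarray, reach: float) -> list[int]:
    """Image search bounds per lattice direction for a given radial reach."""
    recip = np.linalg.inv(cell).T  # rows are reciprocal vectors (no 2π)
    spacing = 1.0 / np.linalg.norm(recip, axis=1)
    return [int(np.ceil(reach / d)) + 1 for d in spacing]


def _fingerprint(elems_a, coords_a, elems_b, coords_b) -> tuple:
    """Geometry hash of a dimer: sorted labeled inter-molecular distances."""
    d = cdist(coords_a, coords_b)
    items = []
    for ia, ea in enumerate(elems_a):
        for ib, eb in enumerate(elems_b):
            pair = (ea, eb) if ea <= eb else (eb, ea)
            items.append((pair, round(d[ia, ib] / _FINGERPRINT_TOL)))
    return tuple(sorted(items))


def enumerate_dimers(
    structure: CrystalStructure, cutoff: float = DEFAULT_CUTOFF
) -> list[DimerRecord]:
    """Symmetry-unique molecular pairs within a closest-contact cutoff.

    Every ordered pair (molecule of the reference cell, molecule in any
    periodic image) with minimum interatomic distance ≤ cutoff is found
    by brute-force image search, mapped to its unordered canonical form,
    and grouped by a distance fingerprint; each group becomes one record
    whose multiplicity is the anchored (ordered) pair count.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if structure.molecule_partition is None:
        raise InputError("molecules not perceived")
    mols = unwrap_molecules(structure)
    cell = structure.cell_vectors
    centroids = [c.mean(axis=0) for _, c in mols]
    radii = [float(np.max(np.linalg.norm(c - ctr, axis=1))) if len(c) > 1 else 0.0
             for (_, c), ctr in zip(mols, centroids)]
    reach = cutoff + 2.0 * max(radii) + 1e-9
    na, nb, nc = _translation_bounds(cell, reach)

    seen_unordered: set[tuple] = set()
    groups: dict[tuple, dict] = {}
    n_ordered: dict[tuple, int] = {}

    for i, j in itertools.product(range(len(mols)), repeat=2):
        elems_i, coords_i = mols[i]
        elems_j, coords_j = mols[j]
        for t in itertools.product(
            range(-na, na + 1), range(-nb, nb + 1), range(-nc, nc + 1)
        ):
            if i == j and t == (0, 0, 0):
                continue
            shift = np.asarray(t, float) @ cell
            # cheap centroid prefilter before the full distance matrix
            if (np.linalg.norm(centroids[j] + shift - centroids[i])
                    > cutoff + radii[i] + radii[j]):
                continue
            dmin = float(cdist(coords_i, coords_j + shift).min())
            if dmin > cutoff:
                continue
            key = min((i, j, t), (j, i, tuple(-x for x in t)))
            if key not in seen_unordered:
                seen_unordered.add(key)
                fp = _fingerprint(elems_i, coords_i, elems_j, coords_j + shift)
                if fp not in groups:
                    groups[fp] = {
                        "mol_i": key[0], "mol_j": key[1],
                        "translation": key[2], "min_distance": dmin,
                    }
                    n_ordered[fp] = 0
                groups[fp]["min_distance"] = min(groups[fp]["min_distance"], dmin)
            else:
                fp = _fingerprint(elems_i, coords_i, elems_j, coords_j + shift)
            n_ordered[fp] += 1

    return [
        DimerRecord(
            mol_i=g["mol_i"],
            mol_j=g["mol_j"],
            translation=tuple(g["translation"]),
            min_distance=g["min_distance"],
            multiplicity=n_ordered[fp],
        )
        for fp, g in groups.items()
    ]


def evaluate_pair_energies(
    structure: CrystalStructure,
    dimers: Sequence[DimerRecord],
    pair_potential: Callable[[str, str, float], float],
) -> list[DimerRecord]:
    """Fill ε_ij of each record from an analytic atom-pair potential.

    ``pair_potential(elem_a, elem_b, r)`` returns the interaction of two
    atoms at distance r (kJ mol⁻¹); the dimer energy is the sum over all
    inter-molecular atom pairs of the record's representative geometry.
    """
    mols = unwrap_molecules(structure)
    cell = structure.cell_vectors
    out = []
    for rec in dimers:
        elems_i, coords_i = mols[rec.mol_i]
        elems_j, coords_j = mols[rec.mol_j]
        shift = np.asarray(rec.translation, float) @ cell
        d = cdist(coords_i, coords_j + shift)
        eps = sum(
            pair_potential(ea, eb, d[ia, ib])
            for ia, ea in enumerate(elems_i)
            for ib, eb in enumerate(elems_j)
        )
        out.append(
            DimerRecord(rec.mol_i, rec.mol_j, rec.translation,
                        rec.min_distance, rec.multiplicity, float(eps))
        )
    return out


def assemble_lattice_energy(
    monomer_energies: Sequence[tuple[float, float]],
    dimers: Sequence[DimerRecord],
) -> float:
    """Per-cell lattice energy from monomer and pair energies.

    ``monomer_energies[k]`` is ``(E_k, E_k_gas)`` for molecule k of the
    unit cell (kJ mol⁻¹); pass equal values (or zeros) for a
    strain-free sum.  Every dimer record must carry a pair energy.
    """
    strain = 0.0
    for k, pair in enumerate(monomer_energies):
        try:
            e_mol, e_gas = pair
        except TypeError as exc:
            raise InputError(
                f"incomplete energy table: monomer {k} needs (E, E_gas)"
            ) from exc
        strain += e_mol - e_gas
    pair_sum = 0.0
    for rec in dimers:
        if rec.pair_energy is None:
            raise InputError(
                "incomplete energy table: dimer "
                f"({rec.mol_i}, {rec.mol_j}, {rec.translation}) has no ε_ij"
            )
        pair_sum += rec.multiplicity * rec.pair_energy
    return strain + 0.5 * pair_sum


def ranking_correction(
    lat_a_baseline: float,
    lat_a_refined: float,
    lat_b_baseline: float,
    lat_b_refined: float,
) -> float:
    """Refinement-induced ΔE correction for polymorph B relative to A.

    (E_B^refined − E_B^baseline) − (E_A^refined − E_A^baseline), per
    molecule; feed the result to :func:`cqha.ranking.refine_ranking`.
    """
    return (lat_b_refined - lat_b_baseline) - (lat_a_refined - lat_a_baseline)
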