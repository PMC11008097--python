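"""Molecule perception in periodic crystals.

Atoms are bonded when their minimum-image distance is below
r_cov(i) + r_cov(j) + margin; molecules are the connected components of
the bond graph.  The covalent radii are pinned to the Cordero (2008)
consensus set so that perception is reproducible.
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np

from .datamodel import CrystalStructure
from .exceptions import InputError

__all__ = ["COVALENT_RADII", "DEFAULT_BOND_MARGIN", "perceive_molecules",
           "unwrap_molecules"]

log = logging.getLogger(__name__)

#: Default extra slack on the covalent-radius bond criterion, Å.
DEFAULT_BOND_MARGIN = 0.4

#: Covalent radii (Å), Cordero et al. 2008 single-bond consensus values
#: (sp³ carbon; high-spin Mn/Fe/Co).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Ti": 1.60, "Cr": 1.39, "Mn": 1.39, "Fe": 1.32,
    "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "I": 1.39, "Xe": 1.40,
}


def _radius(element: str) -> float:
    el = element.capitalize()
    if el not in COVALENT_RADII:
        raise InputError(f"no covalent radius tabulated for element {element!r}")
    return COVALENT_RADII[el]


def _bond_list(structure: CrystalStructure, margin: float):
    """All bonded pairs (i, j, image shift of j) under the distance criterion."""
    cell = structure.cell_vectors
    frac = structure.frac_coords
    n = structure.n_atoms
    radii = np.array([_radius(e) for e in structure.elements])
    shifts = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
    )
    shift_cart = shifts @ cell
    cart = frac @ cell
    bonds = []
    for i in range(n):
        for j in range(i, n):
            d = cart[j] + shift_cart - cart[i]
            dist = np.linalg.norm(d, axis=1)
            thresh = radii[i] + radii[j] + margin
            for k in np.nonzero(dist < thresh)[0]:
                if i == j and tuple(shifts[k]) >= (0, 0, 0):
                    continue  # self and double-counted self-images
                bonds.append((i, j, tuple(int(x) for x in shifts[k])))
    return bonds


def perceive_molecules(
    structure: CrystalStructure, bond_margin: float = DEFAULT_BOND_MARGIN
) -> CrystalStructure:
    """Return the structure with ``molecule_partition`` filled in.

    Single-atom molecules (an atom bonded to nothing) are allowed and
    logged.  Periodic images are considered when testing bonds.
    """
    n = structure.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j, _t in _bond_list(structure, bond_margin):
        if i != j:
            adj[i].append(j)
            adj[j].append(i)
    part = -np.ones(n, dtype=int)
    mol = 0
    for start in range(n):
        if part[start] >= 0:
            continue
        queue = deque([start])
        part[start] = mol
        size = 0
        while queue:
            a = queue.popleft()
            size += 1
            for b in adj[a]:
                if part[b] < 0:
                    part[b] = mol
                    queue.append(b)
        if size == 1:
            log.info("atom %d (%s) forms a single-atom molecule",
                     start, structure.elements[start])
        mol += 1
    return CrystalStructure(
        cell_vectors=structure.cell_vectors,
        elements=structure.elements,
        frac_coords=structure.frac_coords,
        molecule_partition=part,
        symmetry_ops=structure.symmetry_ops,
    )


def unwrap_molecules(
    structure: CrystalStructure, bond_margin: float = DEFAULT_BOND_MARGIN
):
    """Cartesian coordinates of each molecule made whole across boundaries.

    Returns a list (one entry per molecule) of ``(elements, coords)`` with
    coords chosen so every bond uses the closest periodic image of its
    partner (BFS over the bond graph assigning integer image offsets).
    """
    if structure.molecule_partition is None:
        raise InputError("molecules not perceived")
    cell = structure.cell_vectors
    frac = structure.frac_coords
    part = structure.molecule_partition
    n = structure.n_atoms
    adj: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
    for i, j, t in _bond_list(structure, bond_margin):
        if i != j:
            t = np.array(t)
            adj[i].append((j, t))
            adj[j].append((i, -t))
    offsets = np.zeros((n, 3))
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start]:
            continue
        seen[start] = True
        queue = deque([start])
        while queue:
            a = queue.popleft()
            for b, t in adj[a]:
                if not seen[b]:
                    seen[b] = True
                    offsets[b] = offsets[a] + t
                    queue.append(b)
    cart = (frac + offsets) @ cell
    out = []
    for m in range(int(part.max()) + 1):
        idx = np.nonzero(part == m)[0]
        out.append((tuple(structure.elements[i] for i in idx), cart[idx]))
    return out
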